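"""Somatic filter chain: quality gates, trio status rules, rescue, burden."""

import numpy as np
import pytest

from relapsetrio.filtering import (
    FilterConfig,
    SampleEvidence,
    SomaticEvent,
    call_trio,
    compute_vaf,
    coverage_qc,
    exclude_population_variants,
    pass_quality,
    rescue_cross_tumor,
    somatic_status_single,
    summarize_burden,
)
from relapsetrio.simulate import SimulationConfig, simulate_trio
from relapsetrio.trio_io import SiteObservation, TrioDataset

from conftest import wide_baits

CFG = FilterConfig()


def obs(pos=500, depth=40, alt_reads=10, qphred=35.0, variant_class="SNV",
        functional="missense", **kw):
    ref, alt = ("A", "T") if variant_class == "SNV" else ("A", "ACT")
    return SiteObservation("chr1", pos, ref, alt, depth, alt_reads, qphred,
                           variant_class, functional, **kw)


class TestComputeVaf:
    def test_basic_fraction(self):
        assert compute_vaf(25, 100) == 0.25
        assert compute_vaf(0, 50) == 0.0

    def test_zero_depth_is_nan(self):
        assert np.isnan(compute_vaf(0, 0))

    def test_alt_above_depth_errors(self):
        with pytest.raises(ValueError):
            compute_vaf(3, 0)


class TestPassQuality:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(), True),                                   # depth 40, alt 10, q 35
            (dict(qphred=19.0), False),                       # SNV needs >= 20
            (dict(qphred=20.0), True),
            (dict(variant_class="insertion", functional="frameshift",
                  qphred=25.0), False),                       # indel needs >= 30
            (dict(variant_class="insertion", functional="frameshift",
                  qphred=30.0), True),
            (dict(depth=9, alt_reads=9), False),              # depth gate
            (dict(depth=10, alt_reads=4), False),             # alt-read gate
            (dict(depth=10, alt_reads=5, qphred=20.0), True),  # all at boundary
        ],
    )
    def test_thresholds(self, kw, expected):
        assert pass_quality(obs(**kw), wide_baits(), CFG) is expected

    def test_off_bait_fails(self):
        assert not pass_quality(obs(pos=20_000_001), wide_baits(), CFG)


class TestSomaticStatusSingle:
    @pytest.mark.parametrize(
        "tumor_vaf,remission_vaf,expected",
        [
            (0.40, 0.00, "somatic"),
            (0.40, 0.05, "not_somatic"),   # strict < 0.05
            (0.40, 0.049, "somatic"),
            (0.14, 0.00, "not_somatic"),   # below tumor threshold
            (0.15, 0.00, "somatic"),       # >= 0.15 inclusive
        ],
    )
    def test_vaf_boundaries(self, tumor_vaf, remission_vaf, expected):
        t = obs(depth=100, alt_reads=round(tumor_vaf * 100))
        r = obs(depth=1000, alt_reads=round(remission_vaf * 1000))
        assert somatic_status_single(t, r, CFG) == expected

    def test_missing_remission_is_unassessable(self):
        assert somatic_status_single(obs(alt_reads=30), None, CFG) == "unassessable"
        r0 = obs(depth=0, alt_reads=0)
        assert somatic_status_single(obs(alt_reads=30), r0, CFG) == "unassessable"


def _trio_event(status, other_depth, other_alt):
    return SomaticEvent(
        chrom="chr1", pos=100, ref="A", alt="T", variant_class="SNV",
        functional="missense", status=status,
        per_sample={"diagnosis": SampleEvidence(100, 40),
                    "relapse": SampleEvidence(other_depth, other_alt)},
    )


class TestRescue:
    def test_vaf_arm(self):
        e = _trio_event("somatic_diagnosis", 100, 6)   # VAF 0.06 >= 0.05
        rescue_cross_tumor([e], CFG)
        assert e.status == "somatic_shared" and e.rescued

    def test_read_count_arm(self):
        e = _trio_event("somatic_diagnosis", 150, 2)   # VAF 0.013 but 2 reads
        rescue_cross_tumor([e], CFG)
        assert e.status == "somatic_shared" and e.rescued

    def test_below_both_arms_stays_specific(self):
        e = _trio_event("somatic_diagnosis", 150, 1)
        rescue_cross_tumor([e], CFG)
        assert e.status == "somatic_diagnosis" and not e.rescued

    def test_rescue_never_demotes(self):
        for status in ("somatic_shared", "somatic_relapse", "undetermined"):
            e = _trio_event(status, 150, 0)
            before = e.status
            rescue_cross_tumor([e], CFG)
            assert e.status in (before, "somatic_shared")


class TestPopulationFilter:
    @pytest.mark.parametrize("pop_af,kept", [(0.05, False), (0.011, False),
                                             (0.01, True), (None, True)])
    def test_boundary(self, pop_af, kept):
        e = _trio_event("somatic_shared", 100, 40)
        e.pop_af = pop_af
        assert (len(exclude_population_variants([e], CFG)) == 1) is kept


class TestBurden:
    def test_counts_split_by_class_and_acquisition(self):
        events = [
            _trio_event("somatic_shared", 100, 40),
            _trio_event("somatic_diagnosis", 100, 0),
            _trio_event("somatic_relapse", 100, 40),
        ]
        events[1].variant_class = "insertion"
        events[1].functional = "frameshift"
        b = summarize_burden(events)
        assert b["diagnosis"] == {"substitutions": 1, "indels": 1}
        assert b["relapse_acquired"] == {"substitutions": 1, "indels": 0}

    def test_synonymous_not_counted(self):
        e = _trio_event("somatic_shared", 100, 40)
        e.functional = "synonymous"
        b = summarize_burden([e])
        assert b["diagnosis"] == {"substitutions": 0, "indels": 0}

    def test_all_shared_means_zero_relapse_acquired(self):
        events = [_trio_event("somatic_shared", 100, 40) for _ in range(4)]
        assert summarize_burden(events)["relapse_acquired"]["substitutions"] == 0


class TestCoverageQc:
    def test_mean_and_fraction(self):
        out = coverage_qc(np.array([30.0, 20.0, 40.0, 10.0]))
        assert out == {"mean_depth": 25.0, "fraction_ge_25x": 0.5}
        assert coverage_qc(np.full(10, 91.0)) == {"mean_depth": 91.0,
                                                  "fraction_ge_25x": 1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            coverage_qc(np.array([]))

    def test_gamma_depths_match_empirical_cdf(self):
        rng = np.random.default_rng(5)
        depths = rng.gamma(shape=10, scale=9.1, size=2000)
        out = coverage_qc(depths)
        assert out["mean_depth"] == pytest.approx(depths.mean())
        assert out["fraction_ge_25x"] == pytest.approx((depths >= 25).mean())


class TestTrioCalling:
    def test_noise_free_pure_trio_recovers_every_clonal_mutation(self):
        cfg = SimulationConfig.for_mode("branched", seed=11, n_germline_snps=400,
                                        n_cna_snps=0, purity_diagnosis=1.0,
                                        purity_relapse=1.0, error_rate=0.0,
                                        off_bait_fraction=0.0)
        sim = simulate_trio(cfg)
        events = {e.site: e for e in call_trio(sim.trio)}
        want = {"ancestral": "somatic_shared",
                "diagnosis_specific": "somatic_diagnosis",
                "relapse_specific": "somatic_relapse"}
        for m in sim.truth["mutations"]:
            site = (m["chrom"], m["pos"], m["ref"], m["alt"])
            assert site in events, f"missed {site} ({m['clone']})"
            assert events[site].status == want[m["clone"]]
        # and nothing beyond the truth is called somatic
        truth_sites = {(m["chrom"], m["pos"], m["ref"], m["alt"])
                       for m in sim.truth["mutations"]}
        assert set(events) == truth_sites

    def test_quality_and_population_filters_commute(self):
        cfg = SimulationConfig.for_mode("linear", seed=23, n_germline_snps=300,
                                        n_cna_snps=0)
        sim = simulate_trio(cfg)
        base = call_trio(sim.trio)
        # population filter applied redundantly up front must not change the set
        pre = {role: t[~(t["pop_af"].fillna(0) > CFG.pop_af_max)].reset_index(drop=True)
               for role, t in sim.trio.samples.items()}
        trio2 = TrioDataset(sim.trio.patient_id, pre, sim.trio.baits,
                            sim.trio.fusion_breakpoint)
        assert {e.site for e in base} == {e.site for e in call_trio(trio2)}

    def test_pairs_only_mode_never_calls_diagnosis_somatic(self):
        cfg = SimulationConfig.for_mode("branched", seed=13, n_germline_snps=300,
                                        n_cna_snps=0, include_remission=False)
        sim = simulate_trio(cfg)
        events = call_trio(sim.trio)
        statuses = {e.status for e in events}
        assert "somatic_diagnosis" not in statuses
        assert "somatic_shared" not in statuses
        # relapse-acquired events are still identified
        relapse_true = {(m["chrom"], m["pos"], m["ref"], m["alt"])
                        for m in sim.truth["mutations"]
                        if m["clone"] == "relapse_specific" and m["in_bait"]}
        relapse_called = {e.site for e in events if e.status == "somatic_relapse"}
        assert relapse_true <= relapse_called

    def test_duplicate_site_in_sample_rejected(self, linear_sim):
        import pandas as pd
        t = linear_sim.trio.samples["diagnosis"]
        dup = pd.concat([t, t.iloc[[0]]], ignore_index=True)
        bad = TrioDataset("X", {"diagnosis": dup,
                                "relapse": linear_sim.trio.samples["relapse"]},
                          linear_sim.trio.baits)
        with pytest.raises(Exception, match="duplicate"):
            call_trio(bad)
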