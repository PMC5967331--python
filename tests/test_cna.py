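"""Copy-number stage: LRR/BAF, CBS vs exhaustive oracle, lattice fit, labels."""

import numpy as np
import pandas as pd
import pytest

from relapsetrio.cna import (
    CbsConfig,
    CopyNumberSegment,
    GapConfig,
    PloidyPurityFit,
    assign_allele_specific_cn,
    cbs_changepoints,
    call_cna,
    classify_aberrations,
    compute_lrr_baf,
    fit_ploidy_purity,
    segment_profile,
)
from relapsetrio.simulate import CnaSpec, SimulationConfig, simulate_trio

FAST_CBS = CbsConfig(n_permutations=400)


def exhaustive_single_changepoint(x, min_width=5):
    """Oracle: argmax over single split points of the two-sample |t|."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    best_t, best_i = -np.inf, None
    for i in range(min_width, n - min_width + 1):
        t = abs(x[:i].mean() - x[i:].mean()) / (sd * np.sqrt(1 / i + 1 / (n - i)))
        if t > best_t:
            best_t, best_i = t, i
    return best_i


def snp_frame(lrr, baf=None, chrom="chr1"):
    n = len(lrr)
    return pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, n + 1) * 1000,
        "lrr": lrr,
        "baf": baf if baf is not None else np.full(n, np.nan),
        "is_het": baf is not None,
    })


class TestComputeLrrBaf:
    def test_equal_depths_give_zero_lrr(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": range(1, 101),
                           "tumor_depth": 80, "tumor_b_reads": 40,
                           "normal_depth": 80, "normal_b_reads": 40})
        out = compute_lrr_baf(df)
        assert np.allclose(out["lrr"], 0.0)
        assert np.allclose(out["baf"], 0.5)
        assert out["is_het"].all()

    def test_hom_sites_not_het(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1, 2],
                           "tumor_depth": [100, 100], "tumor_b_reads": [0, 50],
                           "normal_depth": [100, 100], "normal_b_reads": [2, 50]})
        out = compute_lrr_baf(df)
        assert list(out["is_het"]) == [False, True]

    def test_zero_normal_depth_dropped(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1, 2],
                           "tumor_depth": [100, 100], "tumor_b_reads": [50, 50],
                           "normal_depth": [0, 100], "normal_b_reads": [0, 50]})
        assert len(compute_lrr_baf(df)) == 1

    def test_one_copy_loss_shifts_lrr_by_expected_ratio(self, cna_sim):
        sig = compute_lrr_baf(cna_sim.snp_signals["diagnosis"])
        loss = sig[(sig["chrom"] == "chr2") & (sig["pos"] <= 8_000_000)]
        alpha, psi = 0.8, cna_sim.truth["ploidy"]["diagnosis"]
        expected = np.log2((alpha * 1 + 2 * (1 - alpha))
                           / (alpha * psi + 2 * (1 - alpha)))
        assert loss["lrr"].mean() == pytest.approx(expected, abs=0.1)


class TestCbs:
    def test_constant_signal_has_no_breakpoints(self):
        assert cbs_changepoints(np.zeros(200), FAST_CBS) == []

    def test_pure_noise_has_no_breakpoints(self):
        rng = np.random.default_rng(4)
        assert cbs_changepoints(rng.normal(0, 0.1, 150), FAST_CBS) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_step_found_within_three_snps_of_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(1, 0.1, 100)])
        cuts = cbs_changepoints(x, FAST_CBS)
        oracle = exhaustive_single_changepoint(x)
        assert abs(oracle - 100) <= 3
        assert any(abs(c - oracle) <= 3 for c in cuts)
        assert any(abs(c - 100) <= 3 for c in cuts)

    def test_loss_plus_cnloh_found_including_baf_only_breakpoint(self):
        rng = np.random.default_rng(8)
        n = 300
        lrr = rng.normal(0, 0.15, n)
        lrr[:100] += np.log2(0.5)              # one-copy loss, LRR signal
        baf = rng.normal(0.5, 0.05, n)
        baf[100:200] = rng.normal(0.5, 0.05, 100) + np.where(
            rng.random(100) < 0.5, 0.45, -0.45)  # cn-LOH: BAF-only signal
        segments = segment_profile(snp_frame(lrr, np.clip(baf, 0, 1)), FAST_CBS)
        bounds = sorted(s.start for s in segments)[1:]
        assert any(abs(b - 100_000) <= 4000 for b in bounds)   # LRR breakpoint
        assert any(abs(b - 200_000) <= 4000 for b in bounds)   # BAF-only breakpoint

    def test_short_chromosome_is_single_segment(self):
        segs = segment_profile(snp_frame(np.array([0.0, 1.0, 0.0, 1.0])), FAST_CBS)
        assert len(segs) == 1 and segs[0].n_snps == 4


def seg(lrr, dev, n=50, chrom="chr1", start=1, end=1_000_000):
    return CopyNumberSegment(chrom, start, end, n, lrr, dev)


class TestPloidyPurityFit:
    def test_pure_diploid_with_clonal_loss(self):
        # 80% of SNPs normal (2,1), 20% in a clonal one-copy loss (1,0)
        segs = [seg(0.0, 0.0, n=400),
                seg(np.log2(1 / 1.9), 0.5 / 1.0, n=100, chrom="chr2")]
        fit = fit_ploidy_purity(segs)
        assert fit.purity == pytest.approx(1.0, abs=0.05)
        assert fit.ploidy == pytest.approx(1.9, abs=0.2)
        assign_allele_specific_cn(segs, fit)
        assert (segs[1].cn_total, segs[1].cn_minor) == (1, 0)

    def test_half_normal_contamination_recovered(self, cna_sim):
        segs, fit = call_cna(cna_sim.snp_signals["diagnosis"])
        assert fit.purity == pytest.approx(0.8, abs=0.05)
        assert fit.ploidy == pytest.approx(cna_sim.truth["ploidy"]["diagnosis"],
                                           abs=0.2)

    def test_all_normal_profile_is_ambiguous_at_diploid(self):
        segs = [seg(0.0, 0.0, n=100, chrom=f"chr{i}") for i in range(1, 6)]
        fit = fit_ploidy_purity(segs)
        assert fit.ploidy == pytest.approx(2.0, abs=1e-9)
        assert fit.ambiguous
        assert fit.fit_score == pytest.approx(0.0, abs=1e-12)

    def test_reported_solution_scores_best_within_its_ploidy(self):
        segs = [seg(0.0, 0.0, n=400), seg(-0.8, 0.33, n=100, chrom="chr2")]
        fit = fit_ploidy_purity(segs)
        same_psi = [c for c in fit.candidates if abs(c[1] - fit.ploidy) < 0.3]
        assert all(fit.fit_score <= c[2] + 1e-9 for c in same_psi)


class TestAssignment:
    FIT = PloidyPurityFit(ploidy=2.0, purity=1.0, fit_score=0.0, candidates=[])

    def test_exact_lattice_point_major2_minor1(self):
        s = seg(np.log2(3 / 2), abs(1 - 1.5) / 3)
        assign_allele_specific_cn([s], self.FIT)
        assert (s.cn_total, s.cn_minor) == (3, 1)

    def test_cn_neutral_loh_position(self):
        s = seg(0.0, 0.5)
        assign_allele_specific_cn([s], self.FIT)
        assert (s.cn_total, s.cn_minor) == (2, 0)

    def test_tie_breaks_to_highest_minor(self):
        # equidistant between (2,1) at (0, 0) and (2,0) at (0, 0.5)
        s = seg(0.0, 0.25)
        assign_allele_specific_cn([s], self.FIT)
        assert (s.cn_total, s.cn_minor) == (2, 1)

    def test_outlier_flagged_but_assigned(self):
        s = seg(4.5, 0.1)
        assign_allele_specific_cn([s], self.FIT)
        assert s.outlier and s.cn_total is not None


class TestClassification:
    FIT = PloidyPurityFit(ploidy=2.0, purity=1.0, fit_score=0.0, candidates=[])

    @pytest.mark.parametrize(
        "total,minor,expected",
        [
            (3, 1, {"gain"}),
            (5, 2, {"gain", "high_amplification"}),
            (1, 0, {"loss", "LOH"}),
            (0, 0, {"loss", "homozygous_deletion"}),
            (2, 0, {"LOH", "cn_neutral_LOH"}),
            (2, 1, {"normal"}),
            (4, 2, {"gain"}),          # ploidy+2 is gain but not high-level
        ],
    )
    def test_threshold_rules(self, total, minor, expected):
        s = seg(0.0, 0.0)
        s.cn_total, s.cn_minor = total, minor
        classify_aberrations([s], self.FIT)
        assert s.labels == expected

    def test_invariant_under_b_allele_relabeling(self, cna_sim):
        raw = cna_sim.snp_signals["diagnosis"]
        flipped = raw.assign(
            tumor_b_reads=raw["tumor_depth"] - raw["tumor_b_reads"],
            normal_b_reads=raw["normal_depth"] - raw["normal_b_reads"],
        )
        segs_a, fit_a = call_cna(raw)
        segs_b, fit_b = call_cna(flipped)
        assert (fit_a.purity, fit_a.ploidy) == (fit_b.purity, fit_b.ploidy)
        assert [(s.cn_total, s.cn_minor, sorted(s.labels)) for s in segs_a] \
            == [(s.cn_total, s.cn_minor, sorted(s.labels)) for s in segs_b]


class TestEndToEndRecovery:
    def test_events_recovered_with_correct_labels(self, cna_sim):
        want = {"chr1": ((3, 1), "gain"), "chr2": ((1, 0), "loss"),
                "chr3": ((2, 0), "cn_neutral_LOH")}
        segs, fit = call_cna(cna_sim.snp_signals["diagnosis"])
        for chrom, (state, label) in want.items():
            hits = [s for s in segs
                    if s.chrom == chrom and s.start < 8_000_000 and
                    (s.cn_total, s.cn_minor) == state and label in s.labels]
            assert hits, f"{chrom}: {label} {state} not recovered"
        # falsely aberrant SNPs outside the simulated spans (SNP-weighted,
        # so +-3-SNP breakpoint jitter cannot dominate the rate)
        false = sum(s.n_snps for s in segs if s.labels - {"normal"}
                    and not (s.chrom in want and s.start < 8_000_000))
        assert false / sum(s.n_snps for s in segs) <= 0.05
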