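"""Generator contracts: determinism, binomial read model, truth consistency."""

import numpy as np
import pytest
from scipy import stats

from relapsetrio.simulate import (
    CnaSpec,
    ItdSpec,
    SimulationConfig,
    inject_cn_loh,
    simulate_cohort,
    simulate_trio,
    write_trio_files,
)
from relapsetrio.trio_io import load_trio


class TestConfig:
    def test_linear_mode_forbids_diagnosis_specific(self):
        with pytest.raises(ValueError, match="linear"):
            SimulationConfig(mode="linear", n_diagnosis_specific=2)

    def test_ancestral_mode_caps_shared_passengers(self):
        with pytest.raises(ValueError, match="ancestral"):
            SimulationConfig(mode="ancestral", n_ancestral_passengers=9,
                             n_diagnosis_specific=5)


class TestDeterminism:
    def test_same_seed_same_tables(self):
        cfg = SimulationConfig.for_mode("branched", seed=7, n_germline_snps=100,
                                        n_cna_snps=260,
                                        itd=ItdSpec(carrier_fraction=0.2))
        a, b = simulate_trio(cfg), simulate_trio(cfg)
        for role in a.trio.samples:
            assert a.trio.samples[role].equals(b.trio.samples[role])
        for role in a.snp_signals:
            assert a.snp_signals[role].equals(b.snp_signals[role])
        assert a.truth == b.truth

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig.for_mode("linear", seed=9, n_germline_snps=80,
                                        n_cna_snps=0)
        pa = write_trio_files(simulate_trio(cfg), tmp_path / "a")
        pb = write_trio_files(simulate_trio(cfg), tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_cohort_seeding_reproducible(self):
        a = simulate_cohort((1, 1, 1), seed=3)
        b = simulate_cohort((1, 1, 1), seed=3)
        assert [s.config.seed for s in a] == [s.config.seed for s in b]
        assert [s.truth["mode"] for s in a] == ["linear", "branched", "ancestral"]


class TestReadModel:
    def test_clonal_pure_vaf_matches_binomial_moments(self):
        cfg = SimulationConfig(mode="linear", seed=13, n_germline_snps=0,
                               n_ancestral_passengers=1000,
                               n_relapse_specific=0, n_cna_snps=0,
                               purity_diagnosis=1.0, purity_relapse=1.0)
        sim = simulate_trio(cfg)
        t = sim.trio.samples["diagnosis"]
        vaf = t["alt_reads"] / t["depth"]
        assert vaf.mean() == pytest.approx(0.5, abs=0.01)
        # variance dominated by Binomial(~91, 0.5) sampling
        assert vaf.std() == pytest.approx(np.sqrt(0.25 / 91), rel=0.25)

    def test_alt_reads_consistent_with_binomial_chisquare(self):
        cfg = SimulationConfig(mode="linear", seed=21, n_germline_snps=0,
                               n_ancestral_passengers=1000,
                               n_relapse_specific=0, n_cna_snps=0,
                               purity_diagnosis=1.0, purity_relapse=1.0,
                               error_rate=0.0)
        sim = simulate_trio(cfg)
        t = sim.trio.samples["diagnosis"]
        d = t["depth"].to_numpy()
        k = t["alt_reads"].to_numpy()
        z = (k - d * 0.5) / np.sqrt(d * 0.25)
        stat = float((z**2).sum())
        p = stats.chi2.sf(stat, len(z))
        assert p > 0.01

    def test_remission_carries_only_germline_and_noise(self):
        cfg = SimulationConfig.for_mode("branched", seed=5, n_germline_snps=200,
                                        n_cna_snps=0)
        sim = simulate_trio(cfg)
        rem = sim.trio.samples["remission"].set_index(["chrom", "pos", "ref", "alt"])
        for m in sim.truth["mutations"]:
            row = rem.loc[(m["chrom"], m["pos"], m["ref"], m["alt"])]
            assert row["alt_reads"] / max(row["depth"], 1) < 0.05


class TestCloneStructure:
    def test_ancestral_mode_shares_exactly_the_configured_passengers(self):
        cfg = SimulationConfig.for_mode("ancestral", seed=31,
                                        n_ancestral_passengers=3,
                                        n_germline_snps=50, n_cna_snps=0)
        sim = simulate_trio(cfg)
        shared = [m for m in sim.truth["mutations"] if m["clone"] == "ancestral"]
        assert len(shared) == 3
        for m in shared:
            assert m["ccf"]["diagnosis"] == m["ccf"]["relapse"] == 1.0

    def test_subclone_ccf_propagates_to_truth(self):
        cfg = SimulationConfig.for_mode("branched", seed=2, subclone_ccf=0.4,
                                        n_germline_snps=20, n_cna_snps=0)
        sim = simulate_trio(cfg)
        sub = [m for m in sim.truth["mutations"]
               if m["clone"] == "diagnosis_specific"]
        assert sub and all(m["ccf"]["diagnosis"] == 0.4 for m in sub)


class TestEmittedFiles:
    def test_all_outputs_parse_through_trio_io(self, tmp_path):
        cfg = SimulationConfig.for_mode("branched", seed=19, n_germline_snps=150,
                                        n_cna_snps=130,
                                        itd=ItdSpec(carrier_fraction=0.3))
        paths = write_trio_files(simulate_trio(cfg), tmp_path)
        trio = load_trio("SIM19", paths["diagnosis"], paths["relapse"],
                         paths["baits"], paths["remission"])
        assert trio.has_remission
        from relapsetrio.cna import read_snp_signals
        from relapsetrio.itd import read_mismatch_counts
        assert len(read_snp_signals(paths["snps_diagnosis"])) > 0
        assert len(read_mismatch_counts(paths["itd_diagnosis"])) == 200


class TestCnLohInjection:
    def _sim(self):
        cfg = SimulationConfig.for_mode("linear", seed=37, n_germline_snps=30,
                                        n_cna_snps=0, purity_diagnosis=0.9,
                                        purity_relapse=0.9)
        return simulate_trio(inject_cn_loh(cfg))

    def test_duplicated_allele_vaf_matches_m2_expectation(self):
        sim = self._sim()
        m = next(x for x in sim.truth["mutations"] if x["multiplicity"] == 2)
        t = sim.trio.samples["diagnosis"].set_index(["chrom", "pos", "ref", "alt"])
        row = t.loc[(m["chrom"], m["pos"], m["ref"], m["alt"])]
        # expected VAF = alpha*m*ccf / (alpha*n_t + 2(1-alpha)) = 0.9 here
        vaf = row["alt_reads"] / row["depth"]
        assert vaf == pytest.approx(0.9, abs=3 * np.sqrt(0.09 / 91))

    def test_remission_unaffected_by_injection(self):
        sim = self._sim()
        m = next(x for x in sim.truth["mutations"] if x["multiplicity"] == 2)
        rem = sim.trio.samples["remission"].set_index(["chrom", "pos", "ref", "alt"])
        row = rem.loc[(m["chrom"], m["pos"], m["ref"], m["alt"])]
        assert row["alt_reads"] <= 2

    def test_diagnosis_only_injection_leaves_relapse_diploid(self):
        cfg = SimulationConfig.for_mode("branched", seed=41, n_germline_snps=30,
                                        n_cna_snps=0)
        cfg = inject_cn_loh(cfg, samples=("diagnosis",))
        sim = simulate_trio(cfg)
        states = {tuple(e["samples"]): (e["cn_total"], e["cn_minor"])
                  for e in sim.truth["cna_events"]}
        assert states == {("diagnosis",): (2, 0)}

    def test_injection_without_target_clone_errors(self):
        cfg = SimulationConfig(mode="linear", seed=1, n_ancestral_passengers=0,
                               n_relapse_specific=0, n_germline_snps=10,
                               n_cna_snps=0)
        with pytest.raises(ValueError, match="no mutations"):
            simulate_trio(inject_cn_loh(cfg))


class TestCohort:
    def test_mode_mixture_and_size(self):
        sims = simulate_cohort((2, 1, 1), seed=8)
        assert len(sims) == 4
        modes = [s.truth["mode"] for s in sims]
        assert modes.count("linear") == 2
        assert {s.trio.patient_id for s in sims} == {"P01", "P02", "P03", "P04"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort((0, 0, 0), seed=1)
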