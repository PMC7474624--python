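"""Synthetic generators: determinism, planted structure, statistical calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from straintrack import synth
from straintrack.design import generate_design
from straintrack.errors import InputError
from straintrack.kmers import canonical_kmers
from straintrack.stats import one_way_anova, paired_t_test


class TestGenomes:
    def test_no_shared_kmers_when_shared_fraction_zero(self):
        genomes = synth.simulate_genomes(3, 2000, shared_fraction=0.0, seed=1)
        sets = []
        for g in genomes:
            canon, valid = canonical_kmers(g.sequence, 31)
            sets.append(set(canon[valid].tolist()))
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (sets[i] & sets[j])

    def test_half_shared_fraction_of_kmers(self):
        genomes = synth.simulate_genomes(2, 10_000, shared_fraction=0.5,
                                         n_shared_blocks=1, seed=2)
        a, b = genomes
        ca, va = canonical_kmers(a.sequence, 31)
        cb, vb = canonical_kmers(b.sequence, 31)
        shared = set(ca[va].tolist()) & set(cb[vb].tolist())
        frac = len(shared) / len(set(ca[va].tolist()))
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_deterministic(self):
        g1 = synth.simulate_genomes(3, 1500, 0.2, 1, seed=5)
        g2 = synth.simulate_genomes(3, 1500, 0.2, 1, seed=5)
        assert [g.sequence for g in g1] == [g.sequence for g in g2]

    def test_exact_lengths(self):
        for g in synth.simulate_genomes(4, 3333, 0.25, 3, seed=6):
            assert g.length == 3333

    def test_infeasible_parameters(self):
        with pytest.raises(InputError):
            synth.simulate_genomes(2, 1000, shared_fraction=1.0, seed=0)
        with pytest.raises(InputError):
            synth.simulate_genomes(1, 1000, shared_fraction=0.5, seed=0)
        with pytest.raises(InputError):
            synth.simulate_genomes(2, 100, seed=0)  # < 10k


class TestReads:
    def test_single_strain_truth_labels(self):
        genomes = synth.simulate_genomes(2, 2000, seed=1)
        reads, truth = synth.simulate_reads(genomes, {genomes[0].strain_id: 1.0},
                                            300, 100, 0.0, seed=2)
        assert set(truth.read_sources) == {genomes[0].strain_id}

    def test_equal_mixture_counts_within_binomial_interval(self):
        genomes = synth.simulate_genomes(2, 5000, seed=3)
        comp = {g.strain_id: 0.5 for g in genomes}
        n = 100_000
        reads, truth = synth.simulate_reads(genomes, comp, n, 150, 0.0, seed=4)
        k = (truth.read_sources == genomes[0].strain_id).sum()
        lo, hi = sps.binom.interval(0.99, n, 0.5)
        assert lo <= k <= hi

    def test_length_weighting(self):
        """Read share follows composition x genome length, not composition alone."""
        long = synth.simulate_genomes(1, 40_000, seed=5)[0]
        short = synth.simulate_genomes(1, 10_000, seed=6)[0]
        long.strain_id, short.strain_id = "long", "short"
        reads, truth = synth.simulate_reads([long, short], {"long": 0.5, "short": 0.5},
                                            20_000, 150, 0.0, seed=7)
        frac_long = (truth.read_sources == "long").mean()
        assert frac_long == pytest.approx(0.8, abs=0.02)

    def test_deterministic_fastq(self, tmp_path):
        from straintrack.quant import write_fastq
        genomes = synth.simulate_genomes(2, 2000, seed=8)
        comp = {g.strain_id: 0.5 for g in genomes}
        for i in (1, 2):
            reads, _ = synth.simulate_reads(genomes, comp, 100, 80, 0.01, seed=9)
            write_fastq(reads, tmp_path / f"run{i}.fastq")
        assert (tmp_path / "run1.fastq").read_bytes() == (tmp_path / "run2.fastq").read_bytes()

    def test_error_rate_realized(self):
        genomes = synth.simulate_genomes(1, 5000, seed=10)
        clean, _ = synth.simulate_reads(genomes, {genomes[0].strain_id: 1.0},
                                        2000, 100, 0.0, seed=11)
        noisy, _ = synth.simulate_reads(genomes, {genomes[0].strain_id: 1.0},
                                        2000, 100, 0.02, seed=11)
        diff = sum(a != b for (_, s1, _), (_, s2, _) in zip(clean.reads, noisy.reads)
                   for a, b in zip(s1, s2))
        rate = diff / (2000 * 100)
        assert rate == pytest.approx(0.02, abs=0.003)

    def test_validation(self):
        genomes = synth.simulate_genomes(2, 2000, seed=12)
        with pytest.raises(InputError):
            synth.simulate_reads(genomes, {"nope": 1.0}, 10, 100, 0.0, 0)
        with pytest.raises(InputError):
            synth.simulate_reads(genomes, {genomes[0].strain_id: 1.0}, 10, 3000, 0.0, 0)
        with pytest.raises(InputError):
            synth.simulate_reads(genomes, {genomes[0].strain_id: 1.0}, 10, 100, 0.3, 0)


class TestPhenotypes:
    @staticmethod
    def design():
        return generate_design(8, 2, 2, seed=0)

    def test_deterministic_linear_predictor_at_tiny_sigma(self):
        dm = self.design()
        causal = {dm.X.columns[0]: 7.0}
        table, _ = synth.simulate_phenotypes(dm, causal, baseline=10, sigma=1e-9,
                                             mice_per_group=1, seed=1)
        for _, row in table.iterrows():
            expected = 10 + 7.0 * dm.X.loc[row.community_id, dm.X.columns[0]]
            assert row.value == pytest.approx(expected, abs=1e-6)

    def test_planted_gap_recovered(self):
        dm = self.design()
        sid = dm.X.columns[0]
        table, _ = synth.simulate_phenotypes(dm, {sid: 10.0}, baseline=10, sigma=2,
                                             mice_per_group=8, seed=2)
        with_comm = set(dm.X.index[dm.X[sid] == 1])
        w = table[table.community_id.isin(with_comm)]["value"]
        wo = table[~table.community_id.isin(with_comm)]["value"]
        n = min(len(w), len(wo))
        assert abs((w.mean() - wo.mean()) - 10.0) < 3 * 2 / np.sqrt(n)

    def test_null_anova_type_i_error_calibrated(self):
        """All effects zero: community ANOVA rejects at ~5% over 200 seeds."""
        dm = self.design()
        rejections = 0
        for seed in range(200):
            table, _ = synth.simulate_phenotypes(dm, {}, baseline=20, sigma=3,
                                                 mice_per_group=3, seed=seed)
            groups = [sub["value"].to_numpy() for _, sub in table.groupby("community_id")]
            rejections += one_way_anova(groups).p_value < 0.05
        # 3 sigma binomial band around 0.05
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / 200) <= rejections / 200 \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_clipping_to_percentage_range(self):
        dm = self.design()
        table, truth = synth.simulate_phenotypes(dm, {}, baseline=99, sigma=5,
                                                 mice_per_group=10, seed=3)
        assert table["value"].max() <= 100.0
        assert truth.extras["n_clipped"] > 0

    def test_unknown_strain_rejected(self):
        with pytest.raises(InputError):
            synth.simulate_phenotypes(self.design(), {"ghost": 1.0}, seed=0)


class TestDensity:
    def test_deterministic(self):
        a, _ = synth.simulate_density(6, 6, 5.0, 2.0, 0.3, seed=4)
        b, _ = synth.simulate_density(6, 6, 5.0, 2.0, 0.3, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_density_is_exact_quotient(self):
        table, _ = synth.simulate_density(5, 5, 5.0, 1.0, 0.2, seed=5)
        np.testing.assert_allclose(table["density_ng_per_mg"],
                                   table["dna_mass_ng"] / table["fecal_mass_mg"])

    def test_null_shift_paired_p_calibrated(self):
        rejections = 0
        for seed in range(100):
            table, _ = synth.simulate_density(8, 8, 5.0, 0.0, 0.3, seed=seed)
            wide = table.pivot(index="mouse_id", columns="timepoint",
                               values="density_ng_per_mg")
            rejections += paired_t_test(wide["pre"], wide["post"]).p_value < 0.05
        assert rejections / 100 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)

    def test_large_shift_detected_with_power(self):
        detected = 0
        for seed in range(100):
            table, _ = synth.simulate_density(8, 8, 5.0, 5.0, 0.3, seed=seed)
            wide = table.pivot(index="mouse_id", columns="timepoint",
                               values="density_ng_per_mg")
            detected += paired_t_test(wide["pre"], wide["post"]).p_value < 0.05
        assert detected >= 95

    def test_validation(self):
        with pytest.raises(InputError):
            synth.simulate_density(5, 5, -1.0, 0.0, 0.3, 0)
        with pytest.raises(InputError):
            synth.simulate_density(5, 5, 5.0, 0.0, -0.3, 0)


class TestTransplantCohort:
    def test_planted_rates_recovered(self):
        from straintrack.engraftment import cohort_metrics
        presence, metadata, consortia = synth.simulate_transplant_cohort(
            {"R1": 17, "R2": 13, "R3": 20}, {"D1": 9, "D2": 13, "D3": 16, "D4": 18, "D5": 22},
            mice_per_pair=3, engraft_p=0.6, persist_p=0.55, seed=6)
        per_mouse = cohort_metrics(presence, metadata, consortia)
        assert per_mouse["engraftment_fraction"].mean() == pytest.approx(0.6, abs=0.05)
        assert per_mouse["persistence_fraction"].mean() == pytest.approx(0.55, abs=0.05)

    def test_pre_presence_is_recipient_consortium(self):
        presence, metadata, consortia = synth.simulate_transplant_cohort(
            {"R1": 5}, {"D1": 4}, mice_per_pair=2, seed=7)
        pre = presence.xs("pre", level="timepoint")
        for mouse, row in pre.iterrows():
            assert set(row.index[row]) == consortia["R1"]
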