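"""Synthetic genotype generator: frequency model, Hardy-Weinberg sampling, truth."""

import numpy as np
import pytest

import aimsel
from aimsel.io import MISSING
from aimsel.simulate import (
    PopulationSpec,
    SimulationConfig,
    draw_allele_frequencies,
    simulate_genotypes,
)


def two_pop_config(**kw):
    defaults = dict(
        populations=[PopulationSpec("A", 30, 0), PopulationSpec("B", 30, 1)],
        n_snps=50,
        n_aims=10,
        aim_divergence=0.5,
        neutral_divergence=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_empty_population_list_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(populations=[], n_snps=10, n_aims=1)

    @pytest.mark.parametrize(
        "kw",
        [
            {"aim_divergence": 0.0},
            {"aim_divergence": 1.0},
            {"neutral_divergence": 0.6, "aim_divergence": 0.5},
            {"n_aims": 100, "n_snps": 50},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.7)},
            {"missing_rate": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            two_pop_config(**kw)

    def test_admixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PopulationSpec("X", 10, {0: 0.5, 1: 0.4})
        with pytest.raises(ValueError, match="negative"):
            PopulationSpec("X", 10, {0: 1.5, 1: -0.5})


class TestFrequencyModel:
    def test_zero_divergence_shares_ancestral_frequency(self):
        cfg = two_pop_config(neutral_divergence=0.0)
        fr = draw_allele_frequencies(cfg)
        neutral = ~fr.aim_mask
        np.testing.assert_array_equal(fr.lineage_freq[0][neutral], fr.ancestral_p[neutral])
        np.testing.assert_array_equal(fr.lineage_freq[1][neutral], fr.ancestral_p[neutral])

    def test_even_admixture_is_the_mean_of_parents(self):
        cfg = two_pop_config()
        cfg.populations.append(PopulationSpec("MIX", 10, {0: 0.5, 1: 0.5}))
        fr = draw_allele_frequencies(cfg)
        np.testing.assert_allclose(
            fr.population_freq[2],
            0.5 * (fr.lineage_freq[0] + fr.lineage_freq[1]),
            atol=1e-12,
        )

    def test_balding_nichols_variance_matches_F_p_1mp(self):
        # Monte-Carlo: var of the per-lineage frequency around p is F*p*(1-p).
        F = 0.5
        cfg = SimulationConfig(
            populations=[PopulationSpec("A", 5, 0)],
            n_snps=10_000,
            n_aims=10_000,
            aim_divergence=F,
            neutral_divergence=0.0,
            maf_range=(0.2, 0.5),
            seed=7,
        )
        fr = draw_allele_frequencies(cfg)
        dev2 = (fr.lineage_freq[0] - fr.ancestral_p) ** 2
        expected = F * fr.ancestral_p * (1 - fr.ancestral_p)
        ratio = dev2.mean() / expected.mean()
        assert abs(ratio - 1) < 0.05

    def test_deterministic_given_seed(self):
        cfg = two_pop_config(missing_rate=0.05)
        d1 = simulate_genotypes(cfg)
        d2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(d1.genotypes.values, d2.genotypes.values)
        np.testing.assert_array_equal(d1.truth_aims, d2.truth_aims)
        assert d1.freq_table.equals(d2.freq_table)


class TestGenotypeSampling:
    def test_no_missing_when_rate_zero(self):
        ds = simulate_genotypes(two_pop_config(missing_rate=0.0))
        assert (ds.genotypes.values != MISSING).all()

    def test_missingness_present_at_positive_rate(self):
        ds = simulate_genotypes(two_pop_config(missing_rate=0.2, seed=5))
        frac = (ds.genotypes.values == MISSING).mean()
        assert 0.1 < frac < 0.3

    def test_near_zero_frequency_gives_near_constant_genotypes(self):
        # Hardy-Weinberg limit: where a population's true frequency f is tiny,
        # genotypes are almost all homozygous-major (P(0) = (1-f)^2).
        cfg = two_pop_config(aim_mode="cluster", cluster_low=0.05, cluster_high=0.95)
        ds = simulate_genotypes(cfg)
        vals = ds.genotypes.values
        checked = 0
        for g in ("A", "B"):
            rows = ds.labels == g
            low = ds.freq_table.loc[g].to_numpy() <= 0.08
            if low.any():
                block = vals[np.ix_(rows, low)]
                assert (block == 0).mean() > 0.75
                assert (block == 2).mean() < 0.05
                checked += 1
        assert checked > 0

    def test_mean_genotype_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("A", 1000, 0)],
            n_snps=5,
            n_aims=0,
            aim_divergence=0.5,
            neutral_divergence=0.0,
            maf_range=(0.5, 0.5),
            seed=9,
        )
        ds = simulate_genotypes(cfg)
        se = np.sqrt(2 * 0.25 / 1000)
        means = ds.genotypes.values.mean(axis=0)
        assert (np.abs(means - 1.0) < 3 * se).all()

    def test_label_multiset_and_truth_mask(self):
        ds = simulate_genotypes(two_pop_config())
        assert (ds.labels == "A").sum() == 30
        assert (ds.labels == "B").sum() == 30
        assert ds.truth_aims.sum() == 10
        assert ((ds.freq_table.to_numpy() >= 0) & (ds.freq_table.to_numpy() <= 1)).all()

    def test_minor_allele_coding_frequency_at_most_half(self):
        ds = simulate_genotypes(two_pop_config(seed=13, maf_range=(0.4, 0.5)))
        vals = ds.genotypes.values
        freq = vals.sum(axis=0) / (2.0 * vals.shape[0])
        assert (freq <= 0.5 + 1e-12).all()

    def test_empirical_frequency_recovers_truth_table(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec("A", 1000, 0)],
            n_snps=200,
            n_aims=50,
            aim_divergence=0.5,
            neutral_divergence=0.01,
            seed=21,
        )
        ds = simulate_genotypes(cfg)
        emp = ds.genotypes.values.mean(axis=0) / 2.0
        truth = ds.freq_table.loc["A"].to_numpy()
        se = np.sqrt(truth * (1 - truth) / (2 * 1000)) + 1e-9
        assert (np.abs(emp - truth) < 5 * se + 0.005).all()


class TestWriteDataset:
    def test_files_line_counts_and_roundtrip(self, tmp_path):
        cfg = SimulationConfig(
            populations=[PopulationSpec("A", 2, 0)],
            n_snps=3,
            n_aims=1,
            aim_divergence=0.5,
            neutral_divergence=0.01,
            seed=2,
        )
        ds = simulate_genotypes(cfg)
        paths = aimsel.write_dataset(ds, tmp_path / "toy")
        assert len((paths["map"]).read_text().splitlines()) == 3
        assert len((paths["ped"]).read_text().splitlines()) == 2
        samples, variants, pairs = aimsel.read_ped_map(paths["ped"], paths["map"])
        back = aimsel.recode_additive(samples, variants, pairs)
        np.testing.assert_array_equal(back.values, ds.genotypes.values)

    def test_heterozygote_writes_one_of_each_allele(self, tmp_path):
        cfg = two_pop_config(missing_rate=0.0, seed=17)
        ds = simulate_genotypes(cfg)
        paths = aimsel.write_dataset(ds, tmp_path / "het")
        _, _, pairs = aimsel.read_ped_map(paths["ped"], paths["map"])
        het = np.argwhere(ds.genotypes.values == 1)
        assert len(het) > 0
        for i, j in het[:20]:
            assert sorted(pairs[i, j]) == ["A", "G"]

    def test_roundtrip_with_missing_calls(self, tmp_path):
        ds = simulate_genotypes(two_pop_config(missing_rate=0.1, seed=23))
        paths = aimsel.write_dataset(ds, tmp_path / "miss")
        samples, variants, pairs = aimsel.read_ped_map(paths["ped"], paths["map"])
        back = aimsel.recode_additive(samples, variants, pairs)
        orig = ds.genotypes.values
        nonmiss = orig != MISSING
        np.testing.assert_array_equal(back.values[nonmiss], orig[nonmiss])
        np.testing.assert_array_equal(back.values == MISSING, ~nonmiss)
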