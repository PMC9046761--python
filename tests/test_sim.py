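"""Generator correctness: drift-tree limits, Balding–Nichols variance,
mosaic copying process, determinism."""

import numpy as np
import pytest

from admixscan.sim import (DemographySpec, MosaicSpec, sample_genotypes,
                           simulate_mosaic_panel, simulate_tree_frequencies,
                           simulate_tree_panel, write_panel)


class TestTreeFrequencies:
    def test_no_drift_no_admixture_limit(self):
        spec = DemographySpec.uniform_drift(1e-7, n_sites=500, seed=3)
        freqs, truth = simulate_tree_frequencies(spec)
        for pop in freqs:
            assert np.allclose(freqs[pop], truth.ancestral_freq, atol=0.01)

    def test_full_replacement_recipient_premix_equals_donor(self):
        spec = DemographySpec.uniform_drift(0.1, n_sites=200, alpha=1.0, seed=4)
        freqs, truth = simulate_tree_frequencies(spec)
        assert np.array_equal(truth.recipient_premix, freqs["P3"])

    def test_drift_variance_matches_balding_nichols(self):
        # Var(p_child | parent p) = F p (1-p): compare the recipient's
        # squared deviation from its pre-drift mixture to the closed form
        spec = DemographySpec.uniform_drift(
            0.05, n_sites=100_000, alpha=0.3, seed=5)
        freqs, truth = simulate_tree_frequencies(spec)
        m = truth.recipient_premix
        observed = np.mean((freqs["P2"] - m) ** 2)
        expected = np.mean(0.05 * m * (1 - m))
        assert observed == pytest.approx(expected, rel=0.05)

    def test_sister_populations_exchangeable_without_admixture(self):
        spec = DemographySpec.uniform_drift(0.1, n_sites=50_000, seed=6)
        freqs, _ = simulate_tree_frequencies(spec)
        diff = freqs["P1"] - freqs["P2"]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_degenerate_drift_rejected(self, bad):
        with pytest.raises(ValueError):
            DemographySpec.uniform_drift(bad, n_sites=10)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DemographySpec.uniform_drift(0.05, alpha=1.5)


class TestSampleGenotypes:
    def test_fixed_frequencies_give_fixed_genotypes(self):
        freqs = {"A": np.zeros(50), "B": np.ones(50)}
        gm, panel = sample_genotypes(freqs, 10, seed=7)
        a = panel.indices_in(gm, "A")
        b = panel.indices_in(gm, "B")
        assert (gm.dosage[:, a] == 0).all()
        assert (gm.dosage[:, b] == 2).all()

    def test_heterozygosity_at_half(self):
        freqs = {"A": np.full(10_000, 0.5)}
        gm, _ = sample_genotypes(freqs, 50, seed=8)
        het = (gm.dosage == 1).mean()
        se = np.sqrt(0.25 / gm.dosage.size)
        assert abs(het - 0.5) < 3 * se

    def test_missingness_applied(self):
        freqs = {"A": np.full(2_000, 0.5)}
        gm, _ = sample_genotypes(freqs, 20, missing_rate=0.1, seed=9)
        miss = (gm.dosage == -1).mean()
        assert 0.05 < miss < 0.15

    def test_qual_mixture_straddles_filter_threshold(self):
        freqs = {"A": np.full(2_000, 0.5)}
        gm, _ = sample_genotypes(freqs, 5, seed=10)
        assert (gm.qual < 20).any() and (gm.qual > 20).any()


class TestMosaic:
    def test_planted_tract_fully_homozygous_without_error(self):
        spec = MosaicSpec(length=1_000_000, site_density=1e-3, n_samples=5,
                          k_founders=10, rho=1e-5, error_rate=0.0,
                          tracts=[(2, 200_001, 800_000)], seed=11)
        haps, gm, truth = simulate_mosaic_panel(spec)
        inside = (gm.positions >= 200_001) & (gm.positions <= 800_000)
        assert np.isin(gm.dosage[inside, 2], [0, 2]).all()

    def test_no_switching_copies_whole_founders(self):
        spec = MosaicSpec(length=100_000, site_density=1e-3, n_samples=4,
                          k_founders=5, rho=0.0, seed=12)
        _, _, truth = simulate_mosaic_panel(spec)
        assert (truth.founder_paths == truth.founder_paths[:, :1]).all()

    def test_switch_count_matches_copying_rate(self):
        # founder id changes ~ Binomial(sum over steps of p_switch*(K-1)/K)
        spec = MosaicSpec(length=2_000_000, site_density=1e-3, n_samples=40,
                          k_founders=10, rho=1e-5, seed=13)
        _, _, truth = simulate_mosaic_panel(spec)
        d = np.diff(truth.positions)
        p = (1 - np.exp(-spec.rho * d)) * (spec.k_founders - 1) / spec.k_founders
        n_hap = 2 * spec.n_samples
        expected = n_hap * p.sum()
        observed = (np.diff(truth.founder_paths, axis=1) != 0).sum()
        sd = np.sqrt(n_hap * (p * (1 - p)).sum())
        assert abs(observed - expected) < 4 * sd

    def test_tract_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            MosaicSpec(length=1000, tracts=[(0, 500, 2000)])

    def test_overlapping_tracts_rejected(self):
        with pytest.raises(ValueError):
            MosaicSpec(length=10_000, tracts=[(0, 100, 500), (0, 400, 900)])


class TestDeterminism:
    def test_tree_panel_serialization_byte_identical(self, tmp_path):
        spec = DemographySpec.uniform_drift(0.05, n_sites=300,
                                            samples_per_pop=5, seed=14)
        outputs = []
        for d in ("a", "b"):
            gm, panel, truth = simulate_tree_panel(spec)
            write_panel(gm, panel, truth, tmp_path / d)
            outputs.append({p.name: p.read_bytes()
                            for p in sorted((tmp_path / d).iterdir())})
        assert outputs[0] == outputs[1]

    def test_mosaic_deterministic_given_seed(self):
        spec = MosaicSpec(length=200_000, site_density=1e-3, n_samples=3,
                          seed=15)
        h1, gm1, _ = simulate_mosaic_panel(spec)
        h2, gm2, _ = simulate_mosaic_panel(spec)
        assert np.array_equal(h1, h2)
        assert np.array_equal(gm1.dosage, gm2.dosage)
        assert np.array_equal(gm1.positions, gm2.positions)
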