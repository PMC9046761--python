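"""ABBA-BABA machinery: site patterns, D, jackknife, f-hat, polarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from admixscan.core import PopulationPanel
from admixscan.dstat import (SitePatternCounts, admixture_fraction,
                             block_jackknife, block_pattern_counts,
                             d_statistic, polarize, run_trio,
                             site_pattern_terms, split_half_fhat)
from admixscan.sim import DemographySpec, simulate_tree_panel

from conftest import make_gm


class TestSitePatterns:
    @pytest.mark.parametrize("p,expected", [
        ((0, 1, 1, 0), (1.0, 0.0)),   # pure ABBA
        ((1, 0, 1, 0), (0.0, 1.0)),   # pure BABA
    ])
    def test_pure_patterns(self, p, expected):
        assert site_pattern_terms(*p) == expected

    def test_equal_ingroup_frequencies_balance(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        p3, p4 = rng.random(100), rng.random(100)
        abba, baba = site_pattern_terms(p, p, p3, p4)
        assert np.allclose(abba, baba)


class TestDStatistic:
    def _counts(self, abba, baba):
        m = len(abba)
        return SitePatternCounts(
            abba=np.asarray(abba, float), baba=np.asarray(baba, float),
            n_sites=np.ones(m, int), block_start=np.arange(m),
            block_end=np.arange(m))

    def test_ratio_of_sums(self):
        assert d_statistic(self._counts([30], [10])) == pytest.approx(0.5)

    def test_antisymmetric_in_p1_p2(self):
        rng = np.random.default_rng(2)
        p1, p2, p3, p4 = (rng.random(500) for _ in range(4))
        c12 = block_pattern_counts(p1, p2, p3, p4, n_blocks=5)
        c21 = block_pattern_counts(p2, p1, p3, p4, n_blocks=5)
        assert d_statistic(c12) == pytest.approx(-d_statistic(c21))

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning, match="denominator"):
            assert np.isnan(d_statistic(self._counts([0.0], [0.0])))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (40, 4),
                      elements=st.floats(0, 1, allow_nan=False)))
    def test_d_bounded_by_one(self, freqs):
        c = block_pattern_counts(freqs[:, 0], freqs[:, 1], freqs[:, 2],
                                 freqs[:, 3], n_blocks=4)
        d = d_statistic(c)
        if not np.isnan(d):
            assert -1.0 <= d <= 1.0


class TestBlockJackknife:
    def test_two_block_hand_oracle(self):
        # blocks (30,10) and (10,30): delete-one estimates are -0.5 and
        # +0.5, so SE = sqrt((1/2) * (0.25+0.25)) = 0.5 and D = Z = 0
        c = SitePatternCounts(
            abba=np.array([30.0, 10.0]), baba=np.array([10.0, 30.0]),
            n_sites=np.array([1, 1]), block_start=np.array([0, 1]),
            block_end=np.array([0, 1]))
        se, z = block_jackknife(c)
        assert se == pytest.approx(0.5)
        assert z == pytest.approx(0.0)

    def test_identical_blocks_zero_se(self):
        c = SitePatternCounts(
            abba=np.full(5, 30.0), baba=np.full(5, 10.0),
            n_sites=np.ones(5, int), block_start=np.arange(5),
            block_end=np.arange(5))
        with pytest.warns(UserWarning, match="variance"):
            se, z = block_jackknife(c)
        assert se == 0.0
        assert np.isnan(z)

    def test_degenerate_blocks_merge_then_error(self):
        # one block holds everything: its removal zeroes the denominator,
        # merging collapses to a single block, which cannot be resampled
        c = SitePatternCounts(
            abba=np.array([40.0, 0.0]), baba=np.array([40.0, 0.0]),
            n_sites=np.array([2, 0]), block_start=np.array([0, 1]),
            block_end=np.array([0, 1]))
        with pytest.warns(UserWarning, match="merged"):
            with pytest.raises(ValueError, match="blocks"):
                block_jackknife(c)


class TestFhat:
    def test_p2_equals_p3_gives_unit_fraction(self):
        rng = np.random.default_rng(3)
        p1, p3, p4 = rng.random(300), rng.random(300), rng.random(300) * 0.2
        c = block_pattern_counts(p1, p3, p3, p4, n_blocks=3)
        assert admixture_fraction(c) == pytest.approx(1.0)

    def test_split_half_matches_alpha(self):
        spec = DemographySpec.uniform_drift(
            0.05, n_sites=50_000, samples_per_pop=25, alpha=0.3, seed=41)
        gm, panel, _ = simulate_tree_panel(spec)
        fh = split_half_fhat(gm, panel, "P1", "P2", "P3", "O", seed=5)
        assert fh == pytest.approx(0.3, abs=0.08)


class TestPolarize:
    def test_outgroup_fixed_ref_derived_is_alt(self):
        gm = make_gm([[2, 1, 0, 0], [0, 1, 0, 0]])
        panel = PopulationPanel({"S0": "A", "S1": "A", "S2": "Out", "S3": "Out"})
        freqs, kept, dropped = polarize(gm, panel, ["A"], "Out")
        assert dropped == 0
        assert np.allclose(freqs["A"], [0.75, 0.25])

    def test_outgroup_fixed_alt_derived_is_ref(self):
        gm = make_gm([[2, 1, 2, 2]])
        panel = PopulationPanel({"S0": "A", "S1": "A", "S2": "Out", "S3": "Out"})
        freqs, _, _ = polarize(gm, panel, ["A"], "Out")
        assert freqs["A"][0] == pytest.approx(1 - 0.75)

    def test_outgroup_all_missing_site_dropped(self):
        gm = make_gm([[1, 1, -1, -1], [1, 1, 0, 0]])
        panel = PopulationPanel({"S0": "A", "S1": "A", "S2": "Out", "S3": "Out"})
        freqs, kept, dropped = polarize(gm, panel, ["A"], "Out")
        assert dropped == 1
        assert list(kept) == [1]

    def test_mismatch_rate_bounded_by_outgroup_drift(self, small_tree_panel):
        gm, panel, truth = small_tree_panel
        out_idx = panel.indices_in(gm, "O")
        alt_f = gm.alt_frequency(out_idx)
        called = ~np.isnan(alt_f)
        ancestral_call = np.where(alt_f[called] > 0.5, "ALT", "REF")
        mismatch = np.mean(ancestral_call != truth.ancestral_allele[called])
        # Monte-Carlo oracle: chance a drifted+sampled outgroup major
        # allele differs from the ancestral major allele at F = 0.05
        rng = np.random.default_rng(99)
        p0 = rng.uniform(0.05, 0.95, 50_000)
        th = (1 - 0.05) / 0.05
        p_out = rng.beta(p0 * th, (1 - p0) * th)
        p_hat = rng.binomial(2 * 15, p_out) / (2 * 15)
        oracle = np.mean((p_hat > 0.5) != (p0 > 0.5))
        assert mismatch <= oracle + 3 * np.sqrt(oracle * (1 - oracle) / called.sum())


class TestRunTrio:
    def test_reversing_p1_p2_flips_d_and_z(self, small_tree_panel):
        gm, panel, _ = small_tree_panel
        r12 = run_trio(gm, panel, "P1", "P2", "P3", "O", n_blocks=10)
        r21 = run_trio(gm, panel, "P2", "P1", "P3", "O", n_blocks=10)
        assert r12.d == pytest.approx(-r21.d)
        assert r12.z == pytest.approx(-r21.z)
        assert r12.se == pytest.approx(r21.se)

    def test_d_invariant_to_duplicating_samples(self, small_tree_panel):
        gm, panel, _ = small_tree_panel
        doubled = gm.take_samples(list(range(gm.n_samples)) * 2)
        doubled.samples = [f"{s}_{i}" for i, s in enumerate(doubled.samples)]
        panel2 = PopulationPanel({f"{s}_{i}": panel.membership[s]
                                  for i, s in enumerate(gm.samples * 2)})
        r1 = run_trio(gm, panel, "P1", "P2", "P3", "O", n_blocks=10)
        r2 = run_trio(doubled, panel2, "P1", "P2", "P3", "O", n_blocks=10)
        assert r2.d == pytest.approx(r1.d, abs=1e-12)

    def test_mean_d_and_fhat_increase_with_alpha(self):
        ds, fs = [], []
        for alpha in (0.0, 0.2, 0.4):
            spec = DemographySpec.uniform_drift(
                0.05, n_sites=30_000, samples_per_pop=25, alpha=alpha,
                seed=51)
            gm, panel, _ = simulate_tree_panel(spec)
            r = run_trio(gm, panel, "P1", "P2", "P3", "O", n_blocks=20)
            ds.append(r.d)
            fs.append(r.fhat)
        assert ds[0] < ds[1] < ds[2]
        assert fs[0] < fs[1] < fs[2]

    def test_missing_trio_population_errors(self, small_tree_panel):
        gm, panel, _ = small_tree_panel
        with pytest.raises(KeyError):
            run_trio(gm, panel, "P1", "P2", "NOPE", "O")
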