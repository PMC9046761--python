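"""ROH HMM: emission table, Viterbi against exhaustive enumeration,
segment bookkeeping and FROH definition."""

import numpy as np
import pandas as pd
import pytest

from admixscan.benchmarks import _viterbi_brute_force
from admixscan.roh import (AZ_STATE, HW_STATE, detect_roh,
                           emission_likelihoods, segments_from_path,
                           summarize, viterbi_decode)
from admixscan.sim import MosaicSpec, simulate_mosaic_panel


class TestEmissions:
    def test_full_table_hand_evaluated(self):
        # f=0.2, eps=0.01: HW row (1-f)^2, 2f(1-f), f^2; autozygous row
        # (1-f)(1-eps), eps, f(1-eps)
        lik = emission_likelihoods([0, 1, 2], np.full(3, 0.2), 0.01)
        assert np.allclose(lik[:, 0], [0.64, 0.32, 0.04])
        assert np.allclose(lik[:, 1], [0.792, 0.01, 0.198])

    def test_heterozygote_impossible_when_autozygous_without_error(self):
        lik = emission_likelihoods([1], [0.5], 0.0)
        assert lik[0, 1] == 0.0

    def test_hom_alt_at_half_frequency(self):
        lik = emission_likelihoods([2], [0.5], 0.0)
        assert lik[0, 0] == pytest.approx(0.25)
        assert lik[0, 1] == pytest.approx(0.5)

    def test_missing_genotype_uninformative(self):
        lik = emission_likelihoods([-1], [0.3], 0.01)
        assert np.allclose(lik[0], [1.0, 1.0])

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            emission_likelihoods([0], [0.0], 0.01)


class TestViterbi:
    def test_all_heterozygous_decodes_non_autozygous(self):
        g = np.ones(50, dtype=int)
        lik = emission_likelihoods(g, np.full(50, 0.5), 0.0)
        path = viterbi_decode(lik, np.arange(1, 51) * 1000)
        assert (path == HW_STATE).all()

    def test_homozygous_stretch_decoded_autozygous(self):
        # het-rich flanks, long homozygous interior
        g = np.array([1, 1] + [0, 2, 0, 2, 0, 2, 0, 2, 0, 2, 0, 0] + [1, 1])
        f = np.full(len(g), 0.5)
        pos = np.arange(1, len(g) + 1) * 50_000
        lik = emission_likelihoods(g, f, 0.001)
        t = 1e-6
        path = viterbi_decode(lik, pos, t)
        assert np.array_equal(path, _viterbi_brute_force(lik, pos, t))
        assert (path[2:14] == AZ_STATE).all()
        assert (path[:2] == HW_STATE).all() and (path[14:] == HW_STATE).all()

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = 10
            f = rng.uniform(0.05, 0.95, n)
            g = rng.integers(0, 3, n)
            pos = np.sort(rng.choice(np.arange(1, 5000), n, replace=False))
            eps = rng.uniform(0.001, 0.05)
            t = 10 ** rng.uniform(-6, -3)
            lik = emission_likelihoods(g, f, eps)
            assert np.array_equal(viterbi_decode(lik, pos, t),
                                  _viterbi_brute_force(lik, pos, t))


class TestSegmentsAndSummary:
    def test_segment_boundaries_at_supporting_sites(self):
        path = np.array([0, 1, 1, 1, 0, 1, 0])
        pos = np.array([100, 200, 300, 400, 500, 600, 700])
        seg = segments_from_path(path, pos, "s", "chr1")
        assert len(seg) == 2
        assert list(seg["START"]) == [200, 600]
        assert list(seg["END"]) == [400, 600]
        assert list(seg["NSITES"]) == [3, 1]

    def test_froh_counts_only_runs_over_50kb(self):
        seg = pd.DataFrame({
            "SAMPLE": ["s"] * 3, "CHROM": ["c"] * 3,
            "START": [1, 100_000, 300_000],
            "END": [40_000, 150_000, 360_000],
            "LENGTH_BP": [40_000, 50_000, 60_001],
            "NSITES": [10, 10, 10],
        })
        out = summarize(seg, genome_length=1_000_000)
        row = out.iloc[0]
        assert row["NROH"] == 3
        assert row["SROH"] == 150_001
        assert row["FROH"] == pytest.approx(60_001 / 1_000_000)
        assert row["N_LT_500KB"] == 3
        assert row["N_GE_50KB"] == 2
        assert row["N_GE_1MB"] == 0

    def test_no_segments_all_zero(self):
        seg = segments_from_path([], [], "s", "c")
        out = summarize(seg, genome_length=1_000, samples=["s"])
        assert out.iloc[0][["NROH", "SROH", "FROH"]].tolist() == [0, 0, 0.0]

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            summarize(segments_from_path([], [], "s", "c"), genome_length=0)


@pytest.fixture(scope="module")
def mosaic():
    spec = MosaicSpec(length=3_000_000, site_density=1e-3, n_samples=10,
                      k_founders=30, rho=1e-5, error_rate=0.005,
                      tracts=[(0, 1_000_001, 2_500_000)], seed=77)
    _, gm, truth = simulate_mosaic_panel(spec)
    return gm, truth


class TestDetect:
    def test_segments_sorted_disjoint_within_bounds(self, mosaic):
        gm, _ = mosaic
        scan = detect_roh(gm, error_rate=0.005)
        for _, seg in scan.segments.groupby("SAMPLE"):
            assert (seg["END"] >= seg["START"]).all()
            assert (seg["START"].to_numpy()[1:]
                    > seg["END"].to_numpy()[:-1]).all()
            assert seg["LENGTH_BP"].sum() <= gm.contig_length

    def test_planted_tract_found(self, mosaic):
        gm, truth = mosaic
        scan = detect_roh(gm, error_rate=0.005)
        seg = scan.segments.query("SAMPLE == 'S0' and LENGTH_BP > 1_000_000")
        assert len(seg) >= 1
        top = seg.sort_values("LENGTH_BP").iloc[-1]
        assert top["START"] < 1_100_000 and top["END"] > 2_400_000

    def test_lower_error_rate_never_adds_het_bearing_segments(self, mosaic):
        gm, _ = mosaic

        def het_segments(eps):
            scan = detect_roh(gm, error_rate=eps)
            count = 0
            for r in scan.segments.itertuples():
                j = gm.samples.index(r.SAMPLE)
                inside = (gm.positions >= r.START) & (gm.positions <= r.END)
                count += int((gm.dosage[inside, j] == 1).any())
            return count

        assert het_segments(0.0005) <= het_segments(0.02)
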