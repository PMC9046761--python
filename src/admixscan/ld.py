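"""LD decay: pairwise r² against physical distance.

r² is the squared Pearson correlation of alternate-allele dosages over
samples called at both sites (composite, phase-free LD). Curves bin all
within-chromosome pairs up to a maximum separation and report the mean
r² and pair count per distance bin. Pair enumeration walks a sliding
positional window, so memory is O(sites in window), not O(total pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationPanel

DEFAULT_MAX_DIST = 300_000
DEFAULT_BIN_WIDTH = 1_000
DEFAULT_MAF = 0.05


def pairwise_r2(dos_a, dos_b) -> float:
    """Squared dosage correlation of two sites over jointly called samples.

    NaN when fewer than 2 samples are jointly called or either site is
    monomorphic among them.
    """
    a = np.asarray(dos_a, dtype=float)
    b = np.asarray(dos_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


@dataclass
class DecayCurve:
    population: str
    bin_start: np.ndarray   # bp, inclusive
    bin_end: np.ndarray     # bp, inclusive
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "POP": self.population, "BIN_START": self.bin_start,
            "BIN_END": self.bin_end, "MEAN_R2": self.mean_r2,
            "N_PAIRS": self.n_pairs,
        })

    def half_decay_distance(self) -> float:
        """Midpoint of the first bin where mean r² drops to halfway
        between the first-bin level and the curve's floor (NaN if the
        curve never reaches it)."""
        ok = self.n_pairs > 0
        if ok.sum() < 2:
            return float("nan")
        mids = (self.bin_start[ok] + self.bin_end[ok]) / 2.0
        means = self.mean_r2[ok]
        target = (means[0] + means.min()) / 2.0
        below = np.flatnonzero(means <= target)
        return float(mids[below[0]]) if len(below) else float("nan")


def _binned_pair_sums(dosage, positions, max_dist, bin_width):
    """Accumulate Σr² and counts per distance bin with a sliding window.

    ``dosage`` is float (n_sites, n_samples) with NaN for missing.
    """
    n_sites, n_samples = dosage.shape
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    no_missing = not np.isnan(dosage).any()
    if no_missing:
        mu = dosage.mean(axis=1, keepdims=True)
        sd = dosage.std(axis=1, keepdims=True)
        poly = sd[:, 0] > 0
        zs = np.where(poly[:, None], (dosage - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    hi = 0
    for i in range(n_sites):
        while hi < n_sites and positions[hi] - positions[i] <= max_dist:
            hi += 1
        if hi <= i + 1:
            continue
        j = slice(i + 1, hi)
        dists = positions[j] - positions[i]
        bins = np.minimum(((dists - 1) // bin_width).astype(int), n_bins - 1)
        if no_missing:
            if not poly[i]:
                continue
            r = zs[j] @ zs[i] / n_samples
            r2 = r * r
            valid = poly[i + 1:hi]
        else:
            r2 = np.array([pairwise_r2(dosage[i], dosage[k])
                           for k in range(i + 1, hi)])
            valid = ~np.isnan(r2)
        np.add.at(sums, bins[valid], r2[valid])
        np.add.at(counts, bins[valid], 1)
    return sums, counts


def decay_curve(gm: GenotypeMatrix, panel: PopulationPanel | None = None,
                population: str | None = None,
                max_dist: int = DEFAULT_MAX_DIST,
                bin_width: int = DEFAULT_BIN_WIDTH,
                maf: float = DEFAULT_MAF) -> DecayCurve:
    """Mean-r² decay curve for one population (or all samples).

    Sites below the MAF threshold (within the analyzed samples) are
    excluded. Bins are [1, w], [w+1, 2w], ... up to ``max_dist`` bp.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ValueError("max_dist and bin_width must be > 0")
    if population is not None:
        if panel is None:
            raise ValueError("a panel is required to select a population")
        idx = panel.indices_in(gm, population)
        sub = gm.take_samples([int(i) for i in idx])
    else:
        sub = gm
    f = sub.alt_frequency()
    keep = ~np.isnan(f) & (np.minimum(f, 1 - f) >= maf)
    dosage = sub.dosage[keep].astype(float)
    dosage[sub.dosage[keep] == MISSING] = np.nan
    positions = sub.positions[keep]
    sums, counts = _binned_pair_sums(dosage, positions, max_dist, bin_width)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_bins = len(counts)
    starts = 1 + bin_width * np.arange(n_bins, dtype=np.int64)
    return DecayCurve(
        population=population or "ALL",
        bin_start=starts,
        bin_end=starts + bin_width - 1,
        mean_r2=mean_r2,
        n_pairs=counts,
    )


def merge_bins(curve: DecayCurve, factor: int = 2) -> DecayCurve:
    """Count-weighted merge of adjacent bins (coarser curve)."""
    n = len(curve.n_pairs)
    n_out = int(np.ceil(n / factor))
    sums = np.zeros(n_out)
    counts = np.zeros(n_out, dtype=np.int64)
    for b in range(n):
        o = b // factor
        if curve.n_pairs[b] > 0:
            sums[o] += curve.mean_r2[b] * curve.n_pairs[b]
            counts[o] += curve.n_pairs[b]
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = curve.bin_start[::factor]
    ends = np.concatenate([curve.bin_end[factor - 1::factor],
                           curve.bin_end[-1:]])[:n_out]
    return DecayCurve(curve.population, starts, ends, mean_r2, counts)
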