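"""Population-structure PCA on standardized genotype dosages.

Each site is centered at its mean dosage 2p̂ and scaled by
sqrt(p̂(1−p̂)), p̂ being the sample ALT-allele frequency over called
genotypes — the usual eigenanalysis normalization that equalizes the
drift variance contributed by sites of different frequency. Missing
dosages are imputed to the site mean (zero after centering);
monomorphic sites are dropped. The decomposition is of the
sample × sample covariance of the standardized matrix, so variance
fractions over all components sum to one by the trace identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationPanel


@dataclass
class PCAResult:
    scores: np.ndarray          # (n_samples, k)
    eigenvalues: np.ndarray     # all components, non-increasing
    variance_fraction: np.ndarray
    samples: list
    sites_used: np.ndarray      # positions of retained sites
    loadings: np.ndarray | None = None

    def scores_frame(self, panel: PopulationPanel | None = None) -> pd.DataFrame:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "POP", [panel.membership.get(s, "") if panel else ""
                             for s in self.samples])
        df.insert(0, "SAMPLE", self.samples)
        return df


def standardize(gm: GenotypeMatrix, shrinkage: bool = False):
    """Standardized (n_samples, n_sites) matrix and retained-site mask.

    With ``shrinkage`` the frequency estimate is (1 + ALT count) /
    (2 + 2·called), otherwise the plain MLE. Monomorphic sites (p̂ of 0
    or 1, or nothing called) are dropped; an all-monomorphic input is an
    error.
    """
    ac, an = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        if shrinkage:
            p = (1.0 + ac) / (2.0 + an)
        else:
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    # a constant dosage column (e.g. all heterozygous) carries no
    # variance even when 0 < p < 1; drop those alongside fixed sites
    called = gm.dosage != MISSING
    lo = np.where(called, gm.dosage, 3).min(axis=1)
    hi = np.where(called, gm.dosage, -2).max(axis=1)
    keep = ~np.isnan(p) & (p > 0) & (p < 1) & (an > 0) & (hi > lo)
    if not keep.any():
        raise ValueError("all sites monomorphic; nothing to decompose")
    p = p[keep]
    d = gm.dosage[keep].astype(float)
    miss = gm.dosage[keep] == MISSING
    # center & scale; mean-imputed missing entries become exactly 0
    x = (d - 2.0 * p[:, None]) / np.sqrt(p * (1.0 - p))[:, None]
    x[miss] = 0.0
    return x.T.copy(), keep


def pca(x: np.ndarray, k: int) -> tuple:
    """Eigendecomposition of the sample covariance of a standardized matrix.

    ``x`` is (n_samples, n_sites). Returns (scores, eigenvalues,
    variance fractions) with scores = eigenvector * sqrt(eigenvalue) and
    the sign of each component fixed so its largest-magnitude sample
    coordinate is positive.
    """
    n, m = x.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(samples-1, sites)={min(n - 1, m)}")
    g = (x @ x.T) / m
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    frac = evals / evals.sum()
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(scores[:, j])))
        if scores[i_max, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores, evals, frac


def run_pca(gm: GenotypeMatrix, panel: PopulationPanel | None = None,
            exclude_pops=None, k: int = 10,
            shrinkage: bool = False) -> PCAResult:
    """Standardize + decompose, optionally excluding whole populations."""
    if exclude_pops:
        if panel is None:
            raise ValueError("a panel is required to exclude populations")
        drop = set(panel.samples_in(exclude_pops))
        keep_samples = [s for s in gm.samples if s not in drop]
        gm = gm.take_samples(keep_samples)
    k = min(k, gm.n_samples - 1)
    x, site_mask = standardize(gm, shrinkage=shrinkage)
    scores, evals, frac = pca(x, k)
    return PCAResult(
        scores=scores, eigenvalues=evals, variance_fraction=frac,
        samples=list(gm.samples), sites_used=gm.positions[site_mask],
    )
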