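"""Weir–Cockerham Fst between two pooled sample groups, per site and in
sliding windows.

Per site the estimator decomposes allele-frequency variance into
among-population (a), among-individual-within-population (b) and
within-individual (c) components; Fst = a/(a+b+c). Windows report the
ratio-of-sums Σa / Σ(a+b+c) (the "weighted" estimate) alongside the mean
of per-site ratios. Negative estimates are reported as computed —
clamping would bias the window sums.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationPanel

DEFAULT_SPAN = 20_000
DEFAULT_STEP = 10_000


def wc_components(n1, p1, h1, n2, p2, h2):
    """Two-population Weir–Cockerham variance components (vectorized).

    Parameters are per-site arrays: diploid sample sizes n, ALT-allele
    frequencies p and observed heterozygote frequencies h for each group.
    Returns (a, b, c).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _group_stats(gm: GenotypeMatrix, idx):
    d = gm.dosage[:, idx]
    called = d != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, d, 0).sum(axis=1) / np.maximum(2.0 * n, 1.0)
        h = (d == 1).sum(axis=1) / np.maximum(n, 1.0)
    return n, p, h


def site_fst(gm: GenotypeMatrix, idx1, idx2) -> pd.DataFrame:
    """Per-site W&C components for two sample-index groups.

    Sites where either group has fewer than 2 called diploids are skipped
    (``usable`` False, reason recorded); sites where both groups are
    monomorphic for the same allele have an undefined ratio (components
    all ~0) and are flagged non-usable too.
    """
    n1, p1, h1 = _group_stats(gm, idx1)
    n2, p2, h2 = _group_stats(gm, idx2)
    enough = (n1 >= 2) & (n2 >= 2)
    a = np.full(gm.n_sites, np.nan)
    b = np.full(gm.n_sites, np.nan)
    c = np.full(gm.n_sites, np.nan)
    if enough.any():
        a[enough], b[enough], c[enough] = wc_components(
            n1[enough], p1[enough], h1[enough], n2[enough], p2[enough], h2[enough]
        )
    denom = a + b + c
    usable = enough & (np.abs(denom) > 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(usable, a / np.where(usable, denom, 1.0), np.nan)
    reason = np.where(enough, np.where(usable, "", "monomorphic"), "too_few_called")
    return pd.DataFrame(
        {"pos": gm.positions, "a": a, "b": b, "c": c, "fst": fst,
         "usable": usable, "skip_reason": reason}
    )


def windowed_fst(sites: pd.DataFrame, span: int = DEFAULT_SPAN,
                 step: int = DEFAULT_STEP, chrom_length: int | None = None
                 ) -> pd.DataFrame:
    """Aggregate per-site components into sliding windows.

    Windows are anchored at position 1 and tile [1, chrom_length] with the
    given step; coordinates are 1-based inclusive and the final partial
    window is kept. Each site contributes to every window containing it.
    """
    if span <= 0:
        raise ValueError("window span must be > 0")
    if step <= 0:
        raise ValueError("window step must be > 0")
    if span < step:
        warnings.warn("window span < step leaves gaps between windows")
    if chrom_length is None:
        chrom_length = int(sites["pos"].max()) if len(sites) else span
    starts = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    ends = np.minimum(starts + span - 1, chrom_length)
    use = sites.loc[sites["usable"]]
    pos = use["pos"].to_numpy()
    a = use["a"].to_numpy()
    denom = (use["a"] + use["b"] + use["c"]).to_numpy()
    ratio = use["fst"].to_numpy()
    rows = []
    for s, e in zip(starts, ends):
        inw = (pos >= s) & (pos <= e)
        k = int(inw.sum())
        if k:
            dsum = denom[inw].sum()
            wfst = a[inw].sum() / dsum if dsum != 0 else np.nan
            mfst = float(np.mean(ratio[inw]))
        else:
            wfst = np.nan
            mfst = np.nan
        rows.append((s, e, k, wfst, mfst))
    return pd.DataFrame(
        rows, columns=["BIN_START", "BIN_END", "N_VARIANTS",
                       "WEIGHTED_FST", "MEAN_FST"]
    )


def genome_weighted_fst(sites: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums Fst over usable sites."""
    use = sites.loc[sites["usable"]]
    denom = (use["a"] + use["b"] + use["c"]).sum()
    return float(use["a"].sum() / denom)


def group_contrast(gm: GenotypeMatrix, panel: PopulationPanel,
                   case, control, span: int = DEFAULT_SPAN,
                   step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Case/control pooled-group scan, windows ranked by weighted Fst.

    ``case`` and ``control`` are population lists (e.g. the pigmentation
    breed groupings); their sample sets must be non-empty and disjoint.
    Ties in weighted Fst break by window start ascending.
    """
    case = [case] if isinstance(case, str) else list(case)
    control = [control] if isinstance(control, str) else list(control)
    if not case or not control:
        raise ValueError("case and control population lists must be non-empty")
    if set(case) & set(control):
        raise ValueError("case and control populations overlap")
    idx1 = panel.indices_in(gm, case)
    idx2 = panel.indices_in(gm, control)
    if set(idx1) & set(idx2):
        raise ValueError("case and control sample sets overlap")
    sites = site_fst(gm, idx1, idx2)
    win = windowed_fst(sites, span=span, step=step,
                       chrom_length=gm.contig_length)
    win.insert(0, "CHROM", gm.chrom)
    win = win.sort_values(
        ["WEIGHTED_FST", "BIN_START"], ascending=[False, True],
        na_position="last", kind="mergesort",
    ).reset_index(drop=True)
    return win


# named presets mirroring the pigmentation case/control breed groupings
PIGMENTATION_GROUPS = {
    "dominant_white": ["White_Leghorn", "Cobb"],
    "recessive_white": ["Recessive_White", "HWS", "LWS", "Silkie"],
    "black": ["Emei_Black", "Muchuan_Black_Bone", "Tianfu_Black_Bone",
              "Sumatras", "Langshans", "Black_Cochin", "Java"],
    "yellow": ["Liyang", "Buff_Cochin", "Huiyang_Beard", "Rhode_Island_Red"],
}
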