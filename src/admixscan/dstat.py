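"""ABBA-BABA introgression test.

Patterson's D from population allele frequencies on the four-taxon tree
(((P1,P2),P3),Outgroup): sites are polarized by the outgroup's major
allele, ABBA/BABA terms are the frequency products
``(1-p1) p2 p3 (1-p4)`` and ``p1 (1-p2) p3 (1-p4)``, and
D = Σ(ABBA-BABA) / Σ(ABBA+BABA). Positive D means excess derived-allele
sharing between P2 and P3. The standard error comes from a delete-one
block jackknife over contiguous genomic blocks; Z = D/SE. The admixture
fraction f-hat divides the observed ABBA-BABA excess by the excess
expected under complete replacement of P2 by the donor P3 (the donor's
frequency substituted in the P2 slot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationPanel

DEFAULT_BLOCK_SIZE = 5_000_000


@dataclass
class SitePatternCounts:
    """Per-block ABBA/BABA sums (and optional f-hat denominator sums)."""

    abba: np.ndarray            # per-block Σ abba
    baba: np.ndarray            # per-block Σ baba
    n_sites: np.ndarray         # informative sites per block
    block_start: np.ndarray
    block_end: np.ndarray
    fhat_denom: np.ndarray | None = None  # per-block Σ (abba_d - baba_d)

    def __post_init__(self):
        m = len(self.abba)
        for arr in (self.baba, self.n_sites, self.block_start, self.block_end):
            if len(arr) != m:
                raise ValueError("block arrays must have equal length")
        if (np.asarray(self.abba) < 0).any() or (np.asarray(self.baba) < 0).any():
            raise ValueError("pattern sums must be non-negative")

    @property
    def n_blocks(self) -> int:
        return len(self.abba)


@dataclass
class DResult:
    """One trio's introgression test result."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    fhat: float | None = None

    def to_row(self) -> dict:
        return {
            "P1": self.p1, "P2": self.p2, "P3": self.p3,
            "OUTGROUP": self.outgroup, "nSites": self.n_sites,
            "nBlocks": self.n_blocks, "D": self.d, "SE": self.se,
            "Z": self.z, "fhat": self.fhat,
        }


# --------------------------------------------------------------------------
# polarization and site patterns
# --------------------------------------------------------------------------

def polarize(gm: GenotypeMatrix, panel: PopulationPanel, populations,
             outgroup: str):
    """Derived-allele frequencies per population, rooted by the outgroup.

    The ancestral allele at each site is the outgroup's major allele
    (ties break to REF); derived frequencies are then 1 - ancestral-allele
    frequency per population. Sites where the outgroup is entirely
    missing are dropped and counted.

    Returns (freqs dict incl. the outgroup, kept-site index array,
    n_dropped).
    """
    pops = list(populations)
    if outgroup not in pops:
        pops = pops + [outgroup]
    out_idx = panel.indices_in(gm, outgroup)
    p_out_alt = gm.alt_frequency(out_idx)
    keep = ~np.isnan(p_out_alt)
    n_dropped = int((~keep).sum())
    anc_is_alt = p_out_alt[keep] > 0.5
    freqs = {}
    for pop in pops:
        idx = panel.indices_in(gm, pop)
        p_alt = gm.alt_frequency(idx)[keep]
        freqs[pop] = np.where(anc_is_alt, 1.0 - p_alt, p_alt)
    return freqs, np.flatnonzero(keep), n_dropped


def site_pattern_terms(p1, p2, p3, p4):
    """Frequency-form ABBA and BABA terms per site."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def block_pattern_counts(p1, p2, p3, p4, positions=None,
                         block_size: int = DEFAULT_BLOCK_SIZE,
                         n_blocks: int | None = None,
                         n3_alleles=None) -> SitePatternCounts:
    """Sum site patterns into contiguous jackknife blocks.

    Blocks are physical windows of ``block_size`` bp over ``positions``;
    alternatively ``n_blocks`` splits the (position-sorted) sites into
    equally sized index blocks. Sites with NaN terms are ignored.

    The f-hat denominator needs p3 squared; the plug-in square of a
    sampled frequency is inflated by its sampling variance, so when
    ``n3_alleles`` (called allele counts in P3 per site) is given the
    unbiased estimator p̂3² − p̂3(1−p̂3)/(n3−1) is used instead.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba, baba = site_pattern_terms(p1, p2, p3, p4)
    p3_sq = p3 * p3
    if n3_alleles is not None:
        n3 = np.asarray(n3_alleles, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(n3 > 1, p3 * (1.0 - p3) / np.maximum(n3 - 1.0, 1.0),
                            np.nan)
        p3_sq = p3_sq - corr
    # S(P1, P3, P3, O) = (p3^2 - p1 p3)(1 - p4)
    fden = (p3_sq - p1 * p3) * (1.0 - p4)
    n = len(abba)
    if positions is None:
        positions = np.arange(n, dtype=np.int64)
    positions = np.asarray(positions)
    ok = ~(np.isnan(abba) | np.isnan(baba) | np.isnan(fden))
    abba, baba, fden, positions = abba[ok], baba[ok], fden[ok], positions[ok]
    if n_blocks is not None:
        if n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        edges = np.array_split(np.arange(len(abba)), n_blocks)
        groups = [e for e in edges if len(e)]
    else:
        if block_size <= 0:
            raise ValueError("block_size must be > 0")
        block_id = (positions - positions.min()) // block_size
        groups = [np.flatnonzero(block_id == b) for b in np.unique(block_id)]
    m = len(groups)
    out = SitePatternCounts(
        abba=np.array([abba[g].sum() for g in groups]),
        baba=np.array([baba[g].sum() for g in groups]),
        n_sites=np.array([len(g) for g in groups]),
        block_start=np.array([positions[g[0]] for g in groups]),
        block_end=np.array([positions[g[-1]] for g in groups]),
        fhat_denom=np.array([fden[g].sum() for g in groups]),
    )
    assert out.n_blocks == m
    return out


# --------------------------------------------------------------------------
# D, jackknife, f-hat
# --------------------------------------------------------------------------

def d_statistic(counts: SitePatternCounts) -> float:
    """Ratio-of-sums D over all blocks; NaN when the denominator is 0."""
    num = counts.abba.sum() - counts.baba.sum()
    den = counts.abba.sum() + counts.baba.sum()
    if den <= 0:
        warnings.warn("zero ABBA+BABA denominator; D undefined")
        return float("nan")
    return float(num / den)


def block_jackknife(counts: SitePatternCounts):
    """Delete-one block jackknife SE of D and the Z score.

    SE = sqrt(((m-1)/m) * Σ_j (D_{-j} - mean(D_{-j}))^2). Blocks whose
    removal zeroes the denominator are merged with their right neighbour
    (left for the last block) before resampling. Z is NaN when SE = 0.
    """
    abba, baba = counts.abba.copy(), counts.baba.copy()
    tot_a, tot_b = abba.sum(), baba.sum()
    # merge blocks that would zero the delete-one denominator
    while len(abba) >= 2:
        loo_den = (tot_a + tot_b) - (abba + baba)
        bad = np.flatnonzero(loo_den <= 0)
        if not len(bad):
            break
        j = bad[0]
        k = j + 1 if j + 1 < len(abba) else j - 1
        warnings.warn(f"jackknife block {j} merged with neighbour {k} "
                      "(zero delete-one denominator)")
        abba[k] += abba[j]
        baba[k] += baba[j]
        abba = np.delete(abba, j)
        baba = np.delete(baba, j)
    m = len(abba)
    if m < 2:
        raise ValueError("block jackknife needs >= 2 usable blocks")
    d_full = (tot_a - tot_b) / (tot_a + tot_b)
    loo = ((tot_a - abba) - (tot_b - baba)) / ((tot_a - abba) + (tot_b - baba))
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    z = float(d_full / se) if se > 0 else float("nan")
    if se == 0:
        warnings.warn("zero between-block variance; Z undefined")
    return se, z


def admixture_fraction(counts: SitePatternCounts, split_half: bool = False,
                       **_ignored) -> float:
    """f-hat: observed ABBA-BABA excess over the complete-replacement excess.

    Uses per-block sums; the denominator substitutes the donor (P3)
    frequency in the P2 slot (f_hom form, precomputed at counting time).
    """
    if counts.fhat_denom is None:
        raise ValueError("counts carry no f-hat denominator sums")
    num = counts.abba.sum() - counts.baba.sum()
    den = counts.fhat_denom.sum()
    if den <= 0:
        warnings.warn("non-positive f-hat denominator; f-hat undefined")
        return float("nan")
    return float(num / den)


def split_half_fhat(gm: GenotypeMatrix, panel: PopulationPanel,
                    p1: str, p2: str, p3: str, outgroup: str,
                    block_size: int = DEFAULT_BLOCK_SIZE,
                    n_blocks: int | None = None, seed: int = 0) -> float:
    """f-hat variant with the donor split into two random halves.

    One half of P3 provides the P3 slot, the other the substituted P2
    slot of the denominator — removing the shared-drift term of the
    single-population denominator. Needs >= 2 donor samples.
    """
    donor_samples = panel.samples_in(p3)
    if len(donor_samples) < 2:
        raise ValueError("split-half f-hat needs >= 2 donor samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(donor_samples))
    half = len(donor_samples) // 2
    mem = dict(panel.membership)
    for i in perm[:half]:
        mem[donor_samples[i]] = "__P3A__"
    for i in perm[half:]:
        mem[donor_samples[i]] = "__P3B__"
    panel2 = PopulationPanel(mem)
    freqs, kept, _ = polarize(gm, panel2, [p1, p2, "__P3A__", "__P3B__"], outgroup)
    q1, q2, q3a, q3b, q4 = (freqs[p] for p in
                            (p1, p2, "__P3A__", "__P3B__", outgroup))
    num_a, num_b = site_pattern_terms(q1, q2, q3a, q4)
    den_a, den_b = site_pattern_terms(q1, q3b, q3a, q4)
    den = (den_a - den_b).sum()
    if den <= 0:
        return float("nan")
    return float((num_a - num_b).sum() / den)


def run_trio(gm: GenotypeMatrix, panel: PopulationPanel,
             p1: str, p2: str, p3: str, outgroup: str,
             block_size: int = DEFAULT_BLOCK_SIZE,
             n_blocks: int | None = None) -> DResult:
    """Full trio analysis: polarize, block sums, D, jackknife SE/Z, f-hat."""
    panel.assert_trio(p1, p2, p3, outgroup)
    freqs, kept, _ = polarize(gm, panel, [p1, p2, p3], outgroup)
    _, an3 = gm.allele_counts(panel.indices_in(gm, p3))
    counts = block_pattern_counts(
        freqs[p1], freqs[p2], freqs[p3], freqs[outgroup],
        positions=gm.positions[kept], block_size=block_size, n_blocks=n_blocks,
        n3_alleles=an3[kept],
    )
    d = d_statistic(counts)
    se, z = block_jackknife(counts)
    fhat = admixture_fraction(counts)
    return DResult(
        p1=p1, p2=p2, p3=p3, outgroup=outgroup, d=d, se=se, z=z,
        n_blocks=counts.n_blocks, n_sites=int(counts.n_sites.sum()), fhat=fhat,
    )


def trios_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
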