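"""Synthetic genotype panels with known demographic truth.

Two generators cover the validation needs of the downstream scans:

* a drift-tree model on the fixed four-population topology
  ``(((P1,P2),P3),O)`` with Balding–Nichols drift on every branch and an
  optional one-off admixture pulse of fraction ``alpha`` — unlinked sites,
  suitable for Fst / D / f-hat / PCA parameter recovery;
* a founder-copying mosaic model on one chromosome — haplotypes copy from
  K founders with distance-dependent switching, which induces LD decaying
  with physical distance, and carries planted autozygous tracts for ROH
  recovery.

Both are fully reproducible from their spec + seed and can serialize a
VCF plus plain-text truth files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationPanel
from .vcfio import write_vcf

TREE_POPULATIONS = ("P1", "P2", "P3", "O")
# branches of (((P1,P2),P3),O): P12 is the internal branch root->(P1,P2) ancestor
TREE_BRANCHES = ("P12", "P1", "P2", "P3", "O")


@dataclass
class DemographySpec:
    """Drift-tree simulation parameters.

    ``drift`` maps each branch of (((P1,P2),P3),O) to its Balding–Nichols
    differentiation parameter F in (0,1). The admixture pulse replaces a
    fraction ``alpha`` of the recipient's pre-drift frequency with the
    donor's (post-drift) frequency.
    """

    n_sites: int = 10_000
    samples_per_pop: int = 25
    drift: dict = field(default_factory=lambda: {b: 0.05 for b in TREE_BRANCHES})
    alpha: float = 0.0
    donor: str = "P3"
    recipient: str = "P2"
    anc_freq_range: tuple = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be >= 1")
        missing = set(TREE_BRANCHES) - set(self.drift)
        if missing:
            raise ValueError(f"drift missing branches: {sorted(missing)}")
        for b, f in self.drift.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"drift F for branch {b} must be in (0,1), got {f}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0,1]")
        lo, hi = self.anc_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral frequency range must satisfy 0 < low < high < 1")
        if self.donor not in TREE_POPULATIONS or self.recipient not in ("P1", "P2", "P3"):
            raise ValueError("donor/recipient must be tree populations")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")

    @classmethod
    def uniform_drift(cls, f: float, **kw) -> "DemographySpec":
        return cls(drift={b: f for b in TREE_BRANCHES}, **kw)


@dataclass
class MosaicSpec:
    """Founder-copying mosaic parameters for one synthetic chromosome.

    ``rho`` is the per-bp copying switch rate: between adjacent sites d bp
    apart a haplotype re-draws its founder with probability 1 - exp(-rho*d).
    ``tracts`` is a list of (sample index, start bp, end bp) autozygous
    tracts; inside a tract both chromosomes of the individual copy one
    founder, so its genotypes are homozygous up to genotyping error ``e``.
    """

    length: int = 10_000_000
    site_density: float = 1e-3
    n_samples: int = 30
    k_founders: int = 40
    rho: float = 1e-5
    error_rate: float = 0.0
    tracts: list = field(default_factory=list)
    missing_rate: float = 0.0
    founder_freq_range: tuple = (0.05, 0.95)
    chrom: str = "chr_sim"
    seed: int = 0

    def __post_init__(self):
        if self.length < 2 or self.site_density <= 0:
            raise ValueError("length >= 2 and site_density > 0 required")
        if self.k_founders < 1 or self.n_samples < 1:
            raise ValueError("need >= 1 founder and >= 1 sample")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not (0.0 <= self.error_rate < 1.0) or not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("error and missing rates must be in [0,1)")
        by_ind = {}
        for ind, start, end in self.tracts:
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"tract ({ind},{start},{end}) outside chromosome")
            if not (0 <= ind < self.n_samples):
                raise ValueError(f"tract individual {ind} out of range")
            by_ind.setdefault(ind, []).append((start, end))
        for ind, ts in by_ind.items():
            ts = sorted(ts)
            for (s0, e0), (s1, e1) in zip(ts, ts[1:]):
                if s1 <= e0:
                    raise ValueError(f"overlapping tracts for individual {ind}")


@dataclass
class SimTruth:
    """Generator ground truth serialized alongside the genotypes."""

    spec: object
    pop_freqs: dict | None = None          # population -> per-site frequency
    ancestral_allele: np.ndarray | None = None  # 'REF'/'ALT' per site
    ancestral_freq: np.ndarray | None = None
    recipient_premix: np.ndarray | None = None  # recipient pre-drift frequency
    tracts: pd.DataFrame | None = None
    founder_paths: np.ndarray | None = None     # (2*n_samples, n_sites) founder ids
    positions: np.ndarray | None = None

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spec_dict = dataclasses.asdict(self.spec)
        spec_dict["__type__"] = type(self.spec).__name__
        with open(outdir / "truth_spec.json", "w") as fh:
            json.dump(spec_dict, fh, indent=2, sort_keys=True, default=list)
        if self.pop_freqs is not None:
            df = pd.DataFrame(self.pop_freqs)
            df.insert(0, "ancestral_freq", self.ancestral_freq)
            df.insert(0, "ancestral_allele", self.ancestral_allele)
            if self.positions is not None:
                df.insert(0, "pos", self.positions)
            df.to_csv(outdir / "truth_frequencies.tsv", sep="\t", index=False,
                      float_format="%.8g")
        if self.tracts is not None:
            self.tracts.to_csv(outdir / "truth_tracts.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# drift-tree model
# --------------------------------------------------------------------------

def _balding_nichols(rng, p, f):
    """Child frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around parent p."""
    theta = (1.0 - f) / f
    a = np.clip(p * theta, 1e-12, None)
    b = np.clip((1.0 - p) * theta, 1e-12, None)
    return rng.beta(a, b)


def simulate_tree_frequencies(spec: DemographySpec):
    """Per-population derived(ALT)-allele frequencies under the drift tree.

    Returns (freqs, truth) where freqs maps P1/P2/P3/O to per-site
    frequency arrays. The admixture pulse mixes into the recipient's
    pre-drift frequency: (1-alpha)*parent + alpha*donor(post-drift).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.anc_freq_range
    p0 = rng.uniform(lo, hi, size=spec.n_sites)
    p12 = _balding_nichols(rng, p0, spec.drift["P12"])
    parent = {"P1": p12, "P2": p12, "P3": p0, "O": p0}
    # donor frequency is its post-drift value; draw donor before recipient
    order = [spec.donor] + [p for p in TREE_POPULATIONS if p != spec.donor]
    freqs = {}
    premix = None
    for pop in order:
        pre = parent[pop]
        if pop == spec.recipient and spec.alpha > 0:
            pre = (1.0 - spec.alpha) * pre + spec.alpha * freqs[spec.donor]
            premix = pre
        freqs[pop] = _balding_nichols(rng, pre, spec.drift[pop])
    if premix is None:
        premix = parent[spec.recipient]
    freqs = {pop: freqs[pop] for pop in TREE_POPULATIONS}
    truth = SimTruth(
        spec=spec,
        pop_freqs=freqs,
        ancestral_allele=np.where(p0 > 0.5, "ALT", "REF"),
        ancestral_freq=p0,
        recipient_premix=premix,
    )
    return freqs, truth


def sample_genotypes(
    freqs: dict,
    samples_per_pop: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    spacing: int = 100,
    chrom: str = "chr_sim",
    qual_low_frac: float = 0.1,
):
    """Draw diploid genotypes Binomial(2, p_pop) from population frequencies.

    Positions are laid out every ``spacing`` bp on one synthetic
    chromosome. QUAL values come from a two-component mixture (a
    ``qual_low_frac`` fraction below 20, the rest well above) so the
    quality filter has something to act on.

    Returns (GenotypeMatrix, PopulationPanel, truth positions).
    """
    rng = np.random.default_rng(seed)
    pops = list(freqs)
    n_sites = len(next(iter(freqs.values())))
    cols, samples, membership = [], [], {}
    for pop in pops:
        p = np.clip(np.asarray(freqs[pop], dtype=float), 0.0, 1.0)
        g = rng.binomial(2, p[:, None], size=(n_sites, samples_per_pop))
        cols.append(g.astype(np.int8))
        for i in range(samples_per_pop):
            name = f"{pop}_{i}"
            samples.append(name)
            membership[name] = pop
    dosage = np.hstack(cols)
    if missing_rate > 0:
        miss = rng.random(dosage.shape) < missing_rate
        dosage[miss] = MISSING
    low = rng.random(n_sites) < qual_low_frac
    qual = np.where(low, rng.uniform(5.0, 20.0, n_sites),
                    rng.uniform(30.0, 90.0, n_sites))
    positions = spacing * np.arange(1, n_sites + 1, dtype=np.int64)
    gm = GenotypeMatrix(
        chrom=chrom,
        positions=positions,
        ref=["A"] * n_sites,
        alt=[("G",)] * n_sites,
        qual=qual,
        dosage=dosage,
        samples=samples,
        contig_length=int(positions[-1] + spacing),
    )
    return gm, PopulationPanel(membership)


def simulate_tree_panel(spec: DemographySpec, missing_rate: float = 0.0,
                        spacing: int = 100, chrom: str = "chr_sim"):
    """Convenience: frequencies + genotype sampling in one call.

    Returns (GenotypeMatrix, PopulationPanel, SimTruth). Genotype sampling
    uses a child seed derived from the spec seed, so the whole panel is a
    deterministic function of the spec.
    """
    freqs, truth = simulate_tree_frequencies(spec)
    gm, panel = sample_genotypes(
        freqs, spec.samples_per_pop, missing_rate=missing_rate,
        seed=_child_seed(spec.seed, 1), spacing=spacing, chrom=chrom,
    )
    truth.positions = gm.positions
    return gm, panel, truth


def _child_seed(seed: int, stream: int) -> int:
    """Derived integer seed (< 2^31) for an internal random stream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# founder-copying mosaic model
# --------------------------------------------------------------------------

def simulate_mosaic_panel(spec: MosaicSpec):
    """Phased founder-mosaic haplotypes with planted autozygous tracts.

    Returns (haplotypes, GenotypeMatrix, SimTruth). ``haplotypes`` is a
    (2*n_samples, n_sites) 0/1 array before genotyping error; row 2i and
    2i+1 are the two chromosomes of sample i.
    """
    rng = np.random.default_rng(spec.seed)
    n_sites = max(2, int(round(spec.length * spec.site_density)))
    positions = np.sort(rng.choice(np.arange(1, spec.length + 1),
                                   size=n_sites, replace=False))
    lo, hi = spec.founder_freq_range
    founder_freq = rng.uniform(lo, hi, size=n_sites)
    founders = (rng.random((spec.k_founders, n_sites)) < founder_freq).astype(np.int8)

    d = np.diff(positions)
    p_switch = 1.0 - np.exp(-spec.rho * d)

    n_hap = 2 * spec.n_samples
    paths = np.empty((n_hap, n_sites), dtype=np.int32)
    for h in range(n_hap):
        switches = rng.random(n_sites - 1) < p_switch
        # founder id is piecewise constant between switch points
        n_seg = 1 + int(switches.sum())
        seg_ids = rng.integers(0, spec.k_founders, size=n_seg)
        seg_lengths = np.diff(
            np.concatenate(([0], np.flatnonzero(switches) + 1, [n_sites]))
        )
        paths[h] = np.repeat(seg_ids, seg_lengths)

    # planted autozygosity: both chromosomes copy one founder in the tract
    tract_rows = []
    for ind, start, end in spec.tracts:
        in_tract = (positions >= start) & (positions <= end)
        f_id = int(rng.integers(0, spec.k_founders))
        paths[2 * ind, in_tract] = f_id
        paths[2 * ind + 1, in_tract] = f_id
        tract_rows.append(
            {"sample": f"S{ind}", "sample_index": ind, "chrom": spec.chrom,
             "start": start, "end": end, "founder": f_id,
             "n_sites": int(in_tract.sum())}
        )

    site_idx = np.arange(n_sites)
    haps = founders[paths, site_idx[None, :]]

    observed = haps.copy()
    if spec.error_rate > 0:
        flips = rng.random(observed.shape) < spec.error_rate
        observed = np.where(flips, 1 - observed, observed).astype(np.int8)
    dosage = (observed[0::2] + observed[1::2]).T.astype(np.int8)
    if spec.missing_rate > 0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = MISSING

    low = rng.random(n_sites) < 0.1
    qual = np.where(low, rng.uniform(5.0, 20.0, n_sites),
                    rng.uniform(30.0, 90.0, n_sites))
    gm = GenotypeMatrix(
        chrom=spec.chrom,
        positions=positions.astype(np.int64),
        ref=["A"] * n_sites,
        alt=[("G",)] * n_sites,
        qual=qual,
        dosage=dosage,
        samples=[f"S{i}" for i in range(spec.n_samples)],
        contig_length=spec.length,
    )
    truth = SimTruth(
        spec=spec,
        tracts=pd.DataFrame(
            tract_rows,
            columns=["sample", "sample_index", "chrom", "start", "end",
                     "founder", "n_sites"],
        ),
        founder_paths=paths,
        positions=positions.astype(np.int64),
    )
    return haps, gm, truth


def write_panel(gm: GenotypeMatrix, panel: PopulationPanel | None,
                truth: SimTruth | None, outdir) -> None:
    """Serialize a simulated panel: VCF + panel TSV + truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, outdir / "panel.vcf")
    if panel is not None:
        panel.to_file(outdir / "panel.tsv")
    if truth is not None:
        truth.save(outdir)
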