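"""Core in-memory containers: genotype matrix and population panel.

The genotype store is a sites × samples alternate-allele dosage matrix
(0/1/2, -1 for missing) with per-site position, alleles and QUAL — the
working representation behind every downstream scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_DNA = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix for one chromosome.

    Attributes
    ----------
    chrom : chromosome name.
    positions : 1-based bp positions, strictly increasing.
    ref : REF allele per site.
    alt : tuple of ALT alleles per site (>=1; multi-allelic sites carry
        several entries and are flagged, not dropped, at read time).
    qual : site QUAL (NaN when missing).
    dosage : (n_sites, n_samples) int8 array of alternate-allele counts,
        ``MISSING`` (-1) for uncalled genotypes.
    samples : sample identifiers, column order of ``dosage``.
    contig_length : declared contig length (bp) if known.
    """

    chrom: str
    positions: np.ndarray
    ref: list
    alt: list
    qual: np.ndarray
    dosage: np.ndarray
    samples: list
    contig_length: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (sites x samples)")
        n_sites, n_samples = self.dosage.shape
        if n_samples < 1:
            raise ValueError("need at least one sample")
        if len(self.positions) != n_sites or len(self.qual) != n_sites:
            raise ValueError("positions/qual length mismatch with dosage")
        if len(self.ref) != n_sites or len(self.alt) != n_sites:
            raise ValueError("allele list length mismatch with dosage")
        if len(self.samples) != n_samples:
            raise ValueError("sample list length mismatch with dosage")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosage entries must be in {-1, 0, 1, 2}")
        self.alt = [tuple(a) if not isinstance(a, tuple) else a for a in self.alt]

    # ---- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def called(self) -> np.ndarray:
        """Boolean (sites x samples) mask of called genotypes."""
        return self.dosage != MISSING

    def is_biallelic_snv(self) -> np.ndarray:
        """Per-site mask: single-base REF, exactly one single-base ALT."""
        out = np.zeros(self.n_sites, dtype=bool)
        for i, (r, a) in enumerate(zip(self.ref, self.alt)):
            out[i] = (
                len(a) == 1
                and isinstance(r, str)
                and len(r) == 1
                and r in _DNA
                and len(a[0]) == 1
                and a[0] in _DNA
            )
        return out

    def allele_counts(self, sample_idx: Sequence[int] | None = None):
        """(alt allele count, called allele count) per site over a sample set."""
        d = self.dosage if sample_idx is None else self.dosage[:, list(sample_idx)]
        called = d != MISSING
        ac_alt = np.where(called, d, 0).sum(axis=1).astype(np.int64)
        an = 2 * called.sum(axis=1).astype(np.int64)
        return ac_alt, an

    def alt_frequency(self, sample_idx: Sequence[int] | None = None) -> np.ndarray:
        """ALT allele frequency per site over called genotypes (NaN if none)."""
        ac, an = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    # ---- subsetting ------------------------------------------------------

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            qual=self.qual[idx],
            dosage=self.dosage[idx, :],
            samples=list(self.samples),
            contig_length=self.contig_length,
        )

    def take_samples(self, which: Iterable) -> "GenotypeMatrix":
        """Subset columns by sample name or integer index, order preserved."""
        idx = []
        for w in which:
            if isinstance(w, (int, np.integer)):
                idx.append(int(w))
            else:
                try:
                    idx.append(self.samples.index(w))
                except ValueError:
                    raise KeyError(f"unknown sample: {w!r}") from None
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
            qual=self.qual.copy(),
            dosage=self.dosage[:, idx],
            samples=[self.samples[i] for i in idx],
            contig_length=self.contig_length,
        )


@dataclass
class PopulationPanel:
    """Sample → population map with optional named groups (case/control,
    trio roles)."""

    membership: Mapping[str, str]
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.membership = dict(self.membership)

    @classmethod
    def from_file(cls, path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["sample", "population"], dtype=str)
        return cls(dict(zip(df["sample"], df["population"])))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.membership.items():
                fh.write(f"{s}\t{p}\n")

    @property
    def populations(self) -> list:
        seen = []
        for p in self.membership.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples_in(self, populations) -> list:
        if isinstance(populations, str):
            populations = [populations]
        pops = set(populations)
        unknown = pops - set(self.membership.values())
        if unknown:
            raise KeyError(f"unknown population(s): {sorted(unknown)}")
        return [s for s, p in self.membership.items() if p in pops]

    def indices_in(self, gm: GenotypeMatrix, populations) -> np.ndarray:
        """Column indices of gm.samples belonging to the given populations."""
        wanted = set(self.samples_in(populations))
        idx = [i for i, s in enumerate(gm.samples) if s in wanted]
        if not idx:
            raise ValueError(
                f"no samples of population(s) {populations!r} present in matrix"
            )
        return np.asarray(idx, dtype=np.intp)

    def assert_trio(self, p1, p2, p3, outgroup) -> None:
        roles = [p1, p2, p3, outgroup]
        if len(set(roles)) != 4:
            raise ValueError("trio roles must name four distinct populations")
        known = set(self.membership.values())
        missing = [r for r in roles if r not in known]
        if missing:
            raise KeyError(f"trio roles not in panel: {missing}")
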