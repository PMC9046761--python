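"""VCF input/output and the site-filtering stage.

Reading goes through cyvcf2/htslib; writing is a minimal VCF v4.2 text
emitter sufficient for GT-only matrices (round-trip safe on dosage,
position and QUAL).

The filter retains bi-allelic SNVs with call rate > 0.5, minor allele
count > 3 (over called genotypes) and site QUAL > 20 — all strict
inequalities — and attributes each removed site to the first failing
criterion in that order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix

FILTER_CRITERIA = ("biallelic_snv", "call_rate", "mac", "qual")

# strict thresholds of the site filter
CALL_RATE_MIN = 0.5
MAC_MIN = 3
QUAL_MIN = 20.0


class VcfReadError(ValueError):
    pass


def read_vcf(path, sample_subset=None) -> GenotypeMatrix:
    """Read a single-chromosome multi-sample VCF into a GenotypeMatrix.

    Multi-allelic and indel records are retained (the filter stage flags
    them); for multi-allelic genotypes the dosage is the count of
    non-reference alleles. ``sample_subset`` restricts and orders columns.
    """
    vcf = VCF(str(path), gts012=False, strict_gt=False)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in vcf.samples]
        if unknown:
            raise VcfReadError(f"sample(s) not in VCF header: {unknown}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    contig_length = None
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##contig=") and "length=" in raw:
            try:
                contig_length = int(
                    raw.split("length=")[1].split(",")[0].rstrip(">")
                )
            except ValueError:
                pass
            break

    chrom = None
    positions, ref, alt, qual, rows = [], [], [], [], []
    for record_no, v in enumerate(vcf, start=1):
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise VcfReadError(
                f"record {record_no}: multiple chromosomes in one file "
                f"({chrom!r} then {v.CHROM!r}); read per chromosome"
            )
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2 or any(a is None or a < 0 for a in alleles):
                row[j] = MISSING
            else:
                row[j] = int(alleles[0] > 0) + int(alleles[1] > 0)
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(tuple(v.ALT))
        qual.append(np.nan if v.QUAL is None else float(v.QUAL))
        rows.append(row)
    if chrom is None:
        raise VcfReadError(f"no variant records in {path}")
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        qual=np.asarray(qual, dtype=float),
        dosage=np.vstack(rows),
        samples=samples,
        contig_length=contig_length,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCF v4.2 (GT only)."""
    length = gm.contig_length
    if length is None:
        length = int(gm.positions[-1]) if gm.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            q = gm.qual[i]
            qs = "." if np.isnan(q) else format(q, ".6g")
            gts = "\t".join(_GT_STR[int(d)] for d in gm.dosage[i])
            fh.write(
                f"{gm.chrom}\t{gm.positions[i]}\t.\t{gm.ref[i]}\t"
                f"{','.join(gm.alt[i])}\t{qs}\t.\t.\tGT\t{gts}\n"
            )


def filter_sites(gm: GenotypeMatrix):
    """Apply the site filters; return (filtered matrix, report).

    Criteria, in attribution order:
      a. bi-allelic SNV (single-base REF and exactly one single-base ALT)
      b. fraction of called genotypes > 0.5
      c. minor allele count over called genotypes > 3
      d. site QUAL > 20 (missing QUAL fails)

    A site must pass all four; the report charges each removed site to the
    first criterion it fails, so report counts sum to sites removed.
    """
    n = gm.n_sites
    snv = gm.is_biallelic_snv()
    called = gm.called()
    call_rate = called.sum(axis=1) / gm.n_samples
    ac_alt, an = gm.allele_counts()
    mac = np.minimum(ac_alt, an - ac_alt)
    with np.errstate(invalid="ignore"):
        qual_ok = gm.qual > QUAL_MIN  # NaN compares False
    masks = {
        "biallelic_snv": snv,
        "call_rate": call_rate > CALL_RATE_MIN,
        "mac": mac > MAC_MIN,
        "qual": qual_ok,
    }
    keep = np.ones(n, dtype=bool)
    removed = {}
    for crit in FILTER_CRITERIA:
        fails_here = keep & ~masks[crit]
        removed[crit] = int(fails_here.sum())
        keep &= masks[crit]
    report = pd.DataFrame(
        {
            "criterion": list(FILTER_CRITERIA),
            "removed": [removed[c] for c in FILTER_CRITERIA],
        }
    )
    report["remaining"] = n - report["removed"].cumsum()
    return gm.take_sites(keep), report
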