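import numpy as np
import pytest

from admixscan.core import GenotypeMatrix, PopulationPanel
from admixscan.sim import DemographySpec, simulate_tree_panel

TOY_SAMPLES = [f"S{i}" for i in range(1, 11)]


def _gt(dosages):
    m = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    return "\t".join(m[d] for d in dosages)


def toy_vcf_text() -> str:
    """Hand-enumerated 12-record VCF for the site filter.

    Removals in attribution order: 2 indels + 1 tri-allelic (not
    bi-allelic SNV), 2 low call-rate (0.5 and 0.3 — strict >0.5), 2 low
    MAC (exactly 3 and 2 — strict >3), 1 low QUAL (exactly 20 — strict
    >20); 4 clean records at POS 900..1200 survive.
    """
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=2000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(TOY_SAMPLES) + "\n"
    )
    clean = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]          # MAC 4, all called
    rows = [
        ("chr1\t100\t.\tA\tAT\t50\t.\t.\tGT\t" + _gt(clean)),      # indel
        ("chr1\t200\t.\tAT\tA\t50\t.\t.\tGT\t" + _gt(clean)),      # indel
        ("chr1\t300\t.\tA\tC,T\t50\t.\t.\tGT\t" + _gt(clean)),     # tri-allelic
        ("chr1\t400\t.\tA\tG\t50\t.\t.\tGT\t"
         + _gt([1, 1, 1, 1, 0, None, None, None, None, None])),    # call rate 0.5
        ("chr1\t500\t.\tA\tG\t50\t.\t.\tGT\t"
         + _gt([1, 1, 2, None, None, None, None, None, None, None])),  # 0.3
        ("chr1\t600\t.\tA\tG\t50\t.\t.\tGT\t"
         + _gt([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])),                   # MAC 3
        ("chr1\t700\t.\tA\tG\t50\t.\t.\tGT\t"
         + _gt([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])),                   # MAC 2
        ("chr1\t800\t.\tA\tG\t20\t.\t.\tGT\t"
         + _gt([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])),                   # QUAL 20
        ("chr1\t900\t.\tA\tG\t50\t.\t.\tGT\t" + _gt(clean)),
        ("chr1\t1000\t.\tC\tT\t60\t.\t.\tGT\t" + _gt([2, 2, 0, 0, 0, 0, 0, 0, 0, 0])),
        ("chr1\t1100\t.\tG\tA\t70\t.\t.\tGT\t" + _gt(clean)),
        ("chr1\t1200\t.\tT\tC\t80\t.\t.\tGT\t" + _gt([1, 1, 2, 0, 0, 0, 0, 0, 0, 0])),
    ]
    return header + "\n".join(rows) + "\n"


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy12.vcf"
    path.write_text(toy_vcf_text())
    return path


@pytest.fixture(scope="session")
def small_tree_panel():
    """A small drift-tree panel shared by read-only tests."""
    spec = DemographySpec.uniform_drift(
        0.05, n_sites=3_000, samples_per_pop=15, seed=42)
    gm, panel, truth = simulate_tree_panel(spec)
    return gm, panel, truth


def make_gm(dosage, positions=None, qual=None, chrom="chr1", samples=None,
            contig_length=None):
    """Small-matrix helper for hand-built cases."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if qual is None:
        qual = np.full(n_sites, 50.0)
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=chrom, positions=np.asarray(positions), ref=["A"] * n_sites,
        alt=[("G",)] * n_sites, qual=np.asarray(qual, float), dosage=dosage,
        samples=samples, contig_length=contig_length,
    )
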