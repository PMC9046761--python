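"""Runs of homozygosity via a two-state hidden Markov model.

Per individual, each usable site emits its genotype from one of two
states: non-autozygous (Hardy–Weinberg at the site's allele frequency f)
or autozygous (the two chromosomes are copies, so heterozygotes appear
only through genotyping error ε). Transitions between adjacent usable
sites d bp apart switch state with probability 1 − exp(−t·d). Viterbi
decoding (ties broken toward non-autozygous) yields maximal autozygous
runs; per-individual and per-population summaries report NROH, SROH and
FROH = SROH(runs > 50 kb) / genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationPanel

HW_STATE, AZ_STATE = 0, 1
DEFAULT_ERROR_RATE = 0.005
DEFAULT_TRANSITION = 1e-8   # per-bp state-switch hazard
FROH_MIN_LENGTH = 50_000    # runs longer than this enter the FROH numerator


def emission_likelihoods(genotypes, freq, error_rate: float = DEFAULT_ERROR_RATE):
    """Per-site emission likelihoods, shape (n_sites, 2): [HW, autozygous].

    HW state: (1-f)^2 / 2f(1-f) / f^2 for dosage 0/1/2. Autozygous state:
    (1-f)(1-ε) / ε / f(1-ε). Missing genotypes emit 1 in both states
    (uninformative). Sites must already be restricted to f in (0,1).
    """
    g = np.asarray(genotypes)
    f = np.asarray(freq, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequencies must be in (0,1); pre-filter sites")
    hw = np.select(
        [g == 0, g == 1, g == 2],
        [(1 - f) ** 2, 2 * f * (1 - f), f**2],
        default=1.0,
    )
    az = np.select(
        [g == 0, g == 1, g == 2],
        [(1 - f) * (1 - error_rate), np.full_like(f, error_rate),
         f * (1 - error_rate)],
        default=1.0,
    )
    return np.stack([hw, az], axis=1)


def viterbi_decode(likelihoods, positions, transition: float = DEFAULT_TRANSITION):
    """Most probable two-state path; ties resolve toward non-autozygous.

    ``likelihoods`` is (n_sites, 2); adjacent sites at distance d switch
    state with probability s = 1 − exp(−t·d) (stay with 1 − s). Uniform
    initial state distribution.
    """
    ll = np.log(np.clip(np.asarray(likelihoods, dtype=float), 1e-300, None))
    n = ll.shape[0]
    if n == 0:
        raise ValueError("need at least one usable site")
    pos = np.asarray(positions)
    d = np.diff(pos).astype(float)
    p_switch = np.clip(1.0 - np.exp(-transition * d), 1e-300, 1.0 - 1e-12)
    log_sw = np.log(p_switch)
    log_st = np.log1p(-p_switch)

    back = np.zeros((n, 2), dtype=np.int8)
    s0, s1 = float(ll[0, 0]), float(ll[0, 1])
    e0, e1 = ll[:, 0].tolist(), ll[:, 1].tolist()
    lsw, lst = log_sw.tolist(), log_st.tolist()
    for i in range(1, n):
        stay0, come1 = s0 + lst[i - 1], s1 + lsw[i - 1]
        go1, stay1 = s0 + lsw[i - 1], s1 + lst[i - 1]
        # argmax with tie toward coming from HW (index 0)
        if stay0 >= come1:
            n0 = stay0 + e0[i]
        else:
            n0 = come1 + e0[i]
            back[i, 0] = 1
        if go1 >= stay1:
            n1 = go1 + e1[i]
        else:
            n1 = stay1 + e1[i]
            back[i, 1] = 1
        s0, s1 = n0, n1
    path = np.empty(n, dtype=np.int8)
    path[-1] = HW_STATE if s0 >= s1 else AZ_STATE
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def segments_from_path(path, positions, sample: str, chrom: str) -> pd.DataFrame:
    """Maximal autozygous runs as segments bounded by their supporting sites."""
    path = np.asarray(path)
    pos = np.asarray(positions)
    rows = []
    i = 0
    n = len(path)
    while i < n:
        if path[i] == AZ_STATE:
            j = i
            while j + 1 < n and path[j + 1] == AZ_STATE:
                j += 1
            rows.append({
                "SAMPLE": sample, "CHROM": chrom,
                "START": int(pos[i]), "END": int(pos[j]),
                "LENGTH_BP": int(pos[j] - pos[i] + 1),
                "NSITES": int(j - i + 1),
            })
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(rows, columns=["SAMPLE", "CHROM", "START", "END",
                                       "LENGTH_BP", "NSITES"])


def summarize(segments: pd.DataFrame, genome_length: int,
              min_length: int = FROH_MIN_LENGTH,
              panel: PopulationPanel | None = None,
              samples=None) -> pd.DataFrame:
    """Per-individual NROH/SROH/FROH and length-class counts.

    FROH counts only runs longer than ``min_length`` (default 50 kb) in
    its numerator, divided by ``genome_length``. Length classes tally
    runs < 500 kb, >= 50 kb and >= 1 Mb.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be > 0")
    if samples is None:
        samples = sorted(segments["SAMPLE"].unique()) if len(segments) else []
    rows = []
    for s in samples:
        seg = segments.loc[segments["SAMPLE"] == s, "LENGTH_BP"].to_numpy() \
            if len(segments) else np.array([], dtype=int)
        sroh = int(seg.sum())
        froh = float(seg[seg > min_length].sum()) / genome_length
        rows.append({
            "SAMPLE": s,
            "POP": panel.membership.get(s, "") if panel else "",
            "NROH": int(len(seg)),
            "SROH": sroh,
            "FROH": froh,
            "N_LT_500KB": int((seg < 500_000).sum()),
            "N_GE_50KB": int((seg >= 50_000).sum()),
            "N_GE_1MB": int((seg >= 1_000_000).sum()),
        })
    return pd.DataFrame(rows, columns=["SAMPLE", "POP", "NROH", "SROH", "FROH",
                                       "N_LT_500KB", "N_GE_50KB", "N_GE_1MB"])


@dataclass
class RohScan:
    segments: pd.DataFrame
    summary: pd.DataFrame
    population_summary: pd.DataFrame


def detect_roh(gm: GenotypeMatrix, panel: PopulationPanel | None = None,
               error_rate: float = DEFAULT_ERROR_RATE,
               transition: float = DEFAULT_TRANSITION,
               genome_length: int | None = None,
               min_length: int = FROH_MIN_LENGTH,
               freq_by_population: bool = False) -> RohScan:
    """Decode autozygous segments for every sample and summarize.

    Allele frequencies come from the analyzed panel itself — pooled over
    all samples by default, or per population with
    ``freq_by_population`` — since no external frequency resource is
    assumed. Sites monomorphic in the frequency panel are skipped.
    """
    if genome_length is None:
        genome_length = gm.contig_length
        if genome_length is None:
            genome_length = int(gm.positions[-1])
    seg_frames = []
    if freq_by_population and panel is not None:
        pop_of = {s: panel.membership.get(s) for s in gm.samples}
    for j, sample in enumerate(gm.samples):
        if freq_by_population and panel is not None and pop_of[sample]:
            idx = panel.indices_in(gm, pop_of[sample])
            f = gm.alt_frequency(idx)
        else:
            f = gm.alt_frequency()
        usable = (f > 0) & (f < 1) & (gm.dosage[:, j] != MISSING)
        if not usable.any():
            continue
        lik = emission_likelihoods(gm.dosage[usable, j], f[usable], error_rate)
        path = viterbi_decode(lik, gm.positions[usable], transition)
        seg_frames.append(segments_from_path(path, gm.positions[usable],
                                             sample, gm.chrom))
    segments = (pd.concat(seg_frames, ignore_index=True) if seg_frames
                else segments_from_path([], [], "", gm.chrom))
    summary = summarize(segments, genome_length, min_length,
                        panel=panel, samples=gm.samples)
    if panel is not None and len(summary):
        pop_summary = (
            summary.groupby("POP", as_index=False)
            .agg(N_INDIVIDUALS=("SAMPLE", "count"), MEAN_NROH=("NROH", "mean"),
                 MEAN_SROH=("SROH", "mean"), MEAN_FROH=("FROH", "mean"))
        )
    else:
        pop_summary = pd.DataFrame(
            columns=["POP", "N_INDIVIDUALS", "MEAN_NROH", "MEAN_SROH", "MEAN_FROH"])
    return RohScan(segments=segments, summary=summary,
                   population_summary=pop_summary)
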