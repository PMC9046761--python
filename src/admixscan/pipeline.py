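"""Pipeline orchestration: filter once, then run the requested scans.

A RunConfig (from a YAML file and/or CLI flags) drives
filter → {fst, dstat, roh, ld, pca} on one VCF + panel; every stage
writes a TSV under the output directory and a JSON manifest records
input checksums, parameters and the seed so a run can be replayed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core import PopulationPanel
from .dstat import DEFAULT_BLOCK_SIZE, run_trio, trios_table
from .fst import DEFAULT_SPAN, DEFAULT_STEP, group_contrast
from .ld import DEFAULT_BIN_WIDTH, DEFAULT_MAF, DEFAULT_MAX_DIST, decay_curve
from .pca import run_pca
from .roh import DEFAULT_ERROR_RATE, DEFAULT_TRANSITION, FROH_MIN_LENGTH, detect_roh
from .vcfio import filter_sites, read_vcf

log = logging.getLogger("admixscan")

STAGES = ("fst", "dstat", "roh", "ld", "pca")


@dataclass
class RunConfig:
    vcf: str = ""
    panel: str = ""
    outdir: str = "admixscan_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    # fst
    case: list = field(default_factory=list)
    control: list = field(default_factory=list)
    fst_span: int = DEFAULT_SPAN
    fst_step: int = DEFAULT_STEP
    # dstat
    trios: list = field(default_factory=list)  # each [P1, P2, P3, OUTGROUP]
    block_size: int = DEFAULT_BLOCK_SIZE
    # roh
    roh_error_rate: float = DEFAULT_ERROR_RATE
    roh_transition: float = DEFAULT_TRANSITION
    roh_min_length: int = FROH_MIN_LENGTH
    genome_length: int | None = None
    # ld
    ld_populations: list = field(default_factory=list)  # empty -> all pops
    ld_max_dist: int = DEFAULT_MAX_DIST
    ld_bin_width: int = DEFAULT_BIN_WIDTH
    ld_maf: float = DEFAULT_MAF
    # pca
    pca_k: int = 10
    pca_exclude: list = field(default_factory=list)


def validate_config(raw: dict) -> RunConfig:
    """Normalize a raw mapping into a RunConfig; one error per violation."""
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    errors = []
    for st in cfg.stages:
        if st not in STAGES:
            errors.append(f"unknown stage {st!r}")
    if set(cfg.case) & set(cfg.control):
        errors.append("case and control population lists overlap")
    for trio in cfg.trios:
        if len(trio) != 4 or len(set(trio)) != 4:
            errors.append(f"trio {trio!r} must name four distinct populations")
    if cfg.fst_span <= 0 or cfg.fst_step <= 0:
        errors.append("fst_span and fst_step must be > 0")
    if cfg.block_size <= 0:
        errors.append("block_size must be > 0")
    if cfg.pca_k < 1:
        errors.append("pca_k must be >= 1")
    if errors:
        raise ValueError("; ".join(errors))
    return cfg


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """YAML config + flag overrides (flags win)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {"vcf": _sha256(cfg.vcf), "panel": _sha256(cfg.panel)},
        "stages": {},
        "outputs": [],
    }

    def _write(df, name):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        manifest["outputs"].append(name)

    try:
        gm = read_vcf(cfg.vcf)
        panel = PopulationPanel.from_file(cfg.panel)
        gm_f, report = filter_sites(gm)
        _write(report, "filter_report.tsv")
        log.info("filter: %d -> %d sites", gm.n_sites, gm_f.n_sites)
        manifest["stages"]["filter"] = {
            "sites_in": gm.n_sites, "sites_out": gm_f.n_sites}

        if "fst" in cfg.stages and cfg.case and cfg.control:
            win = group_contrast(gm_f, panel, cfg.case, cfg.control,
                                 span=cfg.fst_span, step=cfg.fst_step)
            _write(win, "fst_windows.tsv")
            manifest["stages"]["fst"] = {
                "span": cfg.fst_span, "step": cfg.fst_step,
                "n_windows": int(len(win))}

        if "dstat" in cfg.stages and cfg.trios:
            results = [run_trio(gm_f, panel, *trio, block_size=cfg.block_size)
                       for trio in cfg.trios]
            _write(trios_table(results), "dstat.tsv")
            manifest["stages"]["dstat"] = {
                "block_size": cfg.block_size, "n_trios": len(results)}

        if "roh" in cfg.stages:
            scan = detect_roh(gm_f, panel, error_rate=cfg.roh_error_rate,
                              transition=cfg.roh_transition,
                              genome_length=cfg.genome_length,
                              min_length=cfg.roh_min_length)
            _write(scan.segments, "roh_segments.tsv")
            _write(scan.summary, "roh_summary.tsv")
            _write(scan.population_summary, "roh_population_summary.tsv")
            manifest["stages"]["roh"] = {
                "error_rate": cfg.roh_error_rate,
                "transition": cfg.roh_transition,
                "n_segments": int(len(scan.segments))}

        if "ld" in cfg.stages:
            import pandas as pd
            pops = cfg.ld_populations or panel.populations
            frames = [decay_curve(gm_f, panel, p, max_dist=cfg.ld_max_dist,
                                  bin_width=cfg.ld_bin_width,
                                  maf=cfg.ld_maf).to_frame()
                      for p in pops]
            _write(pd.concat(frames, ignore_index=True), "ld_decay.tsv")
            manifest["stages"]["ld"] = {
                "max_dist": cfg.ld_max_dist, "bin_width": cfg.ld_bin_width,
                "populations": list(pops)}

        if "pca" in cfg.stages:
            import pandas as pd
            res = run_pca(gm_f, panel, exclude_pops=cfg.pca_exclude or None,
                          k=cfg.pca_k)
            _write(res.scores_frame(panel), "pca_scores.tsv")
            _write(pd.DataFrame({
                "COMPONENT": [f"PC{i+1}" for i in range(len(res.eigenvalues))],
                "EIGENVALUE": res.eigenvalues,
                "VARIANCE_FRACTION": res.variance_fraction,
            }), "pca_eigenvalues.tsv")
            manifest["stages"]["pca"] = {
                "k": int(res.scores.shape[1]),
                "n_sites_used": int(len(res.sites_used))}
    finally:
        # config echo + (possibly partial) manifest always land on disk
        with open(outdir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
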