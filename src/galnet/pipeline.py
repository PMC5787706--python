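"""End-to-end orchestration: synthesis/ingest -> gating -> statistics ->
grid fitting -> landscape placement -> report bundle.

Every stage is a thin call into the library modules; the pipeline adds
configuration loading, logging, seed bookkeeping and a provenance manifest
so a report is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cytometry, inference, meanfield, simulate, synth
from .params import (NetworkParameters, alternative_parameter_sets,
                     default_parameters, load_parameters)

log = logging.getLogger("galnet")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    outdir: Path
    seed: int = 0
    params_file: Path | None = None
    strains: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"REF": (140.0, 0.055), "VAR": (40.0, 0.055)})
    reference_strain: str = "REF"
    concentrations: tuple[float, ...] = (0.05, 0.1, 0.5)
    time_grid: tuple[float, ...] = synth.TWELVE_POINT_GRID
    replicates: int = 2
    events_per_sample: int = 4000
    plate_offsets: dict[str, float] = field(default_factory=lambda: {"P1": 0.0, "P2": 8.0})
    min_cells: int = 3000
    backend: str = "shortcut"
    sim_cells: int = 500
    n_fixed_sets: int = 1
    grid_points: tuple[int, int] = (15, 15)
    n_cells_fit: int = 150
    holdout_gal: float | None = 0.2
    landscape_gal: float | None = None
    landscape_points: tuple[int, int] = (5, 5)
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        kw = dict(raw)
        if "outdir" not in kw:
            raise ValueError("config must define 'outdir'")
        kw["outdir"] = Path(kw["outdir"])
        if kw.get("params_file"):
            pf = Path(kw["params_file"])
            if not pf.exists():
                raise FileNotFoundError(f"parameter file not found: {pf}")
            kw["params_file"] = pf
        if "strains" in kw:
            kw["strains"] = {k: tuple(v) for k, v in kw["strains"].items()}
        for key in ("concentrations", "time_grid", "grid_points", "landscape_points"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return inner
    return wrap


@_stage("synth")
def _synthesize(cfg: RunConfig, params: NetworkParameters):
    design = synth.StudyDesign(
        strains=cfg.strains, concentrations=cfg.concentrations,
        time_grid=cfg.time_grid, replicates=cfg.replicates,
        events_per_sample=cfg.events_per_sample,
        plate_offsets=cfg.plate_offsets, seed=cfg.seed)
    return synth.generate_study(design, params, backend=cfg.backend,
                                sim_cells=cfg.sim_cells)


@_stage("gate")
def _gate(cfg: RunConfig, events):
    min_cells = min(cfg.min_cells, int(0.5 * cfg.events_per_sample))
    return cytometry.gate_events(events, min_cells=min_cells)


@_stage("stats")
def _stats(cfg: RunConfig, gated, controls):
    normalized, report = cytometry.normalize_samples(gated, controls)
    tidy, series = cytometry.analyze_study(normalized)
    return normalized, report, tidy, series


@_stage("fit")
def _fit(cfg: RunConfig, series, params):
    sets = dict(list(alternative_parameter_sets().items())[: cfg.n_fixed_sets])
    if cfg.params_file is not None:
        sets = {"set1": params, **{k: v for k, v in sets.items() if k != "set1"}}
    obs_by_strain: dict[str, dict[float, "inference.InducibilitySeries"]] = {}
    for (strain, gal), ser in series.items():
        if strain == "control":
            continue
        obs_by_strain.setdefault(strain, {})[gal] = ser
    grid_factory = lambda: inference.FitGrid.default(*cfg.grid_points)
    fits, summary = inference.multi_fit(
        obs_by_strain, sets, grid_factory, cfg.reference_strain,
        n_cells=cfg.n_cells_fit, seed=cfg.seed + 17)
    return fits, summary


@_stage("holdout")
def _holdout(cfg: RunConfig, fits):
    rows = []
    grid = np.asarray(cfg.time_grid, dtype=float)
    for fit in fits:
        ser = inference.predict_holdout(fit, cfg.holdout_gal, grid)
        for t, f, s in zip(ser.times, ser.fraction_on, ser.sem):
            rows.append(dict(strain=fit.strain, set_id=fit.fixed_param_set_id,
                             gal=cfg.holdout_gal, time_min=t,
                             fraction_on=f, sem=s))
    return pd.DataFrame(rows)


@_stage("landscape")
def _landscape(cfg: RunConfig, params):
    n_r, n_k = cfg.landscape_points
    rho_grid = np.logspace(1, 3, n_r)
    kgal_grid = np.logspace(np.log10(0.005), np.log10(0.5), n_k)
    lsc = meanfield.landscape(rho_grid, kgal_grid, cfg.landscape_gal, params,
                              n_cells=400, seed=cfg.seed + 29)
    rows = []
    for i, r in enumerate(rho_grid):
        for j, k in enumerate(kgal_grid):
            rows.append(dict(rho=r, kgal=k, label=lsc.labels[i, j]))
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full allele-portrait pipeline and write the report bundle.

    Returns a manifest dict; all tables are written under cfg.outdir.
    Partial outputs are retained if a later stage fails.
    """
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    params = (load_parameters(cfg.params_file) if cfg.params_file
              else default_parameters())

    events, controls, truth, meta = _synthesize(cfg, params)
    truth.to_csv(outdir / "truth.csv", index=False)

    gated, qc = _gate(cfg, events)
    qc.to_json(outdir / "qc.json", orient="records", indent=2)

    normalized, norm_report, tidy, series = _stats(cfg, gated, controls)
    tidy.to_csv(outdir / "curves.csv", index=False)

    fits, summary = _fit(cfg, series, params)
    fit_records = [
        dict(strain=f.strain, set_id=f.fixed_param_set_id, rho_hat=f.rho_hat,
             kgal_hat=f.kgal_hat, rho_err_log10=f.rho_err_log10,
             kgal_err_log10=f.kgal_err_log10, chi2_min=f.chi2_min,
             unidentifiable=f.unidentifiable, seed=f.seed, n_cells=f.n_cells)
        for f in fits
    ]
    (outdir / "fits.json").write_text(json.dumps(fit_records, indent=2))
    rel = {set_id: {s: dict(rho_rel=a.rho_rel, kgal_rel=a.kgal_rel,
                            rho=a.rho, kgal=a.kgal)
                    for s, a in by_strain.items()}
           for set_id, by_strain in summary["relative"].items()}
    (outdir / "relative.json").write_text(json.dumps(
        {"relative": rel, "dispersion": summary["dispersion"]}, indent=2))

    # allele coordinates for landscape placement: relative (rho, Kgal) per
    # strain with the spread across fixed-parameter sets as error bars
    allele_rows = []
    for strain, d in summary["dispersion"].items():
        allele_rows.append(dict(strain=strain,
                                rho_rel=d["rho_rel_median"],
                                rho_rel_sd=d["rho_rel_sd"],
                                kgal_rel=d["kgal_rel_median"],
                                kgal_rel_sd=d["kgal_rel_sd"]))
    pd.DataFrame(allele_rows).to_csv(outdir / "alleles.csv", index=False)

    if cfg.holdout_gal is not None:
        holdout = _holdout(cfg, fits)
        holdout.to_csv(outdir / "holdout.csv", index=False)

    if cfg.landscape_gal is not None:
        lsc = _landscape(cfg, params)
        lsc.to_csv(outdir / "landscape.csv", index=False)

    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "normalization": norm_report,
        "runtime_s": round(time.time() - t_start, 2),
        "outputs": sorted({p.name for p in outdir.iterdir()} | {"manifest.json"}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete in %.1fs", manifest["runtime_s"])
    return manifest
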