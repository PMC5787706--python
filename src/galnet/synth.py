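"""Synthetic flow-cytometry study generator.

Emulates the statistical structure of FACSCalibur event tables acquired in a
strain x galactose x time x replicate x plate design: OFF/ON fluorescence
subpopulations whose ON fraction follows the network model, autofluorescence,
log-normal measurement noise, 10-bit channel saturation, density-gateable
FSC/SSC clouds with debris/doublet outliers, additive plate offsets, and 24
control replicates per plate.  Ground truth (ON labels and fractions,
generating parameters) is emitted alongside so the gating -> statistics ->
inference pipeline is testable end to end without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .cytometry import CHANNEL_MAX, REQUIRED_COLUMNS, EventTable, SchemaError
from .params import NetworkParameters

TWELVE_POINT_GRID = (0, 10, 20, 30, 40, 60, 80, 100, 130, 160, 205, 250)
SIX_POINT_GRID = (0, 30, 60, 80, 130, 210)


@dataclass
class StudyDesign:
    """Sampling design of a synthetic induction study.

    strains maps strain name -> (rho_Gal3, Kgal); plate_offsets maps plate
    name -> additive FL1 offset.  Each plate carries `n_controls` control
    replicates of an OFF-state reference so plate effects are estimable.
    """

    strains: dict[str, tuple[float, float]]
    concentrations: tuple[float, ...] = (0.05, 0.1, 0.5)
    time_grid: tuple[float, ...] = TWELVE_POINT_GRID
    replicates: int = 6
    events_per_sample: int = 10_000
    plate_offsets: dict[str, float] = field(default_factory=lambda: {"P1": 0.0})
    n_controls: int = 24
    control_events: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_sample < 1:
            raise ValueError("events_per_sample must be >= 1")
        if not self.strains:
            raise ValueError("design needs at least one strain")
        if len(self.time_grid) < 2 or list(self.time_grid) != sorted(self.time_grid):
            raise ValueError("time_grid must be ascending with >= 2 points")


@dataclass
class NoiseModel:
    """Measurement model mapping reporter counts to channel units.

    FL1 = autofluorescence + gain * signal * exp(eps), eps ~ N(0, cv^2),
    clipped to the 10-bit range [0, 1023].  FSC/SSC are a correlated Gaussian
    cell cloud plus a fraction of outlier (debris/doublet) events.
    """

    autofluorescence_mean: float = 6.0
    autofluorescence_sd: float = 2.0
    gain: float = 1.0
    measurement_cv: float = 0.05
    fsc_mean: float = 480.0
    fsc_sd: float = 55.0
    ssc_mean: float = 420.0
    ssc_sd: float = 60.0
    fsc_ssc_corr: float = 0.55
    outlier_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")


def _scatter_cloud(rng: np.random.Generator, n: int, noise: NoiseModel):
    cov = np.array([
        [noise.fsc_sd**2, noise.fsc_ssc_corr * noise.fsc_sd * noise.ssc_sd],
        [noise.fsc_ssc_corr * noise.fsc_sd * noise.ssc_sd, noise.ssc_sd**2],
    ])
    xy = rng.multivariate_normal([noise.fsc_mean, noise.ssc_mean], cov, size=n)
    out = rng.random(n) < noise.outlier_fraction
    n_out = int(out.sum())
    if n_out:
        xy[out] = rng.uniform([0, 0], [CHANNEL_MAX, CHANNEL_MAX], size=(n_out, 2))
    return (np.clip(np.rint(xy[:, 0]), 0, CHANNEL_MAX),
            np.clip(np.rint(xy[:, 1]), 0, CHANNEL_MAX))


def _fl1_from_signal(rng: np.random.Generator, signal: np.ndarray,
                     noise: NoiseModel, offset: float):
    eps = rng.normal(0.0, noise.measurement_cv, size=signal.size)
    auto = rng.normal(noise.autofluorescence_mean, noise.autofluorescence_sd,
                      size=signal.size)
    raw = auto + noise.gain * signal * np.exp(eps) + offset
    return np.clip(np.rint(raw), 0, CHANNEL_MAX), float(np.mean(raw > CHANNEL_MAX))


def _assign_plates(design: StudyDesign) -> dict[float, str]:
    """Time points are acquired plate by plate (the multi-plate layout of the
    twelve-point design): split the time grid into contiguous blocks."""
    plates = list(design.plate_offsets)
    blocks = np.array_split(np.asarray(design.time_grid, dtype=float), len(plates))
    return {float(t): plates[k] for k, block in enumerate(blocks) for t in block}


def generate_study(design: StudyDesign, params: NetworkParameters,
                   noise: NoiseModel | None = None, backend: str = "shortcut",
                   sim_cells: int = 500
                   ) -> tuple[EventTable, EventTable, pd.DataFrame, dict]:
    """Generate event tables for a full study plus ground truth.

    Both backends run the exact simulator once per strain x concentration
    and draw each replicate's events from the per-time OFF/ON signal pools
    with Bernoulli(true fraction) labels; backend="ssa" sizes the simulated
    pool at one cell per event, backend="shortcut" at `sim_cells` cells —
    identical schema and ground truth, far cheaper.  Returns
    (events, controls, truth, meta).
    """
    if noise is None:
        noise = NoiseModel()
    if backend not in ("ssa", "shortcut"):
        raise ValueError(f"unknown backend {backend!r}")
    rng = np.random.default_rng(design.seed)
    plate_of_time = _assign_plates(design)
    grid = np.asarray(design.time_grid, dtype=float)

    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for strain, (rho, kgal) in sorted(design.strains.items()):
        p = params.with_gal3(rho=float(rho), kgal=float(kgal))
        n_sim = design.events_per_sample if backend == "ssa" else sim_cells
        for gal in design.concentrations:
            pop = simulate.burn_in(p, n_sim, seed=design.seed)
            ens = simulate.simulate_induction(pop, float(gal), grid,
                                              seed=design.seed + 1)
            thr = simulate.ensemble_threshold(ens)
            for ti, t in enumerate(grid):
                sig_pool = ens.signals[:, ti]
                on_pool = sig_pool[sig_pool > thr]
                off_pool = sig_pool[sig_pool <= thr]
                f_true = float(np.mean(sig_pool > thr))
                for rep in range(1, design.replicates + 1):
                    n_ev = design.events_per_sample
                    is_on = rng.random(n_ev) < f_true
                    if not on_pool.size:
                        is_on[:] = False
                    sig = np.empty(n_ev)
                    if on_pool.size:
                        sig[is_on] = rng.choice(on_pool, size=int(is_on.sum()))
                    pool = off_pool if off_pool.size else sig_pool
                    sig[~is_on] = rng.choice(pool, size=int((~is_on).sum()))
                    plate = plate_of_time[float(t)]
                    offset = design.plate_offsets[plate]
                    fl1, sat = _fl1_from_signal(rng, sig, noise, offset)
                    fsc, ssc = _scatter_cloud(rng, sig.size, noise)
                    sample_id = f"{strain}_g{gal}_t{int(t)}_r{rep}"
                    rows.append(pd.DataFrame({
                        "fsc": fsc, "ssc": ssc, "fl1": fl1,
                        "strain": strain, "gal": float(gal), "time_min": float(t),
                        "replicate": rep, "plate": plate, "sample_id": sample_id,
                    }))
                    truth_rows.append(dict(
                        sample_id=sample_id, strain=strain, gal=float(gal),
                        time_min=float(t), replicate=rep, plate=plate,
                        schedule_fraction=f_true,
                        true_fraction=float(np.mean(is_on)),
                        saturated_fraction=sat,
                        rho_gal3=float(rho), kgal=float(kgal), threshold=thr,
                        threshold_fl1=noise.autofluorescence_mean
                        + noise.gain * thr,
                    ))

    # 24 OFF-reference control replicates per plate
    ctrl_rows = []
    for plate, offset in design.plate_offsets.items():
        for rep in range(1, design.n_controls + 1):
            n_ev = design.control_events
            fl1, _ = _fl1_from_signal(rng, np.zeros(n_ev), noise, offset)
            fsc, ssc = _scatter_cloud(rng, n_ev, noise)
            ctrl_rows.append(pd.DataFrame({
                "fsc": fsc, "ssc": ssc, "fl1": fl1,
                "strain": "control", "gal": 0.0, "time_min": 0.0,
                "replicate": rep, "plate": plate,
                "sample_id": f"control_{plate}_r{rep}",
            }))

    events = EventTable(pd.concat(rows, ignore_index=True))
    controls = EventTable(pd.concat(ctrl_rows, ignore_index=True))
    truth = pd.DataFrame(truth_rows)
    meta = {
        "seed": design.seed, "backend": backend,
        "strains": {s: list(v) for s, v in design.strains.items()},
        "plate_offsets": dict(design.plate_offsets),
        "concentrations": list(design.concentrations),
        "time_grid": [float(t) for t in design.time_grid],
    }
    return events, controls, truth, meta


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_events(table: EventTable, path: str | Path) -> None:
    """Write an event table as CSV with a deterministic column order."""
    cols = list(REQUIRED_COLUMNS)
    extra = [c for c in table.df.columns if c not in cols]
    table.df[cols + extra].to_csv(path, index=False)


def read_events(path: str | Path) -> EventTable:
    """Read an event table, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event file {path} missing column(s): {missing}")
    return EventTable(df)


def write_study(outdir: str | Path, events: EventTable, controls: EventTable,
                truth: pd.DataFrame, meta: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_events(events, outdir / "events.csv")
    write_events(controls, outdir / "controls.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    (outdir / "design.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
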