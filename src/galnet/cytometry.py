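"""Flow-cytometry distribution analysis.

Implements the event-level pipeline used to turn per-cell FL1 readouts into
population statistics: saturation removal and density gating, plate-effect
correction against control replicates, Gaussian-mixture amplitude, the
equal-misclassification ON/OFF threshold, and inducibility (fraction of ON
cells) with binomial errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.mixture import GaussianMixture

from .series import InducibilitySeries, binomial_series

CHANNEL_MAX = 1023
REQUIRED_COLUMNS = ("fsc", "ssc", "fl1", "strain", "gal", "time_min",
                    "replicate", "plate", "sample_id")


class SchemaError(ValueError):
    """Raised when an event table is missing required columns."""


@dataclass
class EventTable:
    """Per-cell cytometry events with sample annotations.

    Channels fsc/ssc/fl1 are on the instrument's 10-bit scale [0, 1023]
    before normalization; FL1 may become negative after baseline subtraction.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"event table missing column(s): {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def samples(self):
        return self.df.groupby("sample_id", sort=True)


@dataclass
class MixtureFit:
    """1- or 2-component Gaussian fit of an FL1 distribution.

    For two components the convention is mu_on > mu_off.  For one component
    the estimates are stored as mu_all/sigma_all.
    """

    n_components: int
    w_off: float
    w_on: float
    mu_off: float
    mu_on: float
    sigma_off: float
    sigma_on: float
    mu_all: float
    sigma_all: float
    loglik: float
    converged: bool


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

def _density_gate_mask(fsc: np.ndarray, ssc: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Keep events inside the highest-density region of the (FSC, SSC) plane
    containing `keep_fraction` of events.

    Density: 128x128 histogram smoothed with a Gaussian kernel at Scott's
    bandwidth; the retained region is the level set of per-event density
    above the (1 - keep_fraction) quantile.
    """
    n = fsc.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    nbins = 128
    lo_f, hi_f = fsc.min() - 1e-9, fsc.max() + 1e-9
    lo_s, hi_s = ssc.min() - 1e-9, ssc.max() + 1e-9
    hist, fe, se = np.histogram2d(fsc, ssc, bins=nbins,
                                  range=[[lo_f, hi_f], [lo_s, hi_s]])
    # Scott bandwidth in data units -> bin units
    factor = n ** (-1.0 / 6.0)
    bw_f = max(factor * fsc.std(), 1e-12) / max((hi_f - lo_f) / nbins, 1e-12)
    bw_s = max(factor * ssc.std(), 1e-12) / max((hi_s - lo_s) / nbins, 1e-12)
    dens = ndimage.gaussian_filter(hist, sigma=(bw_f, bw_s), mode="constant")
    fi = np.clip(np.digitize(fsc, fe) - 1, 0, nbins - 1)
    si = np.clip(np.digitize(ssc, se) - 1, 0, nbins - 1)
    d = dens[fi, si]
    level = np.quantile(d, 1.0 - keep_fraction)
    return d >= level


def gate_events(events: EventTable, keep_fraction: float = 0.60,
                min_cells: int = 3000) -> tuple[EventTable, pd.DataFrame]:
    """Per-sample QC and density gating.

    (i) events saturated on any channel (value 0 or 1023) are removed;
    (ii) a 2D kernel density on (FSC, SSC) defines the peak-density perimeter
    containing `keep_fraction` of the unsaturated events, and only events
    inside it are kept; (iii) samples with fewer than `min_cells` retained
    cells are dropped.  Returns the gated table and a per-sample QC report.
    """
    kept_parts: list[pd.DataFrame] = []
    qc_rows: list[dict] = []
    for sample_id, sub in events.samples():
        n_raw = len(sub)
        ch = sub[["fsc", "ssc", "fl1"]].to_numpy()
        unsat = ~np.any((ch <= 0) | (ch >= CHANNEL_MAX), axis=1)
        sub_u = sub[unsat]
        row = {"sample_id": sample_id, "n_events": n_raw,
               "n_unsaturated": len(sub_u)}
        if len(sub_u) == 0:
            row.update(kept=False, n_gated=0, reason="no unsaturated events")
            qc_rows.append(row)
            continue
        mask = _density_gate_mask(sub_u["fsc"].to_numpy(float),
                                  sub_u["ssc"].to_numpy(float), keep_fraction)
        gated = sub_u[mask]
        if len(gated) < min_cells:
            row.update(kept=False, n_gated=len(gated),
                       reason=f"fewer than {min_cells} cells after gating")
        else:
            row.update(kept=True, n_gated=len(gated), reason="")
            kept_parts.append(gated)
        qc_rows.append(row)
    out = pd.concat(kept_parts, ignore_index=True) if kept_parts else \
        events.df.iloc[0:0].copy()
    return EventTable(out), pd.DataFrame(qc_rows)


# ---------------------------------------------------------------------------
# Plate correction and baseline
# ---------------------------------------------------------------------------

class NormalizationError(ValueError):
    """Raised when plate correction is requested without usable controls."""


def normalize_samples(events: EventTable, controls: EventTable | None = None,
                      baseline: bool = True) -> tuple[EventTable, dict]:
    """Plate-effect correction from control replicates, then t=0 baseline.

    With more than one plate, the per-replicate mean FL1 of the plate
    controls is submitted to a one-way fixed-effect ANOVA on plate; the
    per-plate offsets (control plate mean minus grand mean) are subtracted
    from every FL1 value of that plate.  Single-plate designs skip the plate
    step.  Finally the per-strain mean FL1 at t = 0 is subtracted.
    """
    df = events.df.copy()
    plates = sorted(df["plate"].unique())
    report: dict = {"plates": plates, "offsets": {}, "anova_F": None,
                    "anova_p": None, "baseline": {}}
    if len(plates) > 1:
        if controls is None or len(controls.df) == 0:
            raise NormalizationError(
                "multi-plate design requires control replicates on every plate")
        cdf = controls.df
        missing = set(plates) - set(cdf["plate"].unique())
        if missing:
            raise NormalizationError(f"plates without controls: {sorted(missing)}")
        rep_means = (cdf.groupby(["plate", "replicate"])["fl1"]
                     .mean().reset_index())
        groups = [g["fl1"].to_numpy() for _, g in rep_means.groupby("plate")]
        F, p = stats.f_oneway(*groups)
        grand = rep_means["fl1"].mean()
        offsets = rep_means.groupby("plate")["fl1"].mean() - grand
        report["anova_F"], report["anova_p"] = float(F), float(p)
        report["offsets"] = {k: float(v) for k, v in offsets.items()}
        df["fl1"] = df["fl1"] - df["plate"].map(offsets).astype(float)
    if baseline:
        t0 = df[df["time_min"] == 0]
        if len(t0) == 0:
            raise NormalizationError("no t=0 sample present for baseline subtraction")
        base = t0.groupby("strain")["fl1"].mean()
        report["baseline"] = {k: float(v) for k, v in base.items()}
        df["fl1"] = df["fl1"] - df["strain"].map(base).astype(float)
    return EventTable(df), report


# ---------------------------------------------------------------------------
# Mixture model, amplitude, threshold, inducibility
# ---------------------------------------------------------------------------

def fit_fl1_mixture(values: np.ndarray, random_state: int = 0) -> MixtureFit:
    """Fit 1- and 2-component Gaussian models by EM and select between them.

    The two-component model is accepted only when it is decisively better
    (delta BIC > 10), both weights exceed 0.05 and the means are separated by
    more than twice the larger component sd — a reproducible surrogate for
    the by-eye unimodal/bimodal call.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 50:
        raise ValueError(f"need at least 50 values to fit a mixture, got {x.shape[0]}")
    rng_span = float(np.ptp(x))
    sigma_floor = max(1e-3 * rng_span, 1e-9)
    if rng_span == 0.0:
        m = float(x[0, 0])
        return MixtureFit(1, 1.0, 0.0, m, m, sigma_floor, sigma_floor,
                          m, sigma_floor, 0.0, True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm1 = GaussianMixture(1, n_init=1, random_state=random_state,
                              reg_covar=sigma_floor**2, tol=1e-8).fit(x)
        gm2 = GaussianMixture(2, n_init=5, random_state=random_state,
                              reg_covar=sigma_floor**2, tol=1e-8).fit(x)
    mu_all = float(gm1.means_[0, 0])
    sd_all = max(float(np.sqrt(gm1.covariances_[0, 0, 0])), sigma_floor)
    order = np.argsort(gm2.means_[:, 0])
    mu_lo, mu_hi = (float(gm2.means_[i, 0]) for i in order)
    sd_lo, sd_hi = (max(float(np.sqrt(gm2.covariances_[i, 0, 0])), sigma_floor)
                    for i in order)
    w_lo, w_hi = (float(gm2.weights_[i]) for i in order)
    dbic = gm1.bic(x) - gm2.bic(x)
    accept2 = (dbic > 10.0 and min(w_lo, w_hi) > 0.05
               and (mu_hi - mu_lo) > 2.0 * max(sd_lo, sd_hi))
    if accept2:
        return MixtureFit(2, w_lo, w_hi, mu_lo, mu_hi, sd_lo, sd_hi,
                          mu_all, sd_all, float(gm2.score(x) * x.shape[0]),
                          bool(gm2.converged_))
    return MixtureFit(1, 1.0, 0.0, mu_all, mu_all, sd_all, sd_all,
                      mu_all, sd_all, float(gm1.score(x) * x.shape[0]),
                      bool(gm1.converged_))


def response_amplitude(fit: MixtureFit) -> float:
    """Response amplitude A: mean expression of activated cells.

    A = mu_ALL for a unimodal distribution, A = mu_ON for a bimodal one
    (independent of the component weights).
    """
    return fit.mu_all if fit.n_components == 1 else fit.mu_on


def on_off_threshold(off: tuple[float, float], on: tuple[float, float]) -> float:
    """Equal-misclassification threshold t with P(X_ON < t) = P(X_OFF > t).

    For Gaussian references the defining equation has the closed form
    t = (mu_ON * sigma_OFF + mu_OFF * sigma_ON) / (sigma_OFF + sigma_ON).
    """
    mu_off, sd_off = off
    mu_on, sd_on = on
    if not (sd_off > 0 and sd_on > 0):
        raise ValueError("reference sds must be positive")
    if not mu_on > mu_off:
        raise ValueError("ON reference mean must exceed OFF reference mean")
    return (mu_on * sd_off + mu_off * sd_on) / (sd_off + sd_on)


def inducibility(values: np.ndarray, t: float) -> tuple[float, float]:
    """Fraction of ON cells, I = #{FL1 > t} / #total, with binomial SE."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty FL1 vector")
    frac = float(np.mean(v > t))
    sem = math.sqrt(frac * (1 - frac) / v.size)
    return frac, sem


# ---------------------------------------------------------------------------
# Study-level driver
# ---------------------------------------------------------------------------

def threshold_from_study(events: EventTable) -> float:
    """Derive the ON/OFF threshold from the study's own OFF and ON references.

    OFF reference: all cells acquired at t = 0.  ON reference: activated
    cells of unimodal late-time distributions (the latest time point of each
    strain x concentration whose distribution is unimodal and clearly above
    the OFF reference).
    """
    df = events.df
    off_vals = df.loc[df["time_min"] == 0, "fl1"].to_numpy(float)
    if off_vals.size < 50:
        raise ValueError("too few t=0 events for an OFF reference")
    mu_off, sd_off = float(off_vals.mean()), max(float(off_vals.std()), 1e-9)
    candidates = []
    for (_, _), sub in df[df["time_min"] > 0].groupby(["strain", "gal"]):
        late = sub[sub["time_min"] == sub["time_min"].max()]
        if len(late) < 50:
            continue
        fit = fit_fl1_mixture(late["fl1"].to_numpy(float))
        if fit.n_components == 1 and fit.mu_all > mu_off + 5 * sd_off:
            candidates.append((fit.mu_all, late["fl1"].to_numpy(float)))
    if not candidates:
        raise ValueError("no unimodal induced late-time distribution found "
                         "to serve as ON reference")
    # keep only fully induced candidates: partially induced mixtures that the
    # unimodal guard lets through have depressed means and inflated sds and
    # would drag the threshold into the OFF tail
    top = max(mu for mu, _ in candidates)
    on = np.concatenate([v for mu, v in candidates if mu >= 0.75 * top])
    thr = on_off_threshold((mu_off, sd_off),
                           (float(on.mean()), max(float(on.std()), 1e-9)))
    return max(thr, mu_off + 5 * sd_off)


def analyze_study(events: EventTable, threshold: float | None = None
                  ) -> tuple[pd.DataFrame, dict[tuple[str, float], InducibilitySeries]]:
    """Per strain x concentration inducibility series and per-sample amplitude.

    Returns a tidy frame (strain, gal, time_min, fraction_on, sem, n_cells,
    amplitude) and the corresponding InducibilitySeries keyed by
    (strain, gal).
    """
    if threshold is None:
        threshold = threshold_from_study(events)
    rows = []
    series: dict[tuple[str, float], InducibilitySeries] = {}
    for (strain, gal), sub in events.df.groupby(["strain", "gal"]):
        times = np.sort(sub["time_min"].unique())
        n_on, n_tot, amps = [], [], []
        for t in times:
            vals = sub.loc[sub["time_min"] == t, "fl1"].to_numpy(float)
            n_on.append(int(np.sum(vals > threshold)))
            n_tot.append(vals.size)
            amp = float("nan")
            if vals.size >= 50:
                amp = response_amplitude(fit_fl1_mixture(vals))
            amps.append(amp)
        ser = binomial_series(times, n_on, n_tot, strain=strain, gal=float(gal))
        ser.threshold = float(threshold)
        series[(strain, float(gal))] = ser
        for t, f, s, n, a in zip(times, ser.fraction_on, ser.sem, ser.n_cells, amps):
            rows.append(dict(strain=strain, gal=float(gal), time_min=float(t),
                             fraction_on=float(f), sem=float(s),
                             n_cells=int(n), amplitude=a, threshold=threshold))
    return pd.DataFrame(rows), series
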