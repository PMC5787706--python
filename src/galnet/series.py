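"""Inducibility time series: fraction of ON cells vs. time with binomial errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class InducibilitySeries:
    """Fraction of ON cells (reporter above the ON/OFF threshold) over time.

    times        minutes, ascending
    fraction_on  proportion of cells with signal above threshold, in [0, 1]
    sem          binomial standard error sqrt(I(1-I)/n) per time point
    n_cells      cells counted per time point
    strain, gal  annotations (gal in % w/v)
    """

    times: np.ndarray
    fraction_on: np.ndarray
    sem: np.ndarray
    n_cells: np.ndarray
    strain: str = ""
    gal: float = float("nan")
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_on = np.asarray(self.fraction_on, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_cells = np.asarray(self.n_cells)
        if not (self.times.shape == self.fraction_on.shape == self.sem.shape):
            raise ValueError("times, fraction_on and sem must have equal shapes")
        if np.any((self.fraction_on < 0) | (self.fraction_on > 1)):
            raise ValueError("fraction_on must lie in [0, 1]")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")

    def __len__(self) -> int:
        return self.times.size


def binomial_series(times, n_on, n_tot, strain="", gal=float("nan")) -> InducibilitySeries:
    """Build a series from ON counts and totals with binomial standard errors."""
    n_on = np.asarray(n_on, dtype=float)
    n_tot = np.asarray(n_tot, dtype=float)
    frac = np.divide(n_on, n_tot, out=np.zeros_like(n_on), where=n_tot > 0)
    sem = np.sqrt(np.clip(frac * (1 - frac), 0, None) / np.maximum(n_tot, 1))
    return InducibilitySeries(
        times=np.asarray(times, dtype=float),
        fraction_on=frac,
        sem=sem,
        n_cells=n_tot.astype(int),
        strain=strain,
        gal=gal,
    )
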