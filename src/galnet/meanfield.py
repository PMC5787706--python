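"""Mean-field companion of the stochastic model.

The deterministic reduction replaces promoter occupancy by its probability
p_on and molecule counts by their means:

    dp/dt = k_on (1 - p) - k_off p
    dm/dt = alpha + delta_alpha * p - beta m
    dP/dt = gamma m - mu P

with k_on / k_off evaluated from the same rate laws as the SSA.  It provides
steady states and a bistability scan over the (rho_Gal3, Kgal) plane, the
stochastic-simulation-based gradual/binary classifier, and the phenotypic
landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import simulate
from .params import NetworkParameters
from .ssa import GAL1, GAL3, GAL80, REPORTER

# state vector: [p_on(4), m(4), P(4), mature]; P[REPORTER] is immature GFP
STATE_DIM = 13


@dataclass
class MeanFieldState:
    """Deterministic state: promoter ON probabilities, mean mRNA, mean protein."""

    p_on: np.ndarray
    m: np.ndarray
    P: np.ndarray
    gfp_mature: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.p_on, self.m, self.P, [self.gfp_mature]])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "MeanFieldState":
        v = np.asarray(v, dtype=float)
        return cls(p_on=v[0:4].copy(), m=v[4:8].copy(), P=v[8:12].copy(),
                   gfp_mature=float(v[12]))


@dataclass
class PhenotypeLandscape:
    """Gradual/binary/intermediate labels (and optional bistability mask)
    over a log-spaced (rho_Gal3, Kgal) grid at one galactose concentration."""

    rho_grid: np.ndarray
    kgal_grid: np.ndarray
    gal: float
    labels: np.ndarray            # dtype=object matrix of labels
    bistable_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (self.rho_grid.size, self.kgal_grid.size)
        if self.labels.shape != expected:
            raise ValueError("labels shape must match grids")
        if self.bistable_mask is not None and self.bistable_mask.shape != expected:
            raise ValueError("bistable_mask shape must match grids")


def _rate_terms(P: np.ndarray, params: NetworkParameters, gal: float):
    s = params.shared
    f = gal / (gal + s.Kgal) if gal > 0 else 0.0
    x = (f * P[GAL1] / s.K1) ** 2 + (f * P[GAL3] / s.K3) ** 2
    y = (P[GAL80] / s.K80) ** 2
    return x, y


def mean_field_rhs(state: MeanFieldState, params: NetworkParameters,
                   gal: float) -> MeanFieldState:
    """Time derivatives of the mean-field state."""
    v = state.to_vector()
    dv = _rhs_vector(0.0, v, params, gal)
    return MeanFieldState.from_vector(dv)


def _rhs_vector(t: float, v: np.ndarray, params: NetworkParameters,
                gal: float) -> np.ndarray:
    p, m, P, M = v[0:4], v[4:8], v[8:12], v[12]
    x, y = _rate_terms(P, params, gal)
    s = params.shared
    dv = np.empty(STATE_DIM)
    for i, g in enumerate(params.genes):
        kon = s.k0_on * x ** g.n_sites
        koff = s.k0_off * y ** g.n_sites
        dv[i] = kon * (1.0 - p[i]) - koff * p[i]
        dv[4 + i] = g.alpha + g.delta_alpha * p[i] - g.beta * m[i]
        if i == REPORTER:
            dv[8 + i] = g.gamma * m[i] - (g.mu + s.nu_mat) * P[i]
        else:
            dv[8 + i] = g.gamma * m[i] - g.mu * P[i]
    rep = params.genes[REPORTER]
    dv[12] = s.nu_mat * P[REPORTER] - rep.mu * M
    return dv


def off_state(params: NetworkParameters) -> MeanFieldState:
    """Deterministic steady state with all promoters OFF (leak only)."""
    return _quasi_state(params, p_on=np.zeros(4))


def on_state(params: NetworkParameters) -> MeanFieldState:
    """Deterministic state with all promoters fully ON (used as a start)."""
    return _quasi_state(params, p_on=np.ones(4))


def _quasi_state(params: NetworkParameters, p_on: np.ndarray) -> MeanFieldState:
    s = params.shared
    m = np.array([(g.alpha + g.delta_alpha * p_on[i]) / g.beta
                  for i, g in enumerate(params.genes)])
    P = np.empty(4)
    for i, g in enumerate(params.genes):
        if i == REPORTER:
            P[i] = g.gamma * m[i] / (g.mu + s.nu_mat)
        else:
            P[i] = g.gamma * m[i] / g.mu
    rep = params.genes[REPORTER]
    M = s.nu_mat * P[REPORTER] / rep.mu
    return MeanFieldState(p_on=p_on.astype(float), m=m, P=P, gfp_mature=M)


def integrate(params: NetworkParameters, gal: float, time_grid: np.ndarray,
              state0: MeanFieldState | None = None) -> np.ndarray:
    """Integrate the mean-field ODE; returns states (n_times, STATE_DIM)."""
    if state0 is None:
        state0 = off_state(params)
    grid = np.asarray(time_grid, dtype=float)
    sol = solve_ivp(_rhs_vector, (grid[0], grid[-1]), state0.to_vector(),
                    t_eval=grid, args=(params, gal), method="LSODA",
                    rtol=1e-11, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return sol.y.T


def reporter_trajectory(params: NetworkParameters, gal: float,
                        time_grid: np.ndarray) -> np.ndarray:
    """Mean mature-reporter trajectory from the OFF steady state."""
    return integrate(params, gal, time_grid)[:, 12]


# ---------------------------------------------------------------------------
# Steady states and bistability
# ---------------------------------------------------------------------------

def _protein_residual(Pvec: np.ndarray, params: NetworkParameters,
                      gal: float) -> np.ndarray:
    """Self-consistency residual on (Gal1p, Gal3p, Gal80p).

    At a fixed point promoter occupancy and mRNA are explicit functions of
    the protein vector, so steady states solve a reduced 3-dimensional
    system; the reporter follows passively.
    """
    P = np.array([Pvec[0], Pvec[1], Pvec[2], 0.0])
    x, y = _rate_terms(P, params, gal)
    s = params.shared
    res = np.empty(3)
    for i in (GAL1, GAL3, GAL80):
        g = params.genes[i]
        kon = s.k0_on * x ** g.n_sites
        koff = s.k0_off * y ** g.n_sites
        p_on = kon / (kon + koff) if (kon + koff) > 0 else 0.0
        m = (g.alpha + g.delta_alpha * p_on) / g.beta
        res[i] = g.gamma * m / g.mu - Pvec[i]
    return res


def _full_state_from_proteins(Pvec: np.ndarray, params: NetworkParameters,
                              gal: float) -> MeanFieldState:
    P = np.array([Pvec[0], Pvec[1], Pvec[2], 0.0])
    x, y = _rate_terms(P, params, gal)
    s = params.shared
    p_on = np.empty(4)
    m = np.empty(4)
    for i, g in enumerate(params.genes):
        kon = s.k0_on * x ** g.n_sites
        koff = s.k0_off * y ** g.n_sites
        p_on[i] = kon / (kon + koff) if (kon + koff) > 0 else 0.0
        m[i] = (g.alpha + g.delta_alpha * p_on[i]) / g.beta
    Pfull = np.array([Pvec[0], Pvec[1], Pvec[2], 0.0])
    rep = params.genes[REPORTER]
    Pfull[REPORTER] = rep.gamma * m[REPORTER] / (rep.mu + s.nu_mat)
    M = s.nu_mat * Pfull[REPORTER] / rep.mu
    return MeanFieldState(p_on=p_on, m=m, P=Pfull, gfp_mature=M)


def _jacobian(v: np.ndarray, params: NetworkParameters, gal: float,
              eps: float = 1e-6) -> np.ndarray:
    n = v.size
    J = np.empty((n, n))
    f0 = _rhs_vector(0.0, v, params, gal)
    for j in range(n):
        dv = np.zeros(n)
        h = eps * max(abs(v[j]), 1.0)
        dv[j] = h
        J[:, j] = (_rhs_vector(0.0, v + dv, params, gal) - f0) / h
    return J


def steady_states(params: NetworkParameters, gal: float, n_restarts: int = 16,
                  seed: int = 0) -> list[MeanFieldState]:
    """Stable fixed points of the mean-field system.

    Multi-start root finding on the reduced protein system from OFF-like and
    ON-like starts plus random log-uniform restarts; duplicates are merged at
    relative tolerance 1e-6 and stability assessed from the eigenvalues of
    the finite-difference Jacobian of the full system.

    Raises RuntimeError if no start converges.
    """
    starts = [off_state(params).P[:3], on_state(params).P[:3]]
    rng = np.random.default_rng(seed)
    lo = np.maximum(off_state(params).P[:3], 1e-3)
    hi = np.maximum(on_state(params).P[:3], lo * 10)
    for _ in range(n_restarts):
        u = rng.uniform(size=3)
        starts.append(np.exp(np.log(lo) + u * (np.log(hi * 10) - np.log(lo))))

    roots: list[np.ndarray] = []
    any_converged = False
    for s0 in starts:
        sol = root(_protein_residual, s0, args=(params, gal), method="hybr",
                   options={"xtol": 1e-12})
        if not sol.success or np.any(sol.x < -1e-6):
            continue
        any_converged = True
        Pr = np.maximum(sol.x, 0.0)
        if not any(np.allclose(Pr, r, rtol=1e-6, atol=1e-8) for r in roots):
            roots.append(Pr)
    if not any_converged:
        raise RuntimeError("steady-state search failed to converge from any start")

    stable: list[MeanFieldState] = []
    for Pr in roots:
        st = _full_state_from_proteins(Pr, params, gal)
        eig = np.linalg.eigvals(_jacobian(st.to_vector(), params, gal))
        if np.all(eig.real < -1e-9):
            stable.append(st)
    return stable


def bistability_scan(rho_grid: np.ndarray, kgal_grid: np.ndarray,
                     params: NetworkParameters, gal: float) -> np.ndarray:
    """Boolean mask over the (rho_Gal3, Kgal) grid where the deterministic
    system has at least two stable fixed points.  Cells where the search
    fails entirely are left as False and reported via NaN-safe scanning."""
    rho_grid = np.asarray(rho_grid, dtype=float)
    kgal_grid = np.asarray(kgal_grid, dtype=float)
    if rho_grid.size < 1 or kgal_grid.size < 1:
        raise ValueError("grids must be non-empty")
    mask = np.zeros((rho_grid.size, kgal_grid.size), dtype=bool)
    for i, rho in enumerate(rho_grid):
        for j, kg in enumerate(kgal_grid):
            p = params.with_gal3(rho=float(rho), kgal=float(kg))
            try:
                states = steady_states(p, gal)
            except RuntimeError:
                continue
            mask[i, j] = len(states) >= 2
    return mask


# ---------------------------------------------------------------------------
# Gradual / binary classification and the phenotypic landscape
# ---------------------------------------------------------------------------

GRADUAL, BINARY, INTERMEDIATE, NO_RESPONSE = (
    "gradual", "binary", "intermediate", "none")

#: fraction band and minimum dwell used by the classifier (min)
CLASSIFY_LOW, CLASSIFY_HIGH, CLASSIFY_WINDOW = 0.1, 0.9, 40.0


def classify_series(times: np.ndarray, fraction: np.ndarray) -> str:
    """Label an ON-fraction time course.

    gradual      the ON fraction traverses 0.1 -> 0.9 in under 40 min
    binary       ON and OFF cells coexist (fraction within [0.1, 0.9]) for a
                 contiguous window of at least 40 min
    none         the fraction never reaches 0.1
    intermediate anything else
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(fraction, dtype=float)
    if np.max(f) < CLASSIFY_LOW:
        return NO_RESPONSE
    i10 = int(np.argmax(f >= CLASSIFY_LOW))
    reached_high = np.any(f >= CLASSIFY_HIGH)
    if reached_high:
        i90 = int(np.argmax(f >= CLASSIFY_HIGH))
        if times[i90] - times[i10] < CLASSIFY_WINDOW:
            return GRADUAL
    in_band = (f >= CLASSIFY_LOW) & (f <= CLASSIFY_HIGH)
    best = 0.0
    start = None
    for k in range(times.size):
        if in_band[k]:
            if start is None:
                start = times[k]
            best = max(best, times[k] - start)
        else:
            start = None
    if best >= CLASSIFY_WINDOW:
        return BINARY
    return INTERMEDIATE


def classify_response(params: NetworkParameters, gal: float,
                      n_cells: int = 400, seed: int = 0,
                      time_grid: np.ndarray | None = None,
                      population: simulate.Population | None = None) -> str:
    """Stochastic-simulation-based gradual/binary/intermediate label."""
    if n_cells < 200:
        raise ValueError("classification needs n_cells >= 200")
    if time_grid is None:
        time_grid = np.arange(0.0, 251.0, 5.0)
    ser = simulate.predicted_inducibility(params, gal, time_grid, n_cells,
                                          seed, population=population)
    return classify_series(ser.times, ser.fraction_on)


def landscape(rho_grid: np.ndarray, kgal_grid: np.ndarray, gal: float,
              params: NetworkParameters, n_cells: int = 400, seed: int = 0,
              include_bistability: bool = False) -> PhenotypeLandscape:
    """Phenotypic landscape: classify_response at every (rho, Kgal) grid cell.

    Burn-in populations are shared across the Kgal axis (the pre-induction
    state at [gal] = 0 does not depend on Kgal).
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    kgal_grid = np.asarray(kgal_grid, dtype=float)
    labels = np.empty((rho_grid.size, kgal_grid.size), dtype=object)
    for i, rho in enumerate(rho_grid):
        base = params.with_gal3(rho=float(rho))
        pop = simulate.burn_in(base, n_cells, seed)
        for j, kg in enumerate(kgal_grid):
            p = base.with_gal3(kgal=float(kg))
            pop_k = simulate.Population(pop.prom, pop.mrna, pop.prot,
                                        pop.mature, pop.efac, p, pop.t)
            labels[i, j] = classify_response(p, gal, n_cells=n_cells,
                                             seed=seed, population=pop_k)
    mask = None
    if include_bistability:
        mask = bistability_scan(rho_grid, kgal_grid, params, gal)
    return PhenotypeLandscape(rho_grid=rho_grid, kgal_grid=kgal_grid,
                              gal=float(gal), labels=labels,
                              bistable_mask=mask)
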