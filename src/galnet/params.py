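"""Parameterization and closed-form rate laws of the four-gene GAL induction model.

The model tracks GAL1, GAL3, GAL80 and a P_GAL1-driven fluorescent reporter.
Each promoter is a two-state telegraph switch whose OFF->ON rate is driven by
galactose-activated Gal1p/Gal3p dimers and whose ON->OFF rate is driven by
Gal80p dimers.  The identifiable GAL3 meta-parameter is the *gene strength*

    rho_Gal3 = alpha3 * gamma3 / (beta3 * mu3 * K3),

the mean basal Gal3p level in units of the effective constant K3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

GENE_NAMES = ("GAL1", "GAL3", "GAL80", "REPORTER")

#: Number of free GAL3-dependent parameters exposed by the model:
#: alpha3, delta_alpha3, beta3, gamma3, mu3, K3, Kgal.
N_GAL3_FREE_PARAMETERS = 7


class ParameterError(ValueError):
    """Raised for invalid or incomplete model parameters."""


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ParameterError(f"{name} must be finite and >= 0, got {value!r}")


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ParameterError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class GeneKinetics:
    """Kinetic constants of one gene.

    alpha        leaky transcription rate (mRNA/min, promoter OFF)
    delta_alpha  additional transcription rate when the promoter is ON
                 (mRNA/min); the ON-state rate is alpha + delta_alpha
    beta         mRNA degradation rate (1/min)
    gamma        translation rate per mRNA (protein/min)
    mu           protein degradation/dilution rate (1/min)
    n_sites      number of strong Gal4p binding sites in the promoter
    """

    name: str
    alpha: float
    delta_alpha: float
    beta: float
    gamma: float
    mu: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.name not in GENE_NAMES:
            raise ParameterError(f"unknown gene name {self.name!r}")
        for attr in ("alpha", "delta_alpha", "beta", "gamma", "mu"):
            _require_finite_nonneg(f"{self.name}.{attr}", getattr(self, attr))
        if self.n_sites < 1 or int(self.n_sites) != self.n_sites:
            raise ParameterError(
                f"{self.name}.n_sites must be a positive integer, got {self.n_sites!r}"
            )

    @property
    def basal_mrna_mean(self) -> float:
        """Stationary mean mRNA with the promoter permanently OFF."""
        return self.alpha / self.beta

    @property
    def basal_protein_mean(self) -> float:
        """Stationary mean protein with the promoter permanently OFF."""
        return self.alpha * self.gamma / (self.beta * self.mu)


@dataclass(frozen=True)
class SharedConstants:
    """Constants shared by all promoters.

    k0_on    basal OFF->ON switching rate scale (1/min)
    k0_off   basal ON->OFF switching rate scale (1/min)
    K1, K3   effective constants for activated Gal1p / Gal3p dimers (molecules)
    K80      effective constant for Gal80p dimers (molecules)
    Kgal     galactose half-activation concentration (% w/v)
    nu_mat   reporter fluorophore maturation rate (1/min)
    """

    k0_on: float
    k0_off: float
    K1: float
    K3: float
    K80: float
    Kgal: float
    nu_mat: float

    def __post_init__(self) -> None:
        for attr in ("k0_on", "k0_off", "K1", "K3", "K80", "Kgal", "nu_mat"):
            _require_positive(attr, getattr(self, attr))


@dataclass(frozen=True)
class NetworkParameters:
    """Full parameter set: four genes plus shared constants."""

    genes: tuple[GeneKinetics, ...]
    shared: SharedConstants

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if sorted(names) != sorted(GENE_NAMES):
            raise ParameterError(
                f"expected exactly the four genes {GENE_NAMES}, got {names}"
            )
        # Canonical gene order.
        ordered = tuple(sorted(self.genes, key=lambda g: GENE_NAMES.index(g.name)))
        object.__setattr__(self, "genes", ordered)
        if self["REPORTER"].n_sites != self["GAL1"].n_sites:
            raise ParameterError(
                "REPORTER must share n_sites with GAL1 (it is a P_GAL1 construct)"
            )

    def __getitem__(self, name: str) -> GeneKinetics:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def rho_gal3(self) -> float:
        return gene_strength(self["GAL3"], self.shared.K3)

    @property
    def rho_gal1(self) -> float:
        return gene_strength(self["GAL1"], self.shared.K1)

    @property
    def rho_gal80(self) -> float:
        return gene_strength(self["GAL80"], self.shared.K80)

    def free_gal3_parameters(self) -> dict[str, float]:
        """The 7 GAL3-dependent free parameters of the model."""
        g3 = self["GAL3"]
        return {
            "alpha3": g3.alpha,
            "delta_alpha3": g3.delta_alpha,
            "beta3": g3.beta,
            "gamma3": g3.gamma,
            "mu3": g3.mu,
            "K3": self.shared.K3,
            "Kgal": self.shared.Kgal,
        }

    def with_gal3(self, rho: float | None = None, kgal: float | None = None) -> "NetworkParameters":
        """Return a copy with GAL3 strength and/or Kgal set.

        rho is realized by rescaling the GAL3 translation rate gamma3; any
        rho-equivalent realization is interchangeable by the identifiability
        of the meta-parameter.
        """
        genes = list(self.genes)
        shared = self.shared
        if rho is not None:
            _require_positive("rho", rho)
            scale = rho / self.rho_gal3
            g3 = self["GAL3"]
            genes[GENE_NAMES.index("GAL3")] = replace(g3, gamma=g3.gamma * scale)
        if kgal is not None:
            _require_positive("kgal", kgal)
            shared = replace(shared, Kgal=kgal)
        return NetworkParameters(genes=tuple(genes), shared=shared)


@dataclass(frozen=True)
class AlleleSummary:
    """Point summary of one GAL3 allele: strength and galactose constant,
    absolute and relative to a reference allele."""

    strain: str
    rho: float
    kgal: float
    rho_rel: float = float("nan")
    kgal_rel: float = float("nan")

    def __post_init__(self) -> None:
        _require_positive("rho", self.rho)
        _require_positive("kgal", self.kgal)


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def activated_count(protein: float, gal: float, kgal: float) -> float:
    """Number of galactose-activated proteins, Gal* = Gal * (gal/Kgal)/(1 + gal/Kgal).

    Monotone increasing and saturating in gal; equals protein/2 at gal = kgal.
    """
    if not (math.isfinite(protein) and math.isfinite(gal)):
        raise ParameterError("protein and gal must be finite")
    if protein < 0 or gal < 0:
        raise ParameterError("protein and gal must be >= 0")
    _require_positive("kgal", kgal)
    r = gal / kgal
    return protein * r / (1.0 + r)


def promoter_rates(
    gal80p: float,
    gal1_star: float,
    gal3_star: float,
    gene: GeneKinetics,
    shared: SharedConstants,
) -> tuple[float, float]:
    """Telegraph switching rates (k_on, k_off) for one promoter.

    k_on  = k0_on  * ((Gal1p*/K1)^2 + (Gal3p*/K3)^2)^n_i
    k_off = k0_off * (Gal80p/K80)^(2 n_i)

    Activated inducers and the repressor act through their dimers, hence the
    squared concentration ratios; n_i strong Gal4p sites multiply in the
    exponent.
    """
    for name, v in (("gal80p", gal80p), ("gal1_star", gal1_star), ("gal3_star", gal3_star)):
        _require_finite_nonneg(name, v)
    x = (gal1_star / shared.K1) ** 2 + (gal3_star / shared.K3) ** 2
    k_on = shared.k0_on * x ** gene.n_sites
    k_off = shared.k0_off * (gal80p / shared.K80) ** (2 * gene.n_sites)
    return k_on, k_off


def gene_strength(gene: GeneKinetics, K: float) -> float:
    """Gene strength rho = alpha*gamma / (beta*mu*K): the mean basal protein
    level in units of the effective constant K.  Invariant under the joint
    scaling (alpha -> c*alpha, K -> c*K)."""
    for attr in ("alpha", "beta", "gamma", "mu"):
        _require_positive(f"{gene.name}.{attr}", getattr(gene, attr))
    _require_positive("K", K)
    return gene.alpha * gene.gamma / (gene.beta * gene.mu * K)


# ---------------------------------------------------------------------------
# Default parameter set and the six alternative GAL3-independent sets
# ---------------------------------------------------------------------------

def default_parameters() -> NetworkParameters:
    """Reference parameter set.

    Chosen so that basal protein means are a few hundred molecules
    (rho_Gal1 = 100, rho_Gal80 = 250 with K = 1 molecule), mRNA lifetimes
    ~20 min, protein dilution 0.006/min (~2 h doubling), and so that at
    [gal] = 0.5% the GAL3 strengths 140 and 40 (Kgal = 0.055%) produce a
    gradual and a binary induction, respectively.
    """
    genes = (
        GeneKinetics("GAL1", alpha=0.060, delta_alpha=0.420, beta=0.05,
                     gamma=0.50, mu=0.006, n_sites=2),
        GeneKinetics("GAL3", alpha=0.084, delta_alpha=0.420, beta=0.05,
                     gamma=0.50, mu=0.006, n_sites=1),
        GeneKinetics("GAL80", alpha=0.150, delta_alpha=0.150, beta=0.05,
                     gamma=0.50, mu=0.006, n_sites=1),
        GeneKinetics("REPORTER", alpha=0.004, delta_alpha=0.620, beta=0.05,
                     gamma=0.50, mu=0.006, n_sites=2),
    )
    shared = SharedConstants(
        k0_on=1.0e-9, k0_off=1.3e-11,
        K1=1.0, K3=1.0, K80=1.0,
        Kgal=0.055, nu_mat=0.10,
    )
    return NetworkParameters(genes=genes, shared=shared)


def alternative_parameter_sets() -> dict[str, NetworkParameters]:
    """Six alternative GAL3-independent parameter sets for fit replication.

    Each perturbs constants the GAL3 fit conditions on (GAL1/GAL80 strengths,
    fold-activations, promoter switching scales) while leaving the GAL3 block
    free, so that repeated inference probes the robustness of the inferred
    (rho_Gal3, Kgal) to the fixed background.
    """
    base = default_parameters()

    def tweak(gene_updates: dict[str, dict[str, float]],
              shared_updates: dict[str, float]) -> NetworkParameters:
        genes = []
        for g in base.genes:
            upd = gene_updates.get(g.name, {})
            genes.append(replace(g, **upd))
        shared = replace(base.shared, **shared_updates)
        return NetworkParameters(genes=tuple(genes), shared=shared)

    sets = {
        "set1": base,
        "set2": tweak({"GAL1": {"alpha": 0.075}}, {}),                # rho_Gal1 125
        "set3": tweak({"GAL80": {"alpha": 0.120}}, {}),               # rho_Gal80 200
        "set4": tweak({"GAL1": {"delta_alpha": 0.540}}, {}),          # stronger GAL1 induction
        "set5": tweak({}, {"k0_off": 1.7e-11}),                       # faster OFF reversion
        "set6": tweak({"GAL1": {"alpha": 0.050}, "GAL80": {"alpha": 0.180}}, {}),
    }
    return sets


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

_GENE_FIELDS = ("alpha", "delta_alpha", "beta", "gamma", "mu", "n_sites")
_SHARED_FIELDS = ("k0_on", "k0_off", "K1", "K3", "K80", "Kgal", "nu_mat")


def to_dict(params: NetworkParameters) -> dict:
    d: dict = {"genes": {}, "shared": {}}
    for g in params.genes:
        d["genes"][g.name] = {f: getattr(g, f) for f in _GENE_FIELDS}
    d["shared"] = {f: getattr(params.shared, f) for f in _SHARED_FIELDS}
    return d


def from_dict(d: dict) -> NetworkParameters:
    try:
        gene_block = d["genes"]
        shared_block = d["shared"]
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"parameter mapping missing block: {exc}") from exc
    genes = []
    for name in GENE_NAMES:
        if name not in gene_block:
            raise ParameterError(f"missing gene block {name!r}")
        block = gene_block[name]
        missing = [f for f in _GENE_FIELDS if f not in block]
        if missing:
            raise ParameterError(f"gene {name!r} missing fields {missing}")
        genes.append(GeneKinetics(name=name, **{f: block[f] for f in _GENE_FIELDS}))
    missing = [f for f in _SHARED_FIELDS if f not in shared_block]
    if missing:
        raise ParameterError(f"shared block missing fields {missing}")
    shared = SharedConstants(**{f: shared_block[f] for f in _SHARED_FIELDS})
    return NetworkParameters(genes=tuple(genes), shared=shared)


def save_parameters(params: NetworkParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(params), sort_keys=True))


def load_parameters(path: str | Path) -> NetworkParameters:
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    return from_dict(yaml.safe_load(path.read_text()))
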