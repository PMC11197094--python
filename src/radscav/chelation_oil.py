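"""Metal chelation and hydroxyl-radical-inactivating-ligand behaviour (type II).

Covers four linked analyses for an antioxidant binding a redox-active metal
such as Cu(II):

* chelation equilibria — per-pathway equilibrium constants
  K = exp(-dG/RT), their combination into an apparent constant, and
  Maxwell-Boltzmann populations across competing binding motifs;
* pro-oxidant reduction kinetics — Marcus/Eyring/Collins-Kimball rates for
  the reduction of the metal by the antioxidant or physiological reductants,
  scaled by the molar fractions of both partners at the working pH;
* OIL-1 classification — does a given complex slow the metal's reduction
  (and hence Fenton radical production) relative to the free hydrated ion?
* OIL-2 — electron-transfer scavenging of the hydroxyl radical by the
  complexes themselves, plus a thermodynamic screen for hydrogen-transfer
  and adduct channels where explicit rates would sit at the diffusion limit
  anyway (Bell-Evans-Polanyi reasoning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_CONTEXT,
    DEFAULT_DIFFUSION,
    DiffusionInputs,
    KineticContext,
    MarcusInputs,
    collins_kimball,
    eyring_rate,
    marcus_barrier,
    smoluchowski_rate,
)

__all__ = [
    "ChelationPathway",
    "RedoxComparison",
    "ReductionRate",
    "equilibrium_constant",
    "apparent_constant",
    "boltzmann_fractions",
    "reduction_kinetics",
    "oil1_classify",
    "oil2_set_rates",
    "oil2_thermo_screen",
]

MOTIFS = ("C3C4", "C4C5")
STOICHIOMETRIES = ("mono", "bis")


def equilibrium_constant(delta_g: float, ctx: KineticContext = DEFAULT_CONTEXT) -> float:
    """K = exp(-dG/RT) for a complexation (or any) reaction free energy."""
    return math.exp(-delta_g / ctx.rt)


def apparent_constant(k_list, rule: str = "sum") -> float:
    """Combine per-pathway equilibrium constants into one apparent constant.

    ``rule="sum"`` treats the pathways as parallel equilibria feeding the
    same chelated pool (default); ``rule="product"`` multiplies stepwise
    constants, appropriate when the listed pathways are sequential (e.g.
    successive ligand additions of a bis complex).  Which convention a
    given published apparent constant used is not always recoverable, hence
    the switch.
    """
    ks = list(k_list)
    if not ks:
        raise ValueError("no equilibrium constants given")
    if any(k < 0 for k in ks):
        raise ValueError("equilibrium constants must be non-negative")
    if rule == "sum":
        return float(sum(ks))
    if rule == "product":
        return float(np.prod(ks))
    raise ValueError(f"unknown combination rule {rule!r}")


def boltzmann_fractions(delta_g_list, ctx: KineticContext = DEFAULT_CONTEXT) -> np.ndarray:
    """Maxwell-Boltzmann population of competing pathways from their dG values.

    Invariant under adding a constant to every energy; computed with the
    usual max-shift for numerical stability.
    """
    dg = np.asarray(delta_g_list, dtype=float)
    if dg.size == 0:
        raise ValueError("no free energies given")
    x = -(dg - dg.min()) / ctx.rt
    w = np.exp(x)
    return w / w.sum()


@dataclass
class ChelationPathway:
    """One metal-binding route: motif x stoichiometry for a given ligand state.

    ``k_eq`` is filled from dG when not supplied; ``fraction`` is the
    Maxwell-Boltzmann population among the pathways it was normalized with.
    """

    motif: str
    stoichiometry: str
    ligand_species: str
    delta_g_complexation: float
    k_eq: float | None = None
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"motif must be one of {MOTIFS}, got {self.motif!r}")
        if self.stoichiometry not in STOICHIOMETRIES:
            raise ValueError(
                f"stoichiometry must be one of {STOICHIOMETRIES}, got {self.stoichiometry!r}"
            )
        if self.k_eq is None:
            self.k_eq = equilibrium_constant(self.delta_g_complexation)
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def populate_chelation(pathways: list[ChelationPathway],
                       ctx: KineticContext = DEFAULT_CONTEXT) -> list[ChelationPathway]:
    """Fill k_eq and Boltzmann fractions across a set of competing pathways."""
    fracs = boltzmann_fractions([p.delta_g_complexation for p in pathways], ctx)
    for p, f in zip(pathways, fracs):
        p.k_eq = equilibrium_constant(p.delta_g_complexation, ctx)
        p.fraction = float(f)
    return pathways


@dataclass(frozen=True)
class ReductionRate:
    """Outcome of one metal-reduction channel."""

    dg_act: float
    k_tst: float
    k_d: float
    k_app: float
    k_scaled: float  # k_app times the molar fractions of both partners


def reduction_kinetics(
    m: MarcusInputs,
    ctx: KineticContext = DEFAULT_CONTEXT,
    diffusion: DiffusionInputs = DEFAULT_DIFFUSION,
    reductant_fraction: float = 1.0,
    ligand_fraction: float = 1.0,
) -> ReductionRate:
    """Marcus -> Eyring -> Collins-Kimball rate for a metal reduction step,
    scaled by the molar fractions of the reductant and of the ligand species
    at the working pH."""
    if not 0.0 <= reductant_fraction <= 1.0 or not 0.0 <= ligand_fraction <= 1.0:
        raise ValueError("molar fractions must lie in [0, 1]")
    dg_act = marcus_barrier(m.delta_g, m.lamda)
    k_tst = eyring_rate(dg_act, ctx)
    k_d = smoluchowski_rate(diffusion)
    k_app = collins_kimball(k_tst, k_d)
    return ReductionRate(
        dg_act=dg_act,
        k_tst=k_tst,
        k_d=k_d,
        k_app=k_app,
        k_scaled=k_app * reductant_fraction * ligand_fraction,
    )


@dataclass
class RedoxComparison:
    """A complex's reduction rate against the free-ion reference reaction."""

    complex_label: str
    reductant: str
    k_complex: float
    k_reference: float
    direction: str | None = None  # "up" | "down"
    fold_change: float | None = None

    def classify(self) -> "RedoxComparison":
        if self.k_reference <= 0:
            raise ValueError("reference rate must be positive")
        # equality labelled "down": the conservative call in favour of the ligand
        self.direction = "up" if self.k_complex > self.k_reference else "down"
        ratio = self.k_complex / self.k_reference
        self.fold_change = max(ratio, 1.0 / ratio) if ratio > 0 else math.inf
        return self


def oil1_classify(comparisons: list[RedoxComparison]) -> pd.DataFrame:
    """Annotate complex-vs-free-ion reduction rates and flag OIL-1 agents.

    A complex qualifies as an OIL-1 agent when it slows the metal reduction
    with *every* reductant tested (arrow down across the board), i.e. it
    sequesters the ion away from Fenton chemistry rather than accelerating
    its recycling.
    """
    rows = []
    for c in comparisons:
        c.classify()
        rows.append(
            {
                "complex": c.complex_label,
                "reductant": c.reductant,
                "k_complex": c.k_complex,
                "k_reference": c.k_reference,
                "direction": c.direction,
                "arrow": "↑" if c.direction == "up" else "↓",
                "fold_change": c.fold_change,
            }
        )
    df = pd.DataFrame(rows)
    verdict = df.groupby("complex")["direction"].agg(lambda s: set(s) == {"down"})
    df["oil1_agent"] = df["complex"].map(verdict)
    return df


def oil2_set_rates(
    records,
    ctx: KineticContext = DEFAULT_CONTEXT,
    diffusion: DiffusionInputs = DEFAULT_DIFFUSION,
) -> pd.DataFrame:
    """Electron-transfer scavenging of *OH by metal complexes.

    ``records`` is an iterable of mappings (or objects) carrying
    ``complex_label``/``motif``/``delta_g``/``lamda``.  The hydroxyl radical
    has no acid-base speciation, so no fraction scaling applies.
    """
    rows = []
    for rec in records:
        get = rec.get if isinstance(rec, dict) else lambda k, r=rec: getattr(r, k)
        m = MarcusInputs(delta_g=get("delta_g"), lamda=get("lamda"))
        rate = reduction_kinetics(m, ctx, diffusion)
        rows.append(
            {
                "complex": get("complex_label"),
                "motif": get("motif"),
                "delta_g": m.delta_g,
                "lamda": m.lamda,
                "dg_act": rate.dg_act,
                "k_tst": rate.k_tst,
                "k_d": rate.k_d,
                "k_app": rate.k_app,
            }
        )
    return pd.DataFrame(rows)


def oil2_thermo_screen(records) -> pd.DataFrame:
    """Thermodynamic screen of hydrogen-transfer / adduct channels on complexes.

    Partitions sites by the sign of the reaction free energy and ranks them
    by exergonicity (rank 1 = most negative dG).  No rate constants are
    emitted: these barrierless-to-fast channels are expected at or beyond
    the diffusion limit whenever they are exergonic, so dG is the usable
    discriminator.
    """
    rows = []
    for rec in records:
        get = rec.get if isinstance(rec, dict) else lambda k, r=rec: getattr(r, k)
        rows.append(
            {
                "complex": get("complex_label"),
                "mechanism": get("mechanism"),
                "site": get("site"),
                "delta_g": get("delta_g"),
            }
        )
    df = pd.DataFrame(rows)
    df["classification"] = np.where(df["delta_g"] < 0, "exergonic", "endergonic")
    df["rank"] = df["delta_g"].rank(method="min").astype(int)
    return df.sort_values("rank", ignore_index=True)
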