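"""Physical-chemistry kernel: Marcus barriers, Eyring rates, diffusion limits.

The functions here are the elementary blocks every higher-level module
composes: an activation free energy from Marcus theory (or taken as given),
an activated rate constant from transition-state theory, a diffusion-limited
encounter rate from Stokes-Einstein/Smoluchowski, and the Collins-Kimball
interpolation between the two.  All energies are in kcal mol-1, bimolecular
rate constants in M-1 s-1 at the 1 M standard state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import (
    AVOGADRO,
    BOLTZMANN_J,
    DEFAULT_RADIUS_ANTIOXIDANT,
    DEFAULT_RADIUS_RADICAL,
    DEFAULT_TEMPERATURE,
    PLANCK_J,
    R_KCAL,
    WATER_VISCOSITY,
)

__all__ = [
    "KineticContext",
    "MarcusInputs",
    "DiffusionInputs",
    "DEFAULT_CONTEXT",
    "DEFAULT_DIFFUSION",
    "marcus_barrier",
    "marcus_parabola",
    "eyring_rate",
    "invert_eyring",
    "fit_tunneling_factor",
    "fit_reorganization_energy",
    "stokes_einstein_diffusion",
    "smoluchowski_rate",
    "collins_kimball",
]


@dataclass(frozen=True)
class KineticContext:
    """Thermodynamic context for rate evaluations.

    Parameters
    ----------
    temperature
        Absolute temperature in kelvin.
    standard_state
        Reference concentration in mol L-1 for bimolecular rate constants.
    gas_constant_kcal
        Gas constant in kcal mol-1 K-1.
    """

    temperature: float = DEFAULT_TEMPERATURE
    standard_state: float = 1.0
    gas_constant_kcal: float = R_KCAL

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def rt(self) -> float:
        """R*T in kcal mol-1 (0.5925 at 298.15 K)."""
        return self.gas_constant_kcal * self.temperature

    @property
    def boltzmann_over_planck(self) -> float:
        """Eyring prefactor kB*T/h in s-1 (6.212e12 at 298.15 K)."""
        return BOLTZMANN_J * self.temperature / PLANCK_J


@dataclass(frozen=True)
class MarcusInputs:
    """Energetics of one outer-sphere electron-transfer channel.

    ``delta_e`` is the tabulated vertical/reaction energy carried along as
    metadata only; the barrier depends on ``delta_g`` and the reorganization
    energy ``lamda`` alone.
    """

    delta_g: float
    lamda: float
    delta_e: float | None = None

    def __post_init__(self) -> None:
        if not self.lamda > 0:
            raise ValueError(f"reorganization energy must be positive, got {self.lamda}")


@dataclass(frozen=True)
class DiffusionInputs:
    """Solvent context for the diffusion-limited encounter rate.

    Radii in angstrom, viscosity in Pa s.  Defaults describe a
    flavonoid-sized solute meeting a small radical in water at 298.15 K.
    """

    radius_a: float = DEFAULT_RADIUS_ANTIOXIDANT
    radius_b: float = DEFAULT_RADIUS_RADICAL
    viscosity: float = WATER_VISCOSITY
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("radius_a", "radius_b", "viscosity", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


DEFAULT_CONTEXT = KineticContext()
DEFAULT_DIFFUSION = DiffusionInputs()


def marcus_barrier(delta_g, lamda):
    """Marcus activation free energy (lambda/4)*(1 + dG/lambda)**2.

    Vanishes at ``delta_g == -lamda`` (parabola apex) and rises again for
    more exergonic reactions (inverted region); no quantum correction is
    applied there.  Accepts scalars or arrays and broadcasts.
    """
    lam = np.asarray(lamda, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("reorganization energy must be positive")
    dg = np.asarray(delta_g, dtype=float)
    out = lam / 4.0 * (1.0 + dg / lam) ** 2
    if out.ndim == 0:
        return float(out)
    return out


def marcus_parabola(lamda: float, dg_grid) -> np.ndarray:
    """Barrier curve over a grid of reaction free energies (apex at -lambda)."""
    return np.asarray(marcus_barrier(np.asarray(dg_grid, dtype=float), lamda))


def eyring_rate(
    dg_act,
    ctx: KineticContext = DEFAULT_CONTEXT,
    sigma: int = 1,
    kappa: float = 1.0,
):
    """Transition-state-theory rate constant.

    k = sigma * kappa * (kB*T/h) * exp(-dG_act / RT), referenced to the 1 M
    standard state so a bimolecular constant carries units of M-1 s-1.

    ``sigma`` is the reaction-path degeneracy, ``kappa`` a tunneling
    transmission coefficient (>= 1; hydrogen transfers often need large
    values that are rarely tabulated alongside the barrier).
    """
    if sigma < 1 or int(sigma) != sigma:
        raise ValueError(f"path degeneracy sigma must be a positive integer, got {sigma}")
    if kappa < 1:
        raise ValueError(f"tunneling factor kappa must be >= 1, got {kappa}")
    dg = np.asarray(dg_act, dtype=float)
    out = sigma * kappa * ctx.boltzmann_over_planck * np.exp(-dg / ctx.rt)
    if out.ndim == 0:
        return float(out)
    return out


def invert_eyring(
    k: float,
    ctx: KineticContext = DEFAULT_CONTEXT,
    sigma: int = 1,
    kappa: float = 1.0,
) -> float:
    """Activation free energy implied by a rate constant (inverse of eyring_rate)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return ctx.rt * math.log(sigma * kappa * ctx.boltzmann_over_planck / k)


def fit_tunneling_factor(
    dg_act: float, k_target: float, ctx: KineticContext = DEFAULT_CONTEXT, sigma: int = 1
) -> float:
    """Transmission coefficient that reconciles a barrier with a reported rate.

    Hydrogen-transfer rate constants are frequently published with a
    tunneling correction folded in but not printed.  This returns the kappa
    such that ``eyring_rate(dg_act, ctx, sigma, kappa) == k_target``.
    """
    if k_target <= 0:
        raise ValueError("target rate constant must be positive")
    return k_target / eyring_rate(dg_act, ctx, sigma=sigma)


def stokes_einstein_diffusion(
    radius_angstrom: float,
    viscosity: float = WATER_VISCOSITY,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Translational diffusion coefficient D = kB*T / (6 pi eta a), in m2 s-1."""
    if radius_angstrom <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValueError("radius, viscosity and temperature must all be positive")
    radius_m = radius_angstrom * 1e-10
    return BOLTZMANN_J * temperature / (6.0 * math.pi * viscosity * radius_m)


def smoluchowski_rate(d: DiffusionInputs = DEFAULT_DIFFUSION) -> float:
    """Diffusion-limited bimolecular rate k_D = 4 pi (rA+rB)(DA+DB) N_A, in M-1 s-1."""
    d_a = stokes_einstein_diffusion(d.radius_a, d.viscosity, d.temperature)
    d_b = stokes_einstein_diffusion(d.radius_b, d.viscosity, d.temperature)
    r_sum_m = (d.radius_a + d.radius_b) * 1e-10
    # m3 s-1 per pair -> L mol-1 s-1
    return 4.0 * math.pi * r_sum_m * (d_a + d_b) * AVOGADRO * 1e3


def collins_kimball(k_act, k_d):
    """Apparent rate constant k_act*k_D/(k_act + k_D).

    Reduces to the activated rate far below the diffusion limit and to the
    encounter rate when the reaction is activationless; never exceeds either
    argument.  Returns 0 when both rates vanish.
    """
    ka = np.asarray(k_act, dtype=float)
    kd = np.asarray(k_d, dtype=float)
    if np.any(ka < 0) or np.any(kd < 0):
        raise ValueError("rate constants must be non-negative")
    denom = ka + kd
    with np.errstate(invalid="ignore"):
        out = np.where(denom > 0, ka * kd / np.where(denom > 0, denom, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def fit_reorganization_energy(
    delta_g, dg_act, lamda0: float = 20.0
) -> tuple[float, float]:
    """Least-squares reorganization energy from (dG, dG_act) pairs.

    Fits the one-parameter Marcus parabola to observed activation energies
    and returns ``(lamda_hat, standard_error)``.  Used for parameter
    recovery on synthetic ensembles and as a diagnostic on tabulated data.
    """
    dg = np.asarray(delta_g, dtype=float)
    ga = np.asarray(dg_act, dtype=float)
    if dg.size < 2:
        raise ValueError("need at least two (dG, dG_act) pairs")

    popt, pcov = optimize.curve_fit(
        lambda x, lam: marcus_barrier(x, lam), dg, ga, p0=[lamda0]
    )
    return float(popt[0]), float(math.sqrt(pcov[0, 0]))
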