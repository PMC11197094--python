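"""Acid-base bookkeeping: molar fractions of protonation states versus pH.

A polyprotic antioxidant is described by a :class:`ProtonationLadder`
(ordered from most to least protonated); the radical partner, when it is
itself part of an acid-base equilibrium, by a :class:`RadicalAcidBasePair`.
The fractions returned here multiply the per-species total rate constants
to give pH-corrected apparent kinetics — the study conditions stress that
even species present at seemingly negligible populations can dominate the
outcome, so no fraction is ever floored to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProtonationLadder", "RadicalAcidBasePair", "molar_fractions", "active_fraction"]


@dataclass(frozen=True)
class ProtonationLadder:
    """Sequential macroscopic acid dissociation constants of one compound.

    ``labels`` run from the fully protonated to the fully deprotonated
    macro-state (e.g. ``H3Glg, H2Glg-, HGlg2-``); ``pkas`` are the pKa
    values separating consecutive states, so ``len(labels) == len(pkas)+1``.
    Monotonicity of the pKa ladder is not assumed.
    """

    labels: tuple[str, ...]
    pkas: tuple[float, ...]

    def __init__(self, labels, pkas):
        object.__setattr__(self, "labels", tuple(labels))
        object.__setattr__(self, "pkas", tuple(float(p) for p in pkas))
        if len(self.labels) != len(self.pkas) + 1:
            raise ValueError(
                f"ladder needs one more label than pKa values: "
                f"{len(self.labels)} labels vs {len(self.pkas)} pKas"
            )
        if not all(math.isfinite(p) for p in self.pkas):
            raise ValueError("every pKa must be finite")

    @property
    def n_states(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RadicalAcidBasePair:
    """A radical existing in a protonated/deprotonated equilibrium.

    For the hydroperoxyl/superoxide pair (pKa 4.8) only the protonated form
    is the damaging, reactive partner; its population at physiological pH is
    small but never negligible.
    """

    protonated_label: str
    deprotonated_label: str
    pka: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pka):
            raise ValueError("pKa must be finite")


def molar_fractions(ladder: ProtonationLadder, ph):
    """Molar fraction of every protonation state at the given pH.

    State *j* (0 = fully protonated) carries unnormalized weight
    ``10**(j*pH - sum(pKa_1..pKa_j))``; fractions are the normalized
    weights.  ``ph`` may be a scalar or an array; the result has the state
    axis last and always sums to 1 along it.
    """
    ph_arr = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph_arr)):
        raise ValueError("pH must be finite")
    cum = np.concatenate([[0.0], np.cumsum(ladder.pkas)])
    j = np.arange(ladder.n_states)
    exponents = ph_arr[..., None] * j - cum
    # shift by the row-max so 10**x never overflows
    exponents = exponents - exponents.max(axis=-1, keepdims=True)
    weights = 10.0 ** exponents
    fractions = weights / weights.sum(axis=-1, keepdims=True)
    if np.ndim(ph) == 0:
        return fractions.reshape(ladder.n_states)
    return fractions


def active_fraction(pair: RadicalAcidBasePair, ph) -> float:
    """Fraction of the protonated form: 1 / (1 + 10**(pH - pKa))."""
    ph_arr = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph_arr)):
        raise ValueError("pH must be finite")
    out = 1.0 / (1.0 + 10.0 ** (ph_arr - pair.pka))
    if out.ndim == 0:
        return float(out)
    return out
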