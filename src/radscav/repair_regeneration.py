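"""Repair of oxidized biomolecules and antioxidant regeneration (type III).

*Repair*: an antioxidant can restore an oxidatively damaged biomolecule by
donating a hydrogen atom (neutral radicals) or an electron (radical
cations).  Model targets are a truncated linoleic-acid radical (LM), the
2'-deoxyguanosine radical and radical cation (2dG), and N-formylated
amino-acid radicals (NF-Cys, NF-His, NF-Leu, NF-Met, NF-Trp, NF-Tyr).
Channels whose reaction free energy exceeds the screening threshold are
dropped; a target with no surviving channel is deemed not repairable.

*Regeneration*: the spent antioxidant radical (or radical cation) is
reduced back by superoxide and reprotonated from the solvent, closing a
scavenge-regenerate cycle.  Each step is checked for exergonicity and for
diffusion-limited kinetics.

The overall repair rate of species *j* at a given pH is f_j(pH) * k_total_j
— unlike direct scavenging there is no radical acid-base factor, because
the damaged biomolecule itself is the reaction partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ENDERGONIC_DG_THRESHOLD
from .kinetics import (
    DEFAULT_CONTEXT,
    DEFAULT_DIFFUSION,
    DiffusionInputs,
    KineticContext,
    collins_kimball,
    eyring_rate,
    smoluchowski_rate,
)
from .scavenging import PathwayRecord
from .speciation import ProtonationLadder, molar_fractions

__all__ = [
    "REPAIR_TARGET_NAMES",
    "RepairTarget",
    "RepairVerdict",
    "RegenerationStep",
    "repair_feasibility",
    "repair_overall",
    "site_orderings",
    "regeneration_assess",
]

REPAIR_TARGET_NAMES = (
    "LM", "2dG", "NF-Cys", "NF-His", "NF-Leu", "NF-Met", "NF-Trp", "NF-Tyr",
)


@dataclass
class RepairTarget:
    """An oxidized biomolecule model and the donor channels that may fix it."""

    name: str
    form: str  # "radical" | "radical-cation"
    pathways: list[PathwayRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.form not in ("radical", "radical-cation"):
            raise ValueError(f"form must be 'radical' or 'radical-cation', got {self.form!r}")
        if self.form == "radical-cation":
            non_set = [p for p in self.pathways if p.mechanism != "SET"]
            if non_set:
                raise ValueError(
                    f"radical-cation target {self.name}: repair proceeds by electron "
                    "transfer only, found non-SET pathways"
                )


@dataclass(frozen=True)
class RepairVerdict:
    target: str
    retained: list[PathwayRecord]
    excluded: list[PathwayRecord]

    @property
    def repairable(self) -> bool:
        return len(self.retained) > 0


def repair_feasibility(
    target: RepairTarget, threshold: float = ENDERGONIC_DG_THRESHOLD
) -> RepairVerdict:
    """Drop channels with dG >= threshold; no surviving channel = not repairable."""
    retained, excluded = [], []
    for p in target.pathways:
        if p.delta_g is not None and p.delta_g >= threshold:
            excluded.append(p)
        else:
            retained.append(p)
    return RepairVerdict(target=target.name, retained=retained, excluded=excluded)


def repair_overall(k_totals, ladder: ProtonationLadder, ph: float = 7.4) -> np.ndarray:
    """Per-species overall repair rates: f_j(pH) * k_total_j (no radical factor)."""
    k = np.asarray(k_totals, dtype=float)
    if k.shape[-1] != ladder.n_states:
        raise ValueError(
            f"{k.shape[-1]} rate totals for a ladder with {ladder.n_states} states"
        )
    return molar_fractions(ladder, ph) * k


def site_orderings(pathways: list[PathwayRecord]) -> dict[str, list[str]]:
    """Site reactivity ranked two ways: by dG and by barrier.

    Reaction free energies order donor sites thermodynamically, but the
    kinetic ordering follows the activation energies and the two need not
    agree — returning both makes the distinction explicit instead of
    letting the dG ranking masquerade as reactivity.
    """
    with_dg = [p for p in pathways if p.delta_g is not None]
    with_act = [p for p in pathways if p.delta_g_act is not None]
    return {
        "by_delta_g": [p.site for p in sorted(with_dg, key=lambda p: p.delta_g)],
        "by_barrier": [p.site for p in sorted(with_act, key=lambda p: p.delta_g_act)],
    }


@dataclass
class RegenerationStep:
    """One step of the superoxide-mediated regeneration cycle.

    ``site_or_set`` names the hydroxyl site being restored, or "SET" for
    reduction of the radical cation.  ``delta_g_protonation`` is the free
    energy of the subsequent reprotonation from the solvent (absent for
    pure electron steps)."""

    species: str
    site_or_set: str
    delta_g: float
    delta_g_act: float
    k_ref: float | None = None
    delta_g_protonation: float | None = None


def regeneration_assess(
    steps: list[RegenerationStep],
    ctx: KineticContext = DEFAULT_CONTEXT,
    diffusion: DiffusionInputs = DEFAULT_DIFFUSION,
    diffusion_limited_ratio: float = 0.5,
) -> pd.DataFrame:
    """Feasibility report for a regeneration cycle.

    A step is *feasible* when its reaction free energy is negative, and
    *diffusion limited* when its Collins-Kimball rate reaches at least
    ``diffusion_limited_ratio`` of the encounter rate.  ``cycle_closed``
    marks steps whose reprotonation free energy is also favourable (or not
    applicable).  A single endergonic step flags the cycle as broken there.
    """
    k_d = smoluchowski_rate(diffusion)
    rows = []
    for s in steps:
        k_tst = eyring_rate(s.delta_g_act, ctx)
        k_app = collins_kimball(k_tst, k_d)
        rows.append(
            {
                "species": s.species,
                "step": s.site_or_set,
                "delta_g": s.delta_g,
                "dg_act": s.delta_g_act,
                "k_app": k_app,
                "k_ref": s.k_ref,
                "feasible": s.delta_g < 0,
                "diffusion_limited": k_app >= diffusion_limited_ratio * k_d,
                "dg_protonation": s.delta_g_protonation,
                "cycle_closed": s.delta_g < 0
                and (s.delta_g_protonation is None or s.delta_g_protonation < 0),
            }
        )
    return pd.DataFrame(rows)
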