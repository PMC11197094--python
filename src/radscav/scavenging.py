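"""Direct radical scavenging (type I activity).

From per-pathway energetics this module screens thermochemically relevant
channels, evaluates diffusion-corrected rate constants, aggregates them
into branching ratios and per-species totals, applies the molar-fraction
correction for both reaction partners at a given pH, and scans the
resulting overall rate constant across a pH range.

The apparent rate of species *j* against a partially protonated radical is

    k_corrected_j = f_j(pH) * f_radical(pH) * k_total_j
    k_overall     = sum_j k_corrected_j

with f_j the molar fraction of protonation state j and f_radical the
fraction of the reactive (protonated) radical form.  In a non-aqueous
(lipid) medium no acid-base speciation applies and k_overall = k_total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ENDERGONIC_DG_THRESHOLD, PH_SCAN_RANGE, PH_SCAN_STEP
from .kinetics import (
    DEFAULT_CONTEXT,
    DEFAULT_DIFFUSION,
    DiffusionInputs,
    KineticContext,
    collins_kimball,
    eyring_rate,
    marcus_barrier,
    smoluchowski_rate,
)
from .speciation import (
    ProtonationLadder,
    RadicalAcidBasePair,
    active_fraction,
    molar_fractions,
)

__all__ = [
    "MECHANISMS",
    "PathwayRecord",
    "RateEntry",
    "CorrectedOverall",
    "PhScanResult",
    "screen_pathways",
    "evaluate_rates",
    "branching_ratios",
    "total_rate",
    "corrected_overall",
    "ph_scan",
    "plot_ph_scan",
]

MECHANISMS = ("SET", "fHAT", "RAF")


@dataclass
class PathwayRecord:
    """One elementary reaction channel: species x mechanism x site x medium.

    ``delta_g_act`` may be omitted for SET channels when a reorganization
    energy is supplied, in which case the Marcus barrier is computed on the
    fly.  ``k_ref``/``gamma_ref`` hold externally reported values (e.g. a
    published table) for comparison and are never used in computation
    unless explicitly requested.  Unknown tabular columns survive round
    trips through ``extra``.
    """

    species: str
    mechanism: str
    site: str
    medium: str = "water"
    delta_g: float | None = None
    delta_g_act: float | None = None
    lamda: float | None = None
    kappa: float = 1.0
    sigma: int = 1
    k_ref: float | None = None
    gamma_ref: float | None = None
    quality: str = "ok"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if self.kappa < 1:
            raise ValueError(f"kappa must be >= 1, got {self.kappa}")
        if self.sigma < 1:
            raise ValueError(f"sigma must be >= 1, got {self.sigma}")

    @property
    def has_kinetic_inputs(self) -> bool:
        """True when a barrier is available or derivable (SET + lambda)."""
        if self.delta_g_act is not None:
            return True
        return self.mechanism == "SET" and self.lamda is not None and self.delta_g is not None

    def barrier(self) -> float:
        """Activation free energy, from the table or from Marcus theory."""
        if self.delta_g_act is not None:
            return self.delta_g_act
        if self.mechanism == "SET" and self.lamda is not None and self.delta_g is not None:
            return marcus_barrier(self.delta_g, self.lamda)
        raise ValueError(
            f"pathway {self.species}/{self.mechanism}/{self.site}: no activation "
            "free energy and no (SET, delta_g, lambda) triple to derive one"
        )


@dataclass
class RateEntry:
    """Computed kinetic outputs for one pathway."""

    pathway: PathwayRecord
    k_tst: float
    k_d: float
    k_app: float
    gamma: float | None = None


def screen_pathways(
    records: list[PathwayRecord],
    dg_threshold: float = ENDERGONIC_DG_THRESHOLD,
) -> list[PathwayRecord]:
    """Thermochemical pre-screen of reaction channels.

    Keeps every exergonic pathway, endergonic hydrogen-transfer/adduct
    pathways below ``dg_threshold`` (slightly uphill steps can still matter
    when followed by fast exergonic chemistry), and *all* electron-transfer
    pathways regardless of dG — their kinetics follow Marcus theory, so a
    large positive reaction free energy does not by itself preclude a
    usable barrier.  Records without a tabulated dG are passed through.
    """
    kept = []
    for rec in records:
        if rec.mechanism == "SET" or rec.delta_g is None or rec.delta_g < dg_threshold:
            kept.append(rec)
    return kept


def evaluate_rates(
    records: list[PathwayRecord],
    ctx: KineticContext = DEFAULT_CONTEXT,
    diffusion: DiffusionInputs = DEFAULT_DIFFUSION,
) -> list[RateEntry]:
    """Diffusion-corrected rate constant for each pathway.

    k_app = collins_kimball(sigma*kappa*(kBT/h)exp(-dG_act/RT), k_D).
    Raises a single ValueError listing every record that lacks the energies
    needed for a kinetic evaluation.
    """
    bad = [r for r in records if not r.has_kinetic_inputs]
    if bad:
        desc = ", ".join(f"{r.species}/{r.mechanism}/{r.site}" for r in bad)
        raise ValueError(f"records missing kinetic inputs: {desc}")

    k_d = smoluchowski_rate(diffusion)
    entries = []
    for rec in records:
        k_tst = eyring_rate(rec.barrier(), ctx, sigma=rec.sigma, kappa=rec.kappa)
        entries.append(
            RateEntry(pathway=rec, k_tst=k_tst, k_d=k_d, k_app=collins_kimball(k_tst, k_d))
        )
    return entries


def branching_ratios(entries: list[RateEntry]) -> np.ndarray:
    """Percent contribution of each pathway to the species total.

    Gamma_i = 100 * k_i / sum(k); entries must belong to one species and
    medium.  The gammas are written back onto the entries and returned.
    """
    if not entries:
        raise ValueError("no rate entries given")
    groups = {(e.pathway.species, e.pathway.medium) for e in entries}
    if len(groups) > 1:
        raise ValueError(f"entries mix species/medium groups: {sorted(groups)}")
    k = np.array([e.k_app for e in entries], dtype=float)
    total = k.sum()
    if total <= 0:
        raise ValueError("all rate constants are zero; branching ratios undefined")
    gammas = 100.0 * k / total
    for e, g in zip(entries, gammas):
        e.gamma = float(g)
    return gammas


def total_rate(entries: list[RateEntry]) -> float:
    """Arithmetic sum of apparent rate constants (parallel channels)."""
    return float(sum(e.k_app for e in entries))


@dataclass(frozen=True)
class CorrectedOverall:
    """Molar-fraction-corrected kinetics at a single pH."""

    ph: float
    fractions: np.ndarray
    radical_fraction: float
    k_corrected: np.ndarray
    k_overall: float


def corrected_overall(
    k_totals,
    ladder: ProtonationLadder | None = None,
    radical_pair: RadicalAcidBasePair | None = None,
    ph: float = 7.4,
    medium: str = "water",
) -> CorrectedOverall:
    """Combine per-species totals into the pH-corrected overall rate constant.

    In water each total is weighted by its species' molar fraction and, if a
    ``radical_pair`` is given, by the protonated-radical fraction.  In a
    lipid medium no speciation applies: the (single) total is returned
    unchanged as the overall value.
    """
    k = np.asarray(k_totals, dtype=float)
    if medium == "lipid":
        return CorrectedOverall(
            ph=ph,
            fractions=np.ones_like(k),
            radical_fraction=1.0,
            k_corrected=k.copy(),
            k_overall=float(k.sum()),
        )
    if ladder is None:
        raise ValueError("aqueous correction requires a protonation ladder")
    if k.shape[-1] != ladder.n_states:
        raise ValueError(
            f"{k.shape[-1]} rate totals for a ladder with {ladder.n_states} states"
        )
    fractions = molar_fractions(ladder, ph)
    f_rad = active_fraction(radical_pair, ph) if radical_pair is not None else 1.0
    k_corr = fractions * f_rad * k
    return CorrectedOverall(
        ph=ph,
        fractions=fractions,
        radical_fraction=f_rad,
        k_corrected=k_corr,
        k_overall=float(k_corr.sum()),
    )


@dataclass(frozen=True)
class PhScanResult:
    """Overall rate constant across a pH grid, with per-species contributions."""

    ph: np.ndarray
    species: tuple[str, ...]
    contributions: np.ndarray  # (n_ph, n_species), already radical-corrected
    k_overall: np.ndarray

    @property
    def log10_k_overall(self) -> np.ndarray:
        return np.log10(self.k_overall)

    @property
    def argmin_ph(self) -> float:
        """pH at which log10(k_overall) is lowest (basin floor)."""
        return float(self.ph[int(np.argmin(self.k_overall))])

    @property
    def min_log10_k(self) -> float:
        return float(self.log10_k_overall.min())

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.contributions, columns=list(self.species))
        df.insert(0, "ph", self.ph)
        df["k_overall"] = self.k_overall
        df["log10_k_overall"] = self.log10_k_overall
        return df


def ph_scan(
    k_totals,
    ladder: ProtonationLadder,
    radical_pair: RadicalAcidBasePair | None = None,
    ph_start: float = PH_SCAN_RANGE[0],
    ph_stop: float = PH_SCAN_RANGE[1],
    step: float = PH_SCAN_STEP,
) -> PhScanResult:
    """Evaluate the corrected overall rate constant on an inclusive pH grid."""
    if not (0.0 <= ph_start <= 14.0 and 0.0 <= ph_stop <= 14.0 and ph_stop >= ph_start):
        raise ValueError("pH range must lie within [0, 14] with stop >= start")
    n = int(round((ph_stop - ph_start) / step)) + 1
    grid = ph_start + step * np.arange(n)
    if grid.size == 0:
        raise ValueError("empty pH grid")

    k = np.asarray(k_totals, dtype=float)
    fractions = molar_fractions(ladder, grid)  # (n_ph, n_states)
    f_rad = (
        active_fraction(radical_pair, grid)[:, None]
        if radical_pair is not None
        else np.ones((grid.size, 1))
    )
    contributions = fractions * f_rad * k
    return PhScanResult(
        ph=grid,
        species=ladder.labels,
        contributions=contributions,
        k_overall=contributions.sum(axis=1),
    )


def plot_ph_scan(result: PhScanResult, ax=None):
    """Log-scale plot of the overall rate and per-species contributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, name in enumerate(result.species):
        ax.plot(result.ph, np.log10(np.maximum(result.contributions[:, i], 1e-300)),
                label=name, lw=1)
    ax.plot(result.ph, result.log10_k_overall, "k-", lw=2, label="overall")
    ax.set_xlabel("pH")
    ax.set_ylabel(r"$\log_{10}\,k$ (M$^{-1}$ s$^{-1}$)")
    ax.legend()
    return ax
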