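"""Reference fixtures, synthetic pathway ensembles, and tabular I/O.

The fixtures hand-encode the published kinetic/thermochemical tables for
galangin at their printed precision (unicode minus/multiplication signs and
superscript exponents normalized to plain ASCII scientific notation).  They
are the inputs to every worked example and reproduction check; nothing in
the package recomputes the underlying electronic-structure energies.

The synthetic generator emulates pathway ensembles with configurable
distributions of reaction free energy, reorganization energy and barrier —
including a controllable share of Marcus-inverted electron transfers — for
property and parameter-recovery tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    ENDERGONIC_DG_THRESHOLD,
    GALANGIN_PKA1,
    GALANGIN_PKA2,
    HYDROPEROXYL_PKA,
)
from .kinetics import marcus_barrier
from .scavenging import PathwayRecord
from .repair_regeneration import RegenerationStep
from .speciation import ProtonationLadder, RadicalAcidBasePair

__all__ = [
    "SyntheticConfig",
    "FIXTURE_IDS",
    "load_fixture",
    "galangin_ladder",
    "hydroperoxyl_pair",
    "generate_synthetic",
    "read_pathways",
    "write_pathways",
    "parse_scientific",
]

FIXTURE_IDS = ("table1", "table3", "table4", "table5", "table6", "text_constants")

AQUEOUS_SPECIES = ("H3Glg", "H2Glg-", "HGlg2-")


def galangin_ladder(pka1: float = GALANGIN_PKA1, pka2: float = GALANGIN_PKA2) -> ProtonationLadder:
    """Galangin's three aqueous macro-states with the shipped (derived) pKas."""
    return ProtonationLadder(labels=AQUEOUS_SPECIES, pkas=(pka1, pka2))


def hydroperoxyl_pair() -> RadicalAcidBasePair:
    return RadicalAcidBasePair("OOH*", "O2*-", HYDROPEROXYL_PKA)


# --------------------------------------------------------------------------
# Hydroperoxyl scavenging: barrier, rate constant, branching ratio (percent)
# per pathway, plus species totals and pH-corrected values at pH 7.4.
# --------------------------------------------------------------------------

_TABLE1 = {
    "H3Glg_PET": {
        "medium": "lipid",
        "pathways": [
            ("fHAT", "C3", 16.7, 3.77e3, 99.89),
            ("fHAT", "C7", 19.8, 1.73e0, 0.05),
            ("RAF", "C2", 17.8, 8.04e-1, 0.02),
            ("RAF", "C3", 17.3, 1.75e0, 0.05),
        ],
        "k_total": 3.77e3,
        "k_corrected": None,
    },
    "H3Glg": {
        "medium": "water",
        "pathways": [
            ("fHAT", "C3", 15.4, 6.42e3, 99.30),
            ("fHAT", "C5", 24.1, 1.28e-1, 0.00),
            ("fHAT", "C7", 22.0, 6.95e-1, 0.01),
            ("RAF", "C2", 15.6, 3.33e1, 0.52),
            ("RAF", "C3", 16.2, 1.13e1, 0.18),
            ("SET", "SET", 34.1, 5.89e-13, 0.00),
        ],
        "k_total": 6.46e3,
        "k_corrected": 8.81e0,
    },
    "H2Glg-": {
        "medium": "water",
        "pathways": [
            ("fHAT", "C3", 13.8, 5.04e4, 98.64),
            ("fHAT", "C5", 22.3, 2.88e0, 0.01),
            ("RAF", "C2", 14.2, 3.27e2, 0.64),
            ("RAF", "C3", 14.1, 3.64e2, 0.71),
            ("SET", "SET", 19.1, 6.51e-2, 0.00),
        ],
        "k_total": 5.11e4,
        "k_corrected": 5.78e1,
    },
    "HGlg2-": {
        "medium": "water",
        "pathways": [
            ("fHAT", "C5", 22.4, 1.08e1, 0.00),
            ("RAF", "C2", 2.3, 2.50e9, 51.68),
            ("RAF", "C3", 3.5, 1.83e9, 37.92),
            ("RAF", "C4", 5.9, 2.74e8, 5.68),
            ("RAF", "C8", 12.3, 6.59e3, 0.00),
            ("RAF", "C2'", 15.0, 7.11e1, 0.00),
            ("RAF", "C4'", 14.0, 4.38e2, 0.00),
            ("RAF", "C6'", 14.6, 1.42e2, 0.00),
            ("SET", "SET", 6.0, 2.28e8, 4.72),
        ],
        "k_total": 4.83e9,
        "k_corrected": 6.21e4,
    },
}

_TABLE1_K_OVERALL_WATER = 6.21e4


@dataclass(frozen=True)
class SpeciesBlock:
    """One species column of the scavenging table."""

    species: str
    medium: str
    pathways: list[PathwayRecord]
    k_total: float
    k_corrected: float | None


@dataclass(frozen=True)
class ScavengingFixture:
    blocks: dict[str, SpeciesBlock]
    k_overall_water: float

    def aqueous_totals(self) -> list[float]:
        return [self.blocks[s].k_total for s in AQUEOUS_SPECIES]


def reference_rate_entries(block: "SpeciesBlock"):
    """RateEntry list carrying the *published* rate constants of a species
    block, for aggregation (totals, branching ratios) at printed precision."""
    from .scavenging import RateEntry

    return [
        RateEntry(pathway=p, k_tst=p.k_ref, k_d=math.inf, k_app=p.k_ref)
        for p in block.pathways
    ]


def _build_table1() -> ScavengingFixture:
    blocks = {}
    for species, data in _TABLE1.items():
        records = [
            PathwayRecord(
                species=species,
                mechanism=mech,
                site=site,
                medium=data["medium"],
                delta_g_act=dg_act,
                k_ref=k,
                gamma_ref=gamma,
            )
            for mech, site, dg_act, k, gamma in data["pathways"]
        ]
        blocks[species] = SpeciesBlock(
            species=species,
            medium=data["medium"],
            pathways=records,
            k_total=data["k_total"],
            k_corrected=data["k_corrected"],
        )
    return ScavengingFixture(blocks=blocks, k_overall_water=_TABLE1_K_OVERALL_WATER)


# --------------------------------------------------------------------------
# Cu(II) reduction by superoxide / ascorbate for the free hydrated ion and
# the chelates (OIL-1 comparisons): dE, dG, lambda, barrier, rate, and the
# published up/down verdict against the free-ion reference.
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RedoxRow:
    complex_label: str
    stoichiometry: str  # "free" | "mono" | "bis"
    motif: str | None
    reductant: str  # "superoxide" | "ascorbate"
    delta_e: float
    delta_g: float
    lamda: float
    dg_act: float
    k: float
    arrow: str | None  # "up" | "down" | None for the reference row


_TABLE3 = [
    # label, stoich, motif, (dE, dG, lam, dGact, k, arrow) x {superoxide, ascorbate}
    ("Cu(H2O)4^2+", "free", None,
     (1.6, -27.8, 38.7, 0.8, 3.76e9, None), (22.8, -3.1, 33.4, 6.9, 5.70e7, None)),
    ("[Cu(H3Glg)(H2O)2]^2+", "mono", "C3C4",
     (-1.3, -28.3, 35.7, 0.4, 4.07e9, "up"), (19.9, -3.7, 29.8, 5.7, 3.63e8, "up")),
    ("[Cu(H3Glg)(H2O)2]^2+", "mono", "C4C5",
     (-1.6, -27.8, 34.8, 0.4, 4.05e9, "up"), (19.6, -3.2, 28.9, 5.7, 3.47e8, "up")),
    ("[Cu(H2Glg)(H2O)2]^+", "mono", "C3C4",
     (-0.8, -26.3, 34.3, 0.5, 3.98e9, "up"), (20.4, -1.7, 28.5, 6.3, 1.45e8, "up")),
    ("[Cu(H2Glg)(H2O)2]^+", "mono", "C4C5",
     (1.9, -25.2, 35.8, 0.8, 4.06e9, "up"), (23.2, -0.6, 29.9, 7.2, 3.29e7, "down")),
    ("[Cu(HGlg)(H2O)2]", "mono", "C3C4",
     (15.3, -18.5, 42.5, 3.4, 3.33e9, "down"), (36.5, 6.2, 36.7, 12.5, 4.19e3, "down")),
    ("[Cu(H3Glg)2]^2+", "bis", "C3C4",
     (-6.3, -26.8, 29.0, 0.0, 4.35e9, "up"), (14.9, -2.1, 22.8, 4.7, 1.43e9, "up")),
    ("[Cu(H3Glg)2]^2+", "bis", "C4C5",
     (-3.8, -26.2, 30.9, 0.2, 4.28e9, "up"), (17.4, -1.5, 24.8, 5.5, 5.34e8, "up")),
    ("[Cu(H2Glg)2]", "bis", "C4C5",
     (2.2, -19.1, 29.9, 1.0, 4.31e9, "up"), (23.4, 5.5, 23.7, 9.0, 1.51e6, "down")),
    ("[Cu(HGlg)2]^2-", "bis", "C3C4",
     (26.8, -1.7, 37.1, 8.4, 4.12e6, "down"), (48.0, 22.9, 31.0, 23.4, 4.15e-5, "down")),
]


def _build_table3() -> list[RedoxRow]:
    rows = []
    for label, stoich, motif, sup, asc in _TABLE3:
        for reductant, vals in (("superoxide", sup), ("ascorbate", asc)):
            de, dg, lam, act, k, arrow = vals
            rows.append(
                RedoxRow(label, stoich, motif, reductant, de, dg, lam, act, k, arrow)
            )
    return rows


# --------------------------------------------------------------------------
# Electron-transfer scavenging of the hydroxyl radical by the chelates
# (OIL-2 SET table): dE, dG, lambda, barrier, rate.
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SetScavengingRow:
    complex_label: str
    stoichiometry: str
    motif: str
    delta_e: float
    delta_g: float
    lamda: float
    dg_act: float
    k: float


_TABLE4 = [
    ("[Cu(H3Glg)(H2O)2]^2+", "mono", "C3C4", 15.2, 10.0, 15.1, 10.5, 1.32e5),
    ("[Cu(H3Glg)(H2O)2]^2+", "mono", "C4C5", 10.7, 7.0, 13.6, 7.8, 1.18e7),
    ("[Cu(H2Glg)(H2O)2]^+", "mono", "C3C4", -3.8, -5.1, 11.2, 0.8, 4.15e9),
    ("[Cu(H2Glg)(H2O)2]^+", "mono", "C4C5", -5.2, -7.1, 11.8, 0.5, 4.27e9),
    ("[Cu(HGlg)(H2O)2]", "mono", "C3C4", -14.0, -16.8, 12.7, 0.3, 4.16e9),
    ("[Cu(H3Glg)2]^2+", "bis", "C3C4", 18.4, 19.0, 9.3, 21.5, 1.07e-3),
    ("[Cu(H3Glg)2]^2+", "bis", "C4C5", 14.4, 15.0, 9.3, 15.8, 1.61e1),
    ("[Cu(H2Glg)2]", "bis", "C4C5", -1.1, -0.6, 9.4, 2.1, 4.49e9),
    ("[Cu(HGlg)2]^2-", "bis", "C3C4", -13.6, -12.8, 9.1, 0.4, 4.57e9),
]


def _build_table4() -> list[SetScavengingRow]:
    return [SetScavengingRow(*row) for row in _TABLE4]


# --------------------------------------------------------------------------
# Repair of oxidized biomolecule models: per-site dG, barrier and rate for
# each galangin species, with species totals and pH-7.4 overall values.
# Quality flags: "not_converged" marks the published footnote on the
# NF-Tyr radical / HGlg2- / C5 transition state; "inconsistent_print" marks
# the NF-Tyr radical monoanion overall value, whose printed overall/total
# ratio (0.405) disagrees with the species molar fraction every other row
# in the column reproduces (~0.4513).
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RepairRow:
    site: str
    delta_g: float
    dg_act: float | None
    k: float | None
    quality: str = "ok"


@dataclass(frozen=True)
class RepairSpeciesBlock:
    rows: list[RepairRow]
    k_total: float | None
    k_overall: float | None
    overall_quality: str = "ok"


@dataclass(frozen=True)
class RepairTargetFixture:
    name: str
    form: str  # "radical" | "radical-cation"
    species: dict[str, RepairSpeciesBlock]


def _rb(rows, k_total, k_overall, overall_quality="ok"):
    return RepairSpeciesBlock(
        rows=[RepairRow(*r) for r in rows],
        k_total=k_total,
        k_overall=k_overall,
        overall_quality=overall_quality,
    )


_TABLE5 = [
    RepairTargetFixture("LM", "radical", {
        "H3Glg": _rb([("C3", 11.4, None, None), ("C5", 24.3, None, None),
                      ("C7", 20.8, None, None)], None, None),
    }),
    RepairTargetFixture("2dG", "radical", {
        "H3Glg": _rb([("C3", -10.9, 19.5, 1.70e1), ("C5", -1.1, 28.0, 1.33e-4),
                      ("C7", -0.2, 22.9, 1.18e-2)], 1.70e1, 9.23e0),
        "H2Glg-": _rb([("C3", -14.2, 18.3, 1.56e2), ("C5", -3.0, 27.3, 5.62e-4)],
                      1.56e2, 7.04e1),
        "HGlg2-": _rb([("C5", -12.3, 27.4, 2.36e-4)], 2.36e-4, 1.21e-6),
    }),
    RepairTargetFixture("2dG", "radical-cation", {
        "H3Glg": _rb([("SET", 3.2, 6.8, 6.15e7)], 6.15e7, 3.34e7),
        "H2Glg-": _rb([("SET", -11.7, 0.3, 3.71e9)], 3.71e9, 1.67e9),
        "HGlg2-": _rb([("SET", -31.9, 2.2, 3.62e9)], 3.62e9, 1.86e7),
    }),
    RepairTargetFixture("NF-Cys", "radical", {
        "H3Glg": _rb([("C3", -0.7, 19.3, 9.69e0), ("C5", 9.0, 26.7, 2.07e-3),
                      ("C7", 9.9, 30.8, 3.00e-10)], 9.69e0, 5.27e0),
        "H2Glg-": _rb([("C3", -4.1, 17.5, 4.41e1), ("C5", 7.2, 18.7, 5.48e-1)],
                      4.46e1, 2.01e1),
        "HGlg2-": _rb([("C5", -2.1, 5.1, 7.52e8)], 7.52e8, 3.86e6),
    }),
    RepairTargetFixture("NF-His", "radical", {
        "H3Glg": _rb([("C3", -5.9, 22.3, 1.15e-1), ("C5", 3.8, 30.5, 3.02e-7),
                      ("C7", 4.7, 30.1, 1.19e-7)], 1.15e-1, 6.25e-2),
        "H2Glg-": _rb([("C3", -9.3, 20.9, 1.31e1), ("C5", 2.0, 28.9, 5.36e-6)],
                      1.31e0, 5.93e-1),
        "HGlg2-": _rb([("C5", -7.3, 19.4, 9.29e0)], 9.29e0, 4.72e-2),
    }),
    RepairTargetFixture("NF-Leu", "radical", {
        "H3Glg": _rb([("C3", -9.2, 17.9, 4.18e1), ("C5", 0.5, 26.0, 8.90e-5),
                      ("C7", 1.4, 24.4, 1.75e-4)], 4.18e1, 2.27e1),
        "H2Glg-": _rb([("C3", -12.6, 17.7, 9.15e1), ("C5", -1.3, 29.7, 7.11e-7)],
                      9.15e1, 4.13e1),
        "HGlg2-": _rb([("C5", -10.6, 26.4, 4.99e-4)], 4.99e-4, 2.56e-6),
    }),
    RepairTargetFixture("NF-Met", "radical", {
        "H3Glg": _rb([("C3", -7.9, 16.3, 9.61e1), ("C5", 1.8, 31.0, 3.36e-9),
                      ("C7", 2.7, 18.5, 7.06e-1)], 9.68e1, 5.26e1),
        "H2Glg-": _rb([("C3", -11.3, 16.6, 7.29e1), ("C5", 0.0, 31.3, 9.81e-8)],
                      7.29e1, 3.29e1),
        "HGlg2-": _rb([("C5", -9.4, 31.8, 3.29e-7)], 3.29e-7, 1.69e-9),
    }),
    RepairTargetFixture("NF-Trp", "radical-cation", {
        "H3Glg": _rb([("SET", 11.1, 11.8, 1.35e4)], 1.35e4, 7.34e3),
        "H2Glg-": _rb([("SET", -3.9, 1.9, 3.66e9)], 3.66e9, 1.65e9),
        "HGlg2-": _rb([("SET", -23.9, 0.7, 3.71e9)], 3.71e9, 1.90e7),
    }),
    RepairTargetFixture("NF-Tyr", "radical", {
        "H3Glg": _rb([("C3", -2.5, 15.1, 3.76e3), ("C5", 7.2, 23.8, 7.68e-4),
                      ("C7", 8.2, 18.7, 1.45e-1)], 3.76e3, 2.04e3),
        "H2Glg-": _rb([("C3", -5.9, 16.3, 2.52e2), ("C5", 5.4, 21.0, 8.78e-2)],
                      2.52e2, 1.02e2, overall_quality="inconsistent_print"),
        "HGlg2-": _rb([("C5", -3.9, 2.5, 1.77e9, "not_converged")], 1.77e9, 9.05e6),
    }),
    RepairTargetFixture("NF-Tyr", "radical-cation", {
        "H3Glg": _rb([("SET", 1.3, 5.5, 5.18e8)], 5.18e8, 2.81e8),
        "H2Glg-": _rb([("SET", -13.6, 0.0, 3.71e9)], 3.71e9, 1.67e9),
        "HGlg2-": _rb([("SET", -33.6, 3.6, 2.92e9)], 2.92e9, 1.50e7),
    }),
]


# --------------------------------------------------------------------------
# Regeneration of spent galangin radicals by superoxide: reduction dG and
# barrier, rate constant, and reprotonation free energy per site.
# --------------------------------------------------------------------------

_TABLE6 = {
    "H3Glg": [
        ("C3", -20.1, 1.3, 4.00e9, -32.6),
        ("C5", -29.6, 0.8, 3.96e9, -32.8),
        ("C7", -34.2, 0.7, 3.98e9, -29.2),
        ("SET", -49.2, 3.6, 3.98e9, None),
    ],
    "H2Glg-": [
        ("C3", -13.9, 0.7, 3.45e9, -35.1),
        ("C5", -21.3, 0.1, 3.83e9, -39.1),
        ("SET", -34.2, 1.0, 3.98e9, None),
    ],
    "HGlg2-": [
        ("C5", -7.5, 3.6, 3.09e9, -43.8),
        ("SET", -14.2, 1.6, 3.98e9, None),
    ],
}


def _build_table6() -> list[RegenerationStep]:
    steps = []
    for species, rows in _TABLE6.items():
        for site, dg, act, k, dgp in rows:
            steps.append(
                RegenerationStep(
                    species=species,
                    site_or_set=site,
                    delta_g=dg,
                    delta_g_act=act,
                    k_ref=k,
                    delta_g_protonation=dgp,
                )
            )
    return steps


_TEXT_CONSTANTS = {
    "radical_pka": HYDROPEROXYL_PKA,
    "dg_threshold": ENDERGONIC_DG_THRESHOLD,
    "media": ("lipid", "water"),
    "pka1": GALANGIN_PKA1,
    "pka2": GALANGIN_PKA2,
    "k_overall_lipid": 3.77e3,
    "k_overall_water": 6.21e4,
    "ph_scan_min_log10_k": 3.52,
    "set_parabola_apex": -25.0,
    "chelation_two_state_split": (0.85, 0.15),
}


def load_fixture(table_id: str):
    """Return the typed records for one fixture table.

    ``table1`` — hydroperoxyl scavenging (ScavengingFixture);
    ``table3`` — Cu(II) reduction comparisons (list of RedoxRow);
    ``table4`` — hydroxyl scavenging by complexes (list of SetScavengingRow);
    ``table5`` — biomolecule repair (list of RepairTargetFixture);
    ``table6`` — regeneration steps (list of RegenerationStep);
    ``text_constants`` — scalar constants quoted in the running text.
    """
    builders = {
        "table1": _build_table1,
        "table3": _build_table3,
        "table4": _build_table4,
        "table5": lambda: list(_TABLE5),
        "table6": _build_table6,
        "text_constants": lambda: dict(_TEXT_CONSTANTS),
    }
    if table_id not in builders:
        raise KeyError(f"unknown fixture id {table_id!r}; known: {FIXTURE_IDS}")
    return builders[table_id]()


# --------------------------------------------------------------------------
# Synthetic pathway ensembles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic pathway ensemble.

    Reaction free energies are drawn from Normal(dg_mean, dg_sd);
    reorganization energies uniformly from ``lamda_range``.  SET barriers
    follow the Marcus parabola plus Gaussian noise of ``dgact_noise_sd``;
    hydrogen-transfer/adduct barriers follow max(0, dG + hat_offset) plus
    the same noise, mimicking the near-linear dG/barrier correlation of
    H-transfer chemistry.  ``inverted_region_fraction`` of the SET records
    are forced into the Marcus-inverted regime (dG < -lambda).
    """

    n_species: int = 3
    n_pathways_per_species: int = 6
    dg_mean: float = 0.0
    dg_sd: float = 10.0
    lamda_range: tuple[float, float] = (10.0, 40.0)
    dgact_noise_sd: float = 0.0
    inverted_region_fraction: float = 0.0
    hat_offset: float = 17.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_pathways_per_species < 1:
            raise ValueError("ensemble dimensions must be positive")
        if self.dg_sd < 0 or self.dgact_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        lo, hi = self.lamda_range
        if not (0 < lo <= hi):
            raise ValueError("lamda_range must be a positive interval")
        if not 0.0 <= self.inverted_region_fraction <= 1.0:
            raise ValueError("inverted_region_fraction must lie in [0, 1]")


def generate_synthetic(config: SyntheticConfig) -> list[PathwayRecord]:
    """Draw a reproducible synthetic pathway ensemble (fixed seed => identical)."""
    rng = np.random.default_rng(config.seed)
    mechanisms = ("SET", "fHAT", "RAF")
    records: list[PathwayRecord] = []
    for s in range(config.n_species):
        species = f"S{s}"
        for p in range(config.n_pathways_per_species):
            mech = mechanisms[p % len(mechanisms)]
            lam = rng.uniform(*config.lamda_range)
            dg = rng.normal(config.dg_mean, config.dg_sd)
            noise = rng.normal(0.0, config.dgact_noise_sd) if config.dgact_noise_sd else 0.0
            if mech == "SET":
                inverted = rng.random() < config.inverted_region_fraction
                if inverted:
                    dg = -lam - abs(rng.normal(0.0, max(config.dg_sd, 1.0)))
                else:
                    while dg < -lam:  # keep normal-region draws out of inversion
                        dg = rng.normal(config.dg_mean, config.dg_sd)
                dg_act = max(0.0, marcus_barrier(dg, lam) + noise)
            else:
                dg_act = max(0.0, dg + config.hat_offset + noise)
            records.append(
                PathwayRecord(
                    species=species,
                    mechanism=str(mech),
                    site=f"{mech}{p}",
                    medium="water",
                    delta_g=dg,
                    delta_g_act=dg_act,
                    lamda=lam if mech == "SET" else None,
                )
            )
    return records


# --------------------------------------------------------------------------
# Delimited-table I/O
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("species", "mechanism", "site", "medium")
_OPTIONAL_FLOATS = ("dG", "dG_act", "lambda", "kappa", "sigma", "k_ref", "gamma_ref")

# "2.50 × 10^9" and friends -> 2.50e9.  Handles unicode minus and the
# multiplication sign; plain floats pass through unchanged.
_SCI_RE = re.compile(
    r"^\s*(?P<mant>[-−]?\d+(?:\.\d+)?)\s*[x×✕*]\s*10\^?\{?(?P<exp>[-−+]?\d+)\}?\s*$"
)


def parse_scientific(cell: str | float) -> float:
    """Parse a numeric cell, accepting publisher-style scientific notation."""
    if isinstance(cell, (int, float)):
        return float(cell)
    text = str(cell).strip().replace("−", "-")
    m = _SCI_RE.match(text)
    if m:
        return float(m.group("mant")) * 10.0 ** int(m.group("exp"))
    return float(text)


def write_pathways(records: list[PathwayRecord], path) -> None:
    """Write records as a delimited table (full float precision round-trips)."""
    extra_cols: list[str] = []
    for r in records:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for r in records:
        row = {
            "species": r.species,
            "mechanism": r.mechanism,
            "site": r.site,
            "medium": r.medium,
            "dG": r.delta_g,
            "dG_act": r.delta_g_act,
            "lambda": r.lamda,
            "kappa": r.kappa,
            "sigma": r.sigma,
            "k_ref": r.k_ref,
            "gamma_ref": r.gamma_ref,
        }
        row.update({c: r.extra.get(c) for c in extra_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pathways(path) -> list[PathwayRecord]:
    """Read a delimited pathway table, validating the header and every row.

    Unknown columns are preserved in ``PathwayRecord.extra``; malformed
    rows are reported with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pathway table missing required column(s): {', '.join(missing)}")
    known = set(_REQUIRED_COLUMNS) | set(_OPTIONAL_FLOATS)
    extra_cols = [c for c in df.columns if c not in known]

    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            def fnum(col, default=None):
                val = row.get(col, "")
                if val == "" or val is None:
                    return default
                return parse_scientific(val)

            records.append(
                PathwayRecord(
                    species=row["species"],
                    mechanism=row["mechanism"],
                    site=row["site"],
                    medium=row["medium"] or "water",
                    delta_g=fnum("dG"),
                    delta_g_act=fnum("dG_act"),
                    lamda=fnum("lambda"),
                    kappa=fnum("kappa", 1.0),
                    sigma=int(fnum("sigma", 1)),
                    k_ref=fnum("k_ref"),
                    gamma_ref=fnum("gamma_ref"),
                    extra={c: row[c] for c in extra_cols if row[c] != ""},
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("malformed pathway rows:\n" + "\n".join(errors))
    return records
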