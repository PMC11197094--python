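"""YAML/JSON configuration loading for speciation and medium parameters.

A config file looks like::

    ladder:
      labels: [H3Glg, H2Glg-, HGlg2-]
      pkas: [7.4803, 9.3446]
    radical_pair:
      protonated_label: OOH*
      deprotonated_label: O2*-
      pka: 4.8
    medium:
      temperature: 298.15
      viscosity: 8.91e-4
      radius_antioxidant: 4.0
      radius_radical: 2.0

Any section may be omitted; package defaults fill the gaps.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .constants import WATER_VISCOSITY, DEFAULT_TEMPERATURE
from .datasets import galangin_ladder, hydroperoxyl_pair
from .kinetics import DiffusionInputs, KineticContext
from .speciation import ProtonationLadder, RadicalAcidBasePair

__all__ = ["load_config", "AnalysisConfig"]


class AnalysisConfig:
    """Resolved configuration: ladder, radical pair, kinetic/diffusion context."""

    def __init__(self, ladder, radical_pair, context, diffusion):
        self.ladder = ladder
        self.radical_pair = radical_pair
        self.context = context
        self.diffusion = diffusion


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an analysis configuration, falling back to galangin defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}

    if "ladder" in raw:
        ladder = ProtonationLadder(raw["ladder"]["labels"], raw["ladder"]["pkas"])
    else:
        ladder = galangin_ladder()

    if "radical_pair" in raw:
        rp = raw["radical_pair"]
        pair = RadicalAcidBasePair(rp["protonated_label"], rp["deprotonated_label"], rp["pka"])
    else:
        pair = hydroperoxyl_pair()

    medium = raw.get("medium", {})
    context = KineticContext(temperature=medium.get("temperature", DEFAULT_TEMPERATURE))
    diffusion = DiffusionInputs(
        radius_a=medium.get("radius_antioxidant", 4.0),
        radius_b=medium.get("radius_radical", 2.0),
        viscosity=medium.get("viscosity", WATER_VISCOSITY),
        temperature=medium.get("temperature", DEFAULT_TEMPERATURE),
    )
    return AnalysisConfig(ladder, pair, context, diffusion)
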