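"""YAML model/ladder specifications and the shipped presets.

A model file maps model names to ordered rule lists; each rule is a
mapping with a ``param`` name and optional ``species``, ``context``,
``gene_class``, ``compartment`` selectors (string, list, or "*").
A ladder file additionally names ``tiers``: lists of model names in
coarse-to-fine order.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .likelihood import PartitionModel
from .model_selection import Ladder

PRESET_LADDERS = {
    "species-context": "species_context.yaml",
    "divergence-class": "divergence_class.yaml",
    "polymorphism-class": "polymorphism_class.yaml",
    "compartment": "compartment.yaml",
}
PRESET_MODELS_FILE = "models.yaml"


def _load_yaml(source: Union[str, Path, dict]) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def models_from_config(config: Union[str, Path, dict]) -> dict[str, PartitionModel]:
    doc = _load_yaml(config)
    models_doc = doc.get("models", doc)
    out = {}
    for name, rules in models_doc.items():
        out[name] = PartitionModel.from_dicts(str(name), rules)
    return out


def ladder_from_config(config: Union[str, Path, dict]) -> Ladder:
    doc = _load_yaml(config)
    if "tiers" not in doc:
        raise ValueError("ladder config needs a 'tiers' list")
    models = models_from_config(doc)
    tiers = []
    for tier in doc["tiers"]:
        missing = [n for n in tier if n not in models]
        if missing:
            raise ValueError(f"tier references undefined model(s) {missing}")
        tiers.append([models[n] for n in tier])
    return Ladder(name=str(doc.get("name", "ladder")), tiers=tiers)


def _preset_text(filename: str) -> dict:
    ref = resources.files("mknest.presets").joinpath(filename)
    return yaml.safe_load(ref.read_text())


def preset_ladder(name: str) -> Ladder:
    """Load one of the shipped ladders by name (see PRESET_LADDERS)."""
    if name not in PRESET_LADDERS:
        raise KeyError(
            f"unknown preset ladder {name!r}; available: {sorted(PRESET_LADDERS)}"
        )
    return ladder_from_config(_preset_text(PRESET_LADDERS[name]))


def preset_model(name: str) -> PartitionModel:
    """Load a shipped stand-alone model ('full12' or 'selected9')."""
    models = models_from_config(_preset_text(PRESET_MODELS_FILE))
    if name not in models:
        raise KeyError(f"unknown preset model {name!r}; available: {sorted(models)}")
    return models[name]
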