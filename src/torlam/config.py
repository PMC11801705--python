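"""YAML/JSON configuration documents.

A configuration bundles the three declarative inputs of a run: the
molecule's torsion-space specification, the synthetic-model parameters,
and the per-torsion reference-grid specifications.  Angles are degrees,
energies kJ/mol, charges e, as everywhere in the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import yaml

from .grids import TorsionGrid
from .molecule import MoleculeSpec
from .synthetic import SyntheticModelParams

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def config_to_dict(
    molecule: MoleculeSpec,
    params: SyntheticModelParams | None = None,
    grids: Mapping[str, TorsionGrid] | None = None,
) -> dict:
    doc: dict = {"molecule": molecule.to_dict()}
    if params is not None:
        doc["model"] = params.to_dict()
    if grids is not None:
        doc["grids"] = {name: g.to_dict() for name, g in grids.items()}
    return doc


def config_from_dict(doc: Mapping):
    """Parse a configuration document -> (molecule, params, grids).

    ``model`` and ``grids`` sections are optional and return ``None`` when
    absent.  A ``model`` section may either spell out all parameters or
    request deterministic random generation via ``randomized:``.
    """
    molecule = MoleculeSpec.from_dict(doc["molecule"])
    params = None
    if "model" in doc:
        model_doc = doc["model"]
        if "randomized" in model_doc:
            opts = dict(model_doc["randomized"])
            params = SyntheticModelParams.randomized(molecule, **opts)
        else:
            params = SyntheticModelParams.from_dict(model_doc)
        params.validate_for(molecule)
    grids = None
    if "grids" in doc:
        grids = {
            str(name): TorsionGrid.from_dict(g) for name, g in doc["grids"].items()
        }
        missing = set(molecule.torsion_names) - set(grids)
        if missing:
            raise ValueError(f"grids missing for torsions: {sorted(missing)}")
    return molecule, params, grids


def load_config(path):
    """Load a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValueError(f"configuration file {path} does not contain a mapping")
    return config_from_dict(doc)


def save_config(
    path,
    molecule: MoleculeSpec,
    params: SyntheticModelParams | None = None,
    grids: Mapping[str, TorsionGrid] | None = None,
) -> None:
    doc = config_to_dict(molecule, params, grids)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
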