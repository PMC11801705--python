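"""Torsion-space description of a flexible molecule.

The conformational state of a molecule is split into *independent* degrees
of freedom — the flexible torsions theta, in degrees on [0, 360) — and
*dependent* degrees of freedom (bond lengths, bond angles, non-flexible
torsions) that relax to their optimal values whenever the torsions are held
fixed.  The torsions are further partitioned into disjoint *torsional
groups* that are assumed to contribute additively to deviations of energy,
geometry and atomic charges from the in vacuo conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DOF_CATEGORIES",
    "DependentDof",
    "MoleculeSpec",
    "wrap_angle",
]

#: Valid categories for a dependent degree of freedom.
DOF_CATEGORIES = ("bond_length", "bond_angle", "torsion")

#: Units accepted per category.
_CATEGORY_UNITS = {
    "bond_length": "angstrom",
    "bond_angle": "degrees",
    "torsion": "degrees",
}


def wrap_angle(theta):
    """Map angles (degrees) onto the canonical domain [0, 360)."""
    return np.mod(np.asarray(theta, dtype=float), 360.0)


@dataclass(frozen=True)
class DependentDof:
    """One dependent degree of freedom: a label, its category and units."""

    label: str
    category: str
    units: str

    def __post_init__(self):
        if self.category not in DOF_CATEGORIES:
            raise ValueError(
                f"unknown dependent-DoF category {self.category!r}; "
                f"expected one of {DOF_CATEGORIES}"
            )
        expected = _CATEGORY_UNITS[self.category]
        if self.units != expected:
            raise ValueError(
                f"dependent DoF {self.label!r} of category {self.category!r} "
                f"must use units {expected!r}, got {self.units!r}"
            )

    def to_dict(self) -> dict:
        return {"label": self.label, "category": self.category, "units": self.units}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DependentDof":
        return cls(str(d["label"]), str(d["category"]), str(d["units"]))


@dataclass(frozen=True)
class MoleculeSpec:
    """Declarative torsion-space model of a flexible molecule.

    Parameters
    ----------
    torsion_names
        Ordered labels of the ``l`` independent flexible torsions.
    groups
        Partition of torsion indices into disjoint, covering, non-empty
        torsional groups.  Group ``g`` is assumed to affect energy,
        dependent DoFs and charges additively with respect to every other
        group.
    dependent_dofs
        Ordered schema of the dependent degrees of freedom (``M`` entries).
    charge_labels
        Ordered labels of the atoms carrying one point charge (e) each.
    """

    torsion_names: tuple[str, ...]
    groups: tuple[tuple[int, ...], ...]
    dependent_dofs: tuple[DependentDof, ...]
    charge_labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "torsion_names", tuple(self.torsion_names))
        object.__setattr__(
            self, "groups", tuple(tuple(int(i) for i in g) for g in self.groups)
        )
        object.__setattr__(self, "dependent_dofs", tuple(self.dependent_dofs))
        object.__setattr__(self, "charge_labels", tuple(self.charge_labels))

        if not self.torsion_names:
            raise ValueError("molecule must declare at least one torsion")
        if len(set(self.torsion_names)) != len(self.torsion_names):
            raise ValueError("torsion names must be unique")
        if not self.groups or any(len(g) == 0 for g in self.groups):
            raise ValueError("torsional groups must be non-empty")
        flat = [i for g in self.groups for i in g]
        if sorted(flat) != list(range(len(self.torsion_names))):
            raise ValueError(
                "groups must partition the torsion indices: every torsion in "
                "exactly one group"
            )
        if not self.dependent_dofs:
            raise ValueError("dependent-DoF schema must be non-empty")
        labels = [d.label for d in self.dependent_dofs]
        if len(set(labels)) != len(labels):
            raise ValueError("dependent-DoF labels must be unique")
        if not self.charge_labels:
            raise ValueError("charge schema must be non-empty")
        if len(set(self.charge_labels)) != len(self.charge_labels):
            raise ValueError("charge labels must be unique")

    # -- dimensions ---------------------------------------------------------

    @property
    def n_torsions(self) -> int:
        return len(self.torsion_names)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_dependent(self) -> int:
        return len(self.dependent_dofs)

    @property
    def n_charges(self) -> int:
        return len(self.charge_labels)

    def group_indices(self, group_id: int) -> np.ndarray:
        """Torsion indices belonging to group ``group_id`` (0-based)."""
        return np.asarray(self.groups[group_id], dtype=int)

    def category_mask(self, category: str) -> np.ndarray:
        """Boolean mask over the dependent-DoF schema for one category."""
        if category not in DOF_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return np.array([d.category == category for d in self.dependent_dofs])

    def as_single_group(self) -> "MoleculeSpec":
        """The same molecule with all torsions merged into one group.

        Used to build non-partitioned reference databases: with a single
        group the additivity rule degenerates to a plain nearest-reference
        Taylor expansion over the full torsion vector.
        """
        return MoleculeSpec(
            torsion_names=self.torsion_names,
            groups=(tuple(range(self.n_torsions)),),
            dependent_dofs=self.dependent_dofs,
            charge_labels=self.charge_labels,
        )

    def validate_theta(self, theta) -> np.ndarray:
        """Check and wrap a full torsion vector; returns it on [0, 360)."""
        arr = np.asarray(theta, dtype=float)
        if arr.shape != (self.n_torsions,):
            raise ValueError(
                f"expected {self.n_torsions} torsion values, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("torsion values must be finite")
        return wrap_angle(arr)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "torsions": list(self.torsion_names),
            "groups": [[self.torsion_names[i] for i in g] for g in self.groups],
            "dependent_dofs": [d.to_dict() for d in self.dependent_dofs],
            "charges": list(self.charge_labels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MoleculeSpec":
        names = [str(t) for t in d["torsions"]]
        index = {n: i for i, n in enumerate(names)}
        groups = tuple(
            tuple(index[str(t)] for t in g) for g in d["groups"]
        )
        return cls(
            torsion_names=tuple(names),
            groups=groups,
            dependent_dofs=tuple(
                DependentDof.from_dict(x) for x in d["dependent_dofs"]
            ),
            charge_labels=tuple(str(c) for c in d["charges"]),
        )
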