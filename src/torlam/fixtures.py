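"""Ready-made example molecules, synthetic-model parameters and grids.

Each fixture returns ``(molecule, params, grids)``: a torsion-space
specification, a synthetic conformational model standing in for the QM
oracle, and per-torsion reference grids.  The fixtures mirror the standard
benchmark layouts for torsional-group partitioning:

* ``two-torsion``   — two one-torsion groups on a 60-degree wraparound
  grid with first point at 30 degrees (6 references per group);
* ``paraben-like``  — three torsions, groups {t1} and {t2, t3}, same
  wraparound grids (6 + 36 references, 43 oracle minimizations in total);
* ``paracetamol-like`` — three torsions, groups {t1} and {t2, t3}, bounded
  grids of 3, 5 and 5 points (29 vs 76 oracle minimizations);
* ``xx-like``       — eight torsions, groups {t1..t3} and {t4..t8}, the
  benchmark bounded grids with 27 and 162 initial references;
* ``xx-restricted`` — the same molecule on a narrow two-point-per-torsion
  grid around a near-experimental midpoint (8 + 16 references vs 2^7).
"""

from __future__ import annotations

from typing import Mapping

from .grids import TorsionGrid
from .molecule import DependentDof, MoleculeSpec
from .synthetic import SyntheticModelParams

__all__ = ["FIXTURES", "make_fixture", "fixture_names"]


def _dofs(n_lengths: int, n_angles: int, n_torsions: int) -> tuple:
    dofs = []
    for i in range(n_lengths):
        dofs.append(DependentDof(f"r{i + 1}", "bond_length", "angstrom"))
    for i in range(n_angles):
        dofs.append(DependentDof(f"a{i + 1}", "bond_angle", "degrees"))
    for i in range(n_torsions):
        dofs.append(DependentDof(f"phi{i + 1}", "torsion", "degrees"))
    return tuple(dofs)


def _charges(n: int) -> tuple:
    return tuple(f"q{i + 1}" for i in range(n))


def two_torsion(seed: int = 11, epsilon: float = 0.0):
    """Two torsions in two trivial one-torsion groups, 60-degree grids."""
    molecule = MoleculeSpec(
        torsion_names=("t1", "t2"),
        groups=((0,), (1,)),
        dependent_dofs=_dofs(2, 2, 1),
        charge_labels=_charges(6),
    )
    params = SyntheticModelParams.randomized(
        molecule, seed=seed, cross_coupling_epsilon=epsilon
    )
    grids = {
        "t1": TorsionGrid.wraparound(60.0, offset=30.0),
        "t2": TorsionGrid.wraparound(60.0, offset=30.0),
    }
    return molecule, params, grids


def paraben_like(seed: int = 23, epsilon: float = 0.05):
    """Three torsions: an isolated hydroxyl-like torsion vs an ester-like
    pair whose members interact sterically (intra-group coupling)."""
    molecule = MoleculeSpec(
        torsion_names=("t1", "t2", "t3"),
        groups=((0,), (1, 2)),
        dependent_dofs=_dofs(4, 4, 2),
        charge_labels=_charges(10),
    )
    params = SyntheticModelParams.randomized(
        molecule,
        seed=seed,
        cross_coupling_epsilon=epsilon,
        amplitude_range=(8.0, 16.0),
        intra_coupling_amplitude=4.0,
    )
    grids = {name: TorsionGrid.wraparound(60.0, offset=30.0) for name in molecule.torsion_names}
    return molecule, params, grids


def paracetamol_like(seed: int = 31, epsilon: float = 0.05):
    """Three torsions on narrow bounded grids of 3, 5 and 5 points."""
    molecule = MoleculeSpec(
        torsion_names=("t1", "t2", "t3"),
        groups=((0,), (1, 2)),
        dependent_dofs=_dofs(4, 4, 2),
        charge_labels=_charges(10),
    )
    params = SyntheticModelParams.randomized(
        molecule,
        seed=seed,
        cross_coupling_epsilon=epsilon,
        intra_coupling_amplitude=3.0,
    )
    grids = {
        "t1": TorsionGrid.bounded(-30.0, 30.0, 30.0),
        "t2": TorsionGrid.bounded(120.0, 30.0, 240.0),
        "t3": TorsionGrid.bounded(120.0, 30.0, 240.0),
    }
    return molecule, params, grids


_XX_GRIDS = {
    "t1": TorsionGrid.bounded(60.0, 120.0, 300.0),
    "t2": TorsionGrid.bounded(-30.0, 120.0, 210.0),
    "t3": TorsionGrid.bounded(60.0, 120.0, 300.0),
    "t4": TorsionGrid.bounded(-120.0, 120.0, 120.0),
    "t5": TorsionGrid.bounded(0.0, 180.0, 180.0),
    "t6": TorsionGrid.bounded(60.0, 120.0, 300.0),
    "t7": TorsionGrid.bounded(30.0, 120.0, 270.0),
    "t8": TorsionGrid.bounded(-30.0, 120.0, 210.0),
}


def _xx_molecule() -> MoleculeSpec:
    return MoleculeSpec(
        torsion_names=tuple(f"t{i + 1}" for i in range(8)),
        groups=((0, 1, 2), (3, 4, 5, 6, 7)),
        dependent_dofs=_dofs(6, 6, 3),
        charge_labels=_charges(14),
    )


def xx_like(seed: int = 47, epsilon: float = 0.05):
    """Eight torsions in a 3-torsion and a 5-torsion group, wide grids
    (27 and 162 initial references)."""
    molecule = _xx_molecule()
    params = SyntheticModelParams.randomized(
        molecule,
        seed=seed,
        cross_coupling_epsilon=epsilon,
        intra_coupling_amplitude=3.0,
    )
    return molecule, params, dict(_XX_GRIDS)


def xx_restricted(seed: int = 47, epsilon: float = 0.05):
    """The eight-torsion molecule on a narrow two-point-per-torsion grid
    around a near-experimental midpoint; one point only for t6."""
    molecule = _xx_molecule()
    params = SyntheticModelParams.randomized(
        molecule,
        seed=seed,
        cross_coupling_epsilon=epsilon,
        intra_coupling_amplitude=3.0,
    )
    midpoints = {
        "t1": 110.0,
        "t2": 90.0,
        "t3": 180.0,
        "t4": 0.0,
        "t5": 180.0,
        "t7": 270.0,
        "t8": 270.0,
    }
    grids = {
        name: TorsionGrid.bounded(mid - 15.0, 30.0, mid + 15.0)
        for name, mid in midpoints.items()
    }
    grids["t6"] = TorsionGrid.explicit([180.0])
    return molecule, params, grids


FIXTURES = {
    "two-torsion": two_torsion,
    "paraben-like": paraben_like,
    "paracetamol-like": paracetamol_like,
    "xx-like": xx_like,
    "xx-restricted": xx_restricted,
}


def fixture_names() -> list[str]:
    return sorted(FIXTURES)


def make_fixture(name: str, **kwargs):
    """Instantiate a named fixture: ``(molecule, params, grids)``."""
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return factory(**kwargs)
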