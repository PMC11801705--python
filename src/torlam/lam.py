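"""Local approximate models (LAMs) and the group-additivity evaluation rule.

A LAM is a Taylor-expansion surrogate anchored at a reference point where
one constrained minimization was performed: second order in the
intramolecular energy, first order in the dependent degrees of freedom and
the atomic charges.  With torsional-group partitioning, each group g keeps
its own set of reference points, fitted with all other groups pinned at
their in vacuo torsions; a query conformation is evaluated by expanding
each group around its nearest reference and summing the per-group
deviations on top of the in vacuo values:

    U(theta)  = U_vac  + sum_g [ (U_ref - U_vac) + b.d + d.H.d / 2 ]
    beta      = b_vac  + sum_g [ (beta_ref - beta_vac) + K d ]
    q         = q_vac  + sum_g [ (q_ref - q_vac) + A d ]

with d the wrapped deviation of the group's torsions from the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ledger import CallLedger
from .molecule import MoleculeSpec, wrap_angle
from .oracle import ConformationalModel, VacuoRecord, minimize_at, minimize_vacuo

__all__ = [
    "wrap_deviation",
    "ReferenceRecord",
    "GroupDatabase",
    "PartitionedDatabase",
    "GroupContribution",
    "EvaluationResult",
    "nearest_reference",
    "fit_reference",
    "reference_from_record",
    "evaluate_group",
    "evaluate",
    "rebase_vacuo",
]


def wrap_deviation(theta, theta_ref):
    """Signed angular deviation ``theta - theta_ref`` mapped into (-180, 180].

    Vectorized over arrays of torsion values (degrees).  Keeps Taylor
    expansions local on the periodic torsion domain.
    """
    theta = np.asarray(theta, dtype=float)
    theta_ref = np.asarray(theta_ref, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(theta_ref))):
        raise ValueError("wrap_deviation requires finite inputs")
    d = np.mod(theta - theta_ref, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


@dataclass
class ReferenceRecord:
    """One LAM anchor for a torsional group.

    ``U_ref``, ``beta_ref`` and ``q_ref`` are the constrained-minimum
    outputs with this group's torsions at ``theta_ref`` and every other
    group at its in vacuo values; ``b``, ``H``, ``K``, ``A`` are the
    group-subblock derivative matrices extracted at that solution.
    """

    group_id: int
    theta_ref: np.ndarray  # (d,) degrees
    U_ref: float
    beta_ref: np.ndarray  # (M,)
    q_ref: np.ndarray  # (A,)
    b: np.ndarray  # (d,) kJ/mol/deg
    H: np.ndarray  # (d, d) kJ/mol/deg^2
    K: np.ndarray  # (M, d)
    A: np.ndarray  # (A, d)

    def __post_init__(self):
        self.theta_ref = wrap_angle(np.atleast_1d(np.asarray(self.theta_ref, float)))
        for name in ("beta_ref", "q_ref", "b", "H", "K", "A"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d = self.theta_ref.shape[0]
        if self.b.shape != (d,) or self.H.shape != (d, d):
            raise ValueError("derivative block shapes inconsistent with theta_ref")
        if self.K.shape[1] != d or self.A.shape[1] != d:
            raise ValueError("Jacobian blocks inconsistent with group dimension")
        if d and np.max(np.abs(self.H - self.H.T)) > 1e-8 * max(
            1.0, float(np.max(np.abs(self.H)))
        ):
            raise ValueError("reference Hessian block must be symmetric")

    @property
    def dim(self) -> int:
        return self.theta_ref.shape[0]


@dataclass
class GroupDatabase:
    """All LAM reference records of one torsional group."""

    group_id: int
    member_indices: np.ndarray
    records: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=int)

    @property
    def dim(self) -> int:
        return self.member_indices.shape[0]

    def add_record(self, record: ReferenceRecord, wrap_tol: float = 1e-6) -> None:
        if record.dim != self.dim:
            raise ValueError("record dimensionality does not match the group")
        for existing in self.records:
            if np.max(np.abs(wrap_deviation(record.theta_ref, existing.theta_ref))) < wrap_tol:
                raise ValueError(
                    f"duplicate reference point {record.theta_ref} in group "
                    f"{self.group_id}"
                )
        self.records.append(record)

    def theta_refs(self) -> np.ndarray:
        return np.array([r.theta_ref for r in self.records])


@dataclass
class PartitionedDatabase:
    """A LAM database: the in vacuo record plus one GroupDatabase per group."""

    molecule: MoleculeSpec
    vacuo: VacuoRecord
    group_dbs: list
    ledger: CallLedger = field(default_factory=CallLedger)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        covered = sorted(
            int(i) for gdb in self.group_dbs for i in gdb.member_indices
        )
        if covered != list(range(self.molecule.n_torsions)):
            raise ValueError("group databases must cover every torsion exactly once")

    def group_db(self, group_id: int) -> GroupDatabase:
        for gdb in self.group_dbs:
            if gdb.group_id == group_id:
                return gdb
        raise KeyError(f"no group database with id {group_id}")

    def is_stale(self, tol: float = 1e-9) -> bool:
        """True if any stored reference lies below the current in vacuo energy.

        Such a database predates a needed vacuo rebase; see
        :func:`rebase_vacuo`.
        """
        for gdb in self.group_dbs:
            for rec in gdb.records:
                if rec.U_ref < self.vacuo.U_vac - tol:
                    return True
        return False

    @property
    def n_references(self) -> int:
        return sum(len(gdb.records) for gdb in self.group_dbs)


@dataclass(frozen=True)
class GroupContribution:
    """Provenance of one group's share of an evaluation."""

    group_id: int
    reference_index: int
    delta_U: float


@dataclass
class EvaluationResult:
    """LAM reconstruction of energy, geometry and charges at a query point."""

    delta_U: float
    beta: np.ndarray
    charges: np.ndarray
    per_group: list
    below_vacuo: bool = False


def nearest_reference(group_db: GroupDatabase, theta_g) -> int:
    """Index of the record nearest to ``theta_g`` in wrapped Euclidean norm.

    Ties break to the lowest record index.
    """
    if not group_db.records:
        raise ValueError(f"group {group_db.group_id} has no reference records")
    theta_g = np.atleast_1d(np.asarray(theta_g, dtype=float))
    if theta_g.shape != (group_db.dim,):
        raise ValueError(
            f"query has shape {theta_g.shape}, group dimension is {group_db.dim}"
        )
    devs = wrap_deviation(theta_g[None, :], group_db.theta_refs())
    return int(np.argmin(np.linalg.norm(devs, axis=1)))


def reference_from_record(
    molecule: MoleculeSpec, group_id: int, record
) -> ReferenceRecord:
    """Extract a group's LAM blocks from a full constrained-minimum record."""
    idx = molecule.group_indices(group_id)
    return ReferenceRecord(
        group_id=group_id,
        theta_ref=record.theta[idx],
        U_ref=record.energy,
        beta_ref=record.beta,
        q_ref=record.charges,
        b=record.grad_energy[idx],
        H=record.hess_energy[np.ix_(idx, idx)],
        K=record.jac_beta[:, idx],
        A=record.jac_charges[:, idx],
    )


def fit_reference(
    model: ConformationalModel,
    molecule: MoleculeSpec,
    group_id: int,
    theta_ref_g,
    vacuo: VacuoRecord,
) -> ReferenceRecord:
    """Fit one LAM: constrained minimization with other groups at vacuo.

    Assembles the full torsion vector with group ``group_id`` at
    ``theta_ref_g`` and every other torsion at its in vacuo value, runs the
    oracle, and extracts the group-subblock derivative matrices.
    """
    idx = molecule.group_indices(group_id)
    theta_ref_g = np.atleast_1d(np.asarray(theta_ref_g, dtype=float))
    if theta_ref_g.shape != (idx.shape[0],):
        raise ValueError(
            f"reference point has shape {theta_ref_g.shape}, group "
            f"{group_id} holds {idx.shape[0]} torsions"
        )
    theta = np.array(vacuo.theta_vac, dtype=float)
    theta[idx] = theta_ref_g
    record = minimize_at(model, theta)
    return reference_from_record(molecule, group_id, record)


def evaluate_group(record: ReferenceRecord, theta_g, vacuo: VacuoRecord):
    """Taylor-evaluate one group's deviations from the in vacuo values.

    Returns ``(delta_U_g, delta_beta_g, delta_q_g)`` with the deviation
    vector wrapped into (-180, 180].
    """
    theta_g = np.atleast_1d(np.asarray(theta_g, dtype=float))
    if theta_g.shape != (record.dim,):
        raise ValueError(
            f"query has shape {theta_g.shape}, record dimension is {record.dim}"
        )
    d = wrap_deviation(theta_g, record.theta_ref)
    delta_U = (
        record.U_ref
        - vacuo.U_vac
        + float(record.b @ d)
        + 0.5 * float(d @ record.H @ d)
    )
    delta_beta = (record.beta_ref - vacuo.beta_vac) + record.K @ d
    delta_q = (record.q_ref - vacuo.q_vac) + record.A @ d
    return delta_U, delta_beta, delta_q


def evaluate(db: PartitionedDatabase, theta) -> EvaluationResult:
    """Nearest-reference LAM evaluation with the group-additivity rule."""
    theta = db.molecule.validate_theta(theta)
    delta_U = 0.0
    beta = np.array(db.vacuo.beta_vac, dtype=float)
    charges = np.array(db.vacuo.q_vac, dtype=float)
    per_group = []
    for gdb in db.group_dbs:
        theta_g = theta[gdb.member_indices]
        ref_idx = nearest_reference(gdb, theta_g)
        dU, dbeta, dq = evaluate_group(gdb.records[ref_idx], theta_g, db.vacuo)
        delta_U += dU
        beta += dbeta
        charges += dq
        per_group.append(GroupContribution(gdb.group_id, ref_idx, dU))
    return EvaluationResult(
        delta_U=delta_U,
        beta=beta,
        charges=charges,
        per_group=per_group,
        below_vacuo=delta_U < -1e-9,
    )


def rebase_vacuo(
    db: PartitionedDatabase, model: ConformationalModel, theta_new
) -> PartitionedDatabase:
    """Adopt a newly found lower in vacuo minimum and refit all references.

    Re-minimizes from ``theta_new``; if the confirmed minimum undercuts the
    stored ``U_vac``, a new database is returned with the vacuo record
    replaced and every reference refitted (other-group torsions pinned to
    the new vacuo values).  Otherwise the original database is returned
    unchanged with a warning.  The refit costs one oracle minimization per
    reference plus one for the new vacuo point, all logged to the ledger.
    """
    theta_new = db.molecule.validate_theta(theta_new)
    candidate = minimize_vacuo(model, [theta_new])
    if candidate.U_vac >= db.vacuo.U_vac - 1e-9:
        warnings.warn(
            "rebase_vacuo: candidate does not undercut the stored in vacuo "
            "minimum; database unchanged",
            stacklevel=2,
        )
        return db

    ledger = db.ledger.copy()
    ledger.add("rebase", 1)  # the confirming vacuo minimization
    new_group_dbs = []
    for gdb in db.group_dbs:
        new_gdb = GroupDatabase(
            group_id=gdb.group_id,
            member_indices=np.array(gdb.member_indices),
            provenance=dict(gdb.provenance),
        )
        for rec in gdb.records:
            new_gdb.add_record(
                fit_reference(model, db.molecule, gdb.group_id, rec.theta_ref, candidate)
            )
            ledger.add("rebase", 1)
        new_group_dbs.append(new_gdb)

    provenance = dict(db.provenance)
    history = list(provenance.get("rebase_history", []))
    history.append(
        {
            "old_U_vac": float(db.vacuo.U_vac),
            "new_U_vac": float(candidate.U_vac),
            "theta_new": [float(x) for x in theta_new],
            "oracle_calls": db.n_references + 1,
        }
    )
    provenance["rebase_history"] = history
    return PartitionedDatabase(
        molecule=db.molecule,
        vacuo=candidate,
        group_dbs=new_group_dbs,
        ledger=ledger,
        provenance=provenance,
    )
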