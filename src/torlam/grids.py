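"""Reference grids, database construction, call accounting and refinement.

Two uniform-grid dialects are supported:

* ``bounded`` — explicit ``[lower, increment, upper]`` with inclusive
  endpoints, e.g. [60, 120, 300] -> {60, 180, 300};
* ``wraparound`` — a spacing dividing 360 plus an offset, spanning the
  whole circle, e.g. spacing 60 with first point at 30 ->
  {30, 90, 150, 210, 270, 330}.

A partitioned database needs ``sum_g N_g,ref + 1`` oracle minimizations
(one per reference plus the in vacuo point); a non-partitioned database of
the same per-torsion resolution needs ``prod_t N_t + 1``.  The adaptive
variant inserts extra references wherever the surrogate error inside the
crystallographically relevant region exceeds a tolerance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ledger import CallLedger
from .lam import (
    GroupDatabase,
    PartitionedDatabase,
    evaluate_group,
    fit_reference,
    nearest_reference,
    reference_from_record,
)
from .molecule import MoleculeSpec, wrap_angle
from .oracle import ConformationalModel, VacuoRecord, default_starts, minimize_at, minimize_vacuo

__all__ = [
    "TorsionGrid",
    "LedgerProjection",
    "build_uniform_grid",
    "build_group_database",
    "build_partitioned_database",
    "build_full_database",
    "grid_group_sizes",
    "projected_call_counts",
    "percent_reduction",
    "adaptive_refine",
    "validation_max_error",
]


@dataclass(frozen=True)
class TorsionGrid:
    """Reference-point positions for one torsion.

    ``points`` keep the dialect's native values (possibly negative
    degrees); they are wrapped onto [0, 360) only when a full torsion
    vector is assembled.  ``domain`` is the interval candidates may occupy
    during adaptive refinement.
    """

    points: tuple
    dialect: str
    domain: tuple  # (lower, upper) in native degrees

    @classmethod
    def bounded(cls, lower: float, increment: float, upper: float) -> "TorsionGrid":
        if increment <= 0:
            raise ValueError("grid increment must be positive")
        span = upper - lower
        n_steps = span / increment
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"(upper - lower) = {span} not divisible by increment {increment}"
            )
        pts = tuple(lower + k * increment for k in range(int(round(n_steps)) + 1))
        return cls(points=pts, dialect="bounded", domain=(float(lower), float(upper)))

    @classmethod
    def wraparound(cls, increment: float, offset: float = 0.0) -> "TorsionGrid":
        if increment <= 0:
            raise ValueError("grid increment must be positive")
        n = 360.0 / increment
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"360 not divisible by increment {increment}")
        pts = tuple(
            float(np.mod(offset + k * increment, 360.0)) for k in range(int(round(n)))
        )
        return cls(points=pts, dialect="wraparound", domain=(0.0, 360.0))

    @classmethod
    def explicit(cls, points: Sequence[float]) -> "TorsionGrid":
        pts = tuple(float(p) for p in points)
        if not pts:
            raise ValueError("explicit grid must contain at least one point")
        return cls(points=pts, dialect="explicit", domain=(0.0, 360.0))

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_dict(self) -> dict:
        return {
            "dialect": self.dialect,
            "points": list(self.points),
            "domain": list(self.domain),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TorsionGrid":
        dialect = d.get("dialect", "explicit")
        if "points" in d:
            pts = tuple(float(p) for p in d["points"])
            domain = tuple(float(x) for x in d.get("domain", (0.0, 360.0)))
            return cls(points=pts, dialect=str(dialect), domain=domain)
        if dialect == "bounded":
            return cls.bounded(float(d["lower"]), float(d["increment"]), float(d["upper"]))
        if dialect == "wraparound":
            return cls.wraparound(float(d["increment"]), float(d.get("offset", 0.0)))
        raise ValueError(f"cannot parse grid specification {d!r}")


def build_uniform_grid(
    grids: Sequence[TorsionGrid],
) -> np.ndarray:
    """Cartesian product of per-torsion point lists, lexicographic order.

    Returns an array of shape ``(n_points, d)`` in the grids' native
    degrees.
    """
    if not grids:
        raise ValueError("at least one per-torsion grid is required")
    combos = itertools.product(*(g.points for g in grids))
    return np.array(list(combos), dtype=float)


def _grids_for_group(
    molecule: MoleculeSpec, grids: Mapping[str, TorsionGrid], group_id: int
) -> list[TorsionGrid]:
    out = []
    for i in molecule.group_indices(group_id):
        name = molecule.torsion_names[i]
        if name not in grids:
            raise ValueError(f"no grid specified for torsion {name!r}")
        out.append(grids[name])
    return out


def build_group_database(
    model: ConformationalModel,
    molecule: MoleculeSpec,
    group_id: int,
    grids: Sequence[TorsionGrid],
    vacuo: VacuoRecord,
    ledger: CallLedger | None = None,
) -> GroupDatabase:
    """Fit one LAM per grid point of a torsional group."""
    points = build_uniform_grid(grids)
    if points.size == 0:
        raise ValueError(f"group {group_id} grid is empty")
    gdb = GroupDatabase(
        group_id=group_id,
        member_indices=molecule.group_indices(group_id),
        provenance={
            "grids": [g.to_dict() for g in grids],
            "domains": [list(g.domain) for g in grids],
        },
    )
    for point in points:
        gdb.add_record(fit_reference(model, molecule, group_id, point, vacuo))
        if ledger is not None:
            ledger.add(f"fit:group{group_id}")
    return gdb


def build_partitioned_database(
    model: ConformationalModel,
    molecule: MoleculeSpec,
    grids: Mapping[str, TorsionGrid],
    starts: Sequence[np.ndarray] | None = None,
    seed: int = 0,
) -> PartitionedDatabase:
    """In vacuo minimization followed by per-group uniform-grid builds.

    The ledger totals ``sum_g N_g,ref + 1``: one entry per reference fit
    plus one for the in vacuo minimization.
    """
    ledger = CallLedger()
    if starts is None:
        starts = default_starts(molecule, seed=seed)
    vacuo = minimize_vacuo(model, starts)
    ledger.add("vacuo")
    group_dbs = [
        build_group_database(
            model, molecule, gid, _grids_for_group(molecule, grids, gid), vacuo, ledger
        )
        for gid in range(molecule.n_groups)
    ]
    return PartitionedDatabase(
        molecule=molecule,
        vacuo=vacuo,
        group_dbs=group_dbs,
        ledger=ledger,
        provenance={"scheme": "partitioned", "seed": int(seed)},
    )


def build_full_database(
    model: ConformationalModel,
    molecule: MoleculeSpec,
    grids: Mapping[str, TorsionGrid],
    starts: Sequence[np.ndarray] | None = None,
    seed: int = 0,
) -> PartitionedDatabase:
    """Non-partitioned database: all torsions as one group.

    The reference grid is the Cartesian product across every torsion, so
    the ledger totals ``prod_t N_t + 1``.
    """
    merged = molecule.as_single_group()
    db = build_partitioned_database(model, merged, grids, starts=starts, seed=seed)
    db.provenance["scheme"] = "full"
    return db


@dataclass(frozen=True)
class LedgerProjection:
    """Pure-combinatorics projection of oracle-call counts (no oracle runs).

    ``full_equivalent`` is the size a non-partitioned database of matching
    per-group resolution would need: the product of the per-group record
    counts.
    """

    group_sizes: tuple
    partitioned_total: int  # sum + 1 (in vacuo)
    full_total: int  # product + 1 (in vacuo)
    full_equivalent: int  # product of per-group record counts

    @property
    def reduction_percent(self) -> float:
        return percent_reduction(self.full_total, self.partitioned_total)

    def to_dict(self) -> dict:
        return {
            "group_sizes": list(self.group_sizes),
            "partitioned_total": self.partitioned_total,
            "full_total": self.full_total,
            "full_equivalent": self.full_equivalent,
            "reduction_percent": self.reduction_percent,
        }


def grid_group_sizes(
    molecule: MoleculeSpec, grids: Mapping[str, TorsionGrid]
) -> list[int]:
    """Number of grid reference points per torsional group."""
    return [
        int(np.prod([g.n_points for g in _grids_for_group(molecule, grids, gid)]))
        for gid in range(molecule.n_groups)
    ]


def projected_call_counts(
    molecule: MoleculeSpec | None = None,
    grids: Mapping[str, TorsionGrid] | None = None,
    *,
    group_sizes: Sequence[int] | None = None,
) -> LedgerProjection:
    """Project oracle-call totals for partitioned and full schemes.

    Either pass a molecule plus per-torsion grids, or per-group record
    counts directly (e.g. the sizes reached by adaptive refinement).  With
    explicit ``group_sizes`` the full scheme is reported as the
    full-equivalent product, since no per-torsion factorization exists.
    """
    if group_sizes is None:
        if molecule is None or grids is None:
            raise ValueError("provide molecule+grids or group_sizes")
        group_sizes = grid_group_sizes(molecule, grids)
        per_torsion = [
            grids[name].n_points for name in molecule.torsion_names
        ]
        full_refs = int(np.prod(per_torsion))
    else:
        group_sizes = [int(n) for n in group_sizes]
        full_refs = int(math.prod(group_sizes))
    if any(n <= 0 for n in group_sizes):
        raise ValueError("group sizes must be positive")
    return LedgerProjection(
        group_sizes=tuple(group_sizes),
        partitioned_total=int(sum(group_sizes)) + 1,
        full_total=full_refs + 1,
        full_equivalent=int(math.prod(group_sizes)),
    )


def percent_reduction(n_full: int, n_partitioned: int) -> float:
    """Relative saving ``100 (n_full - n_partitioned) / n_full`` in percent."""
    if n_full <= 0:
        raise ValueError("n_full must be positive")
    return 100.0 * (n_full - n_partitioned) / n_full


def adaptive_refine(
    model: ConformationalModel,
    db: PartitionedDatabase,
    group_id: int,
    delta_star: float = 5.0,
    delta_star_star: float = 20.0,
    candidate_budget: int = 512,
    sweep_size: int = 64,
    seed: int = 0,
) -> PartitionedDatabase:
    """Adaptive LAM generation for one group, run to convergence.

    Starting from the group's existing (uniform-grid) references, seeded
    quasi-random candidate conformations are drawn within the group's
    domain, with all other groups held at their in vacuo torsions.
    Candidates whose oracle energy rise exceeds the crystallographic
    relevance cutoff ``delta_star_star`` (kJ/mol) are skipped; wherever the
    surrogate misses the oracle by more than the tolerance ``delta_star``
    (kJ/mol), the already-computed oracle solution is adopted as a new
    reference.  Convergence is a full candidate sweep that adds no point;
    if ``candidate_budget`` is exhausted first the returned group database
    is flagged non-converged.  Deterministic for a given seed.
    """
    from scipy.stats import qmc

    if delta_star <= 0 or delta_star_star <= 0:
        raise ValueError("refinement thresholds must be positive")
    molecule = db.molecule
    old_gdb = db.group_db(group_id)
    if not old_gdb.records:
        raise ValueError("adaptive refinement requires an initial grid")

    gdb = GroupDatabase(
        group_id=group_id,
        member_indices=np.array(old_gdb.member_indices),
        records=list(old_gdb.records),
        provenance=dict(old_gdb.provenance),
    )
    domains = gdb.provenance.get(
        "domains", [[0.0, 360.0]] * gdb.dim
    )
    lower = np.array([d[0] for d in domains])
    upper = np.array([d[1] for d in domains])

    ledger = db.ledger.copy()
    idx = molecule.group_indices(group_id)
    sampler = qmc.Sobol(d=gdb.dim, scramble=True, seed=seed)
    history = []
    converged = False
    used = 0
    while used < candidate_budget and not converged:
        m = min(sweep_size, candidate_budget - used)
        candidates = lower + (upper - lower) * sampler.random(m)
        used += m
        added = 0
        relevant = 0
        for cand in candidates:
            theta = np.array(db.vacuo.theta_vac, dtype=float)
            theta[idx] = cand
            record = minimize_at(model, theta)
            ledger.add(f"adaptive:group{group_id}")
            du_oracle = record.energy - db.vacuo.U_vac
            if du_oracle > delta_star_star:
                continue
            relevant += 1
            ref = gdb.records[nearest_reference(gdb, cand)]
            du_lam, _, _ = evaluate_group(ref, cand, db.vacuo)
            if abs(du_lam - du_oracle) > delta_star:
                gdb.add_record(reference_from_record(molecule, group_id, record))
                added += 1
        history.append(
            {"candidates": int(m), "relevant": int(relevant), "added": int(added)}
        )
        converged = added == 0
    gdb.provenance["adaptive"] = {
        "delta_star": float(delta_star),
        "delta_star_star": float(delta_star_star),
        "seed": int(seed),
        "candidates_used": int(used),
        "converged": bool(converged),
        "history": history,
    }

    group_dbs = [gdb if g.group_id == group_id else g for g in db.group_dbs]
    return PartitionedDatabase(
        molecule=molecule,
        vacuo=db.vacuo,
        group_dbs=group_dbs,
        ledger=ledger,
        provenance=dict(db.provenance),
    )


def validation_max_error(
    model: ConformationalModel,
    db: PartitionedDatabase,
    group_id: int,
    step: float = 1.0,
    relevance_cutoff: float | None = None,
) -> float:
    """Max |LAM - oracle| energy error over a dense scan of one group.

    Scans the group's domain on a uniform grid of the given step (degrees)
    with other groups at vacuo; points whose oracle energy rise exceeds
    ``relevance_cutoff`` (if given) are excluded, mirroring the
    crystallographic-relevance filter.  Intended for 1D/2D groups.
    """
    molecule = db.molecule
    gdb = db.group_db(group_id)
    domains = gdb.provenance.get("domains", [[0.0, 360.0]] * gdb.dim)
    axes = [
        np.arange(lo, hi + 1e-9, step) for lo, hi in domains
    ]
    idx = molecule.group_indices(group_id)
    worst = 0.0
    for point in itertools.product(*axes):
        theta = np.array(db.vacuo.theta_vac, dtype=float)
        theta[idx] = point
        record = minimize_at(model, theta)
        du_oracle = record.energy - db.vacuo.U_vac
        if relevance_cutoff is not None and du_oracle > relevance_cutoff:
            continue
        cand = np.asarray(point, dtype=float)
        ref = gdb.records[nearest_reference(gdb, cand)]
        du_lam, _, _ = evaluate_group(ref, cand, db.vacuo)
        worst = max(worst, abs(du_lam - du_oracle))
    return worst
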