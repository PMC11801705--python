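"""Lossless single-file serialization of LAM databases (HDF5).

Layout::

    /                     attrs: format_version, molecule (JSON),
                                 ledger (JSON), provenance (JSON)
    /vacuo                datasets theta, beta, q; attr U_vac
    /groups/<k>           attrs group_id, provenance (JSON);
                          datasets member_indices, theta_ref, U_ref,
                          beta_ref, q_ref, b, H, K, A  (records stacked
                          along axis 0)

All arrays are stored as float64, so a write/read round trip reproduces
every numeric field bit-exactly.
"""

from __future__ import annotations

import json
import warnings

import h5py
import numpy as np

from .lam import GroupDatabase, PartitionedDatabase, ReferenceRecord
from .ledger import CallLedger
from .molecule import MoleculeSpec
from .oracle import VacuoRecord

__all__ = [
    "FORMAT_VERSION",
    "ArchiveError",
    "VersionError",
    "SchemaError",
    "save_database",
    "load_database",
]

FORMAT_VERSION = "1"


class ArchiveError(RuntimeError):
    """Corrupted or unreadable database archive."""


class VersionError(ArchiveError):
    """Archive written by an incompatible format version."""


class SchemaError(ArchiveError):
    """Archive inconsistent with the expected molecule specification."""


def save_database(db: PartitionedDatabase, path) -> None:
    """Write a database archive; overwrites any existing file."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["molecule"] = json.dumps(db.molecule.to_dict())
        f.attrs["ledger"] = json.dumps(db.ledger.to_dict())
        f.attrs["provenance"] = json.dumps(db.provenance)

        vac = f.create_group("vacuo")
        vac.create_dataset("theta", data=np.asarray(db.vacuo.theta_vac, float))
        vac.create_dataset("beta", data=np.asarray(db.vacuo.beta_vac, float))
        vac.create_dataset("q", data=np.asarray(db.vacuo.q_vac, float))
        vac.attrs["U_vac"] = float(db.vacuo.U_vac)

        groups = f.create_group("groups")
        for k, gdb in enumerate(db.group_dbs):
            g = groups.create_group(str(k))
            g.attrs["group_id"] = int(gdb.group_id)
            g.attrs["provenance"] = json.dumps(gdb.provenance)
            g.create_dataset("member_indices", data=np.asarray(gdb.member_indices, int))
            g.create_dataset("theta_ref", data=np.array([r.theta_ref for r in gdb.records]))
            g.create_dataset("U_ref", data=np.array([r.U_ref for r in gdb.records]))
            g.create_dataset("beta_ref", data=np.array([r.beta_ref for r in gdb.records]))
            g.create_dataset("q_ref", data=np.array([r.q_ref for r in gdb.records]))
            g.create_dataset("b", data=np.array([r.b for r in gdb.records]))
            g.create_dataset("H", data=np.array([r.H for r in gdb.records]))
            g.create_dataset("K", data=np.array([r.K for r in gdb.records]))
            g.create_dataset("A", data=np.array([r.A for r in gdb.records]))


def load_database(
    path, molecule: MoleculeSpec | None = None
) -> PartitionedDatabase:
    """Read a database archive, validating version and schema.

    If ``molecule`` is given, the archived specification must match it
    exactly; otherwise the archived one is used.  Databases whose
    references undercut the stored in vacuo energy are flagged stale with
    a warning (they predate a needed vacuo rebase).
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ArchiveError(f"cannot open archive {path}: {exc}") from exc
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise VersionError(
                f"archive format version {version!r} is not supported "
                f"(expected {FORMAT_VERSION!r})"
            )
        try:
            archived = MoleculeSpec.from_dict(json.loads(f.attrs["molecule"]))
            ledger = CallLedger.from_dict(json.loads(f.attrs["ledger"]))
            provenance = json.loads(f.attrs["provenance"])
        except (KeyError, ValueError) as exc:
            raise ArchiveError(f"corrupted archive metadata: {exc}") from exc
        if molecule is not None and archived != molecule:
            raise SchemaError(
                "archived molecule specification does not match the expected one"
            )
        molecule = archived

        vac = f["vacuo"]
        vacuo = VacuoRecord(
            theta_vac=vac["theta"][()],
            beta_vac=vac["beta"][()],
            q_vac=vac["q"][()],
            U_vac=float(vac.attrs["U_vac"]),
        )

        group_dbs = []
        for k in sorted(f["groups"], key=int):
            g = f["groups"][k]
            gdb = GroupDatabase(
                group_id=int(g.attrs["group_id"]),
                member_indices=g["member_indices"][()],
                provenance=json.loads(g.attrs["provenance"]),
            )
            n = g["U_ref"].shape[0]
            for i in range(n):
                gdb.records.append(
                    ReferenceRecord(
                        group_id=gdb.group_id,
                        theta_ref=g["theta_ref"][i],
                        U_ref=float(g["U_ref"][i]),
                        beta_ref=g["beta_ref"][i],
                        q_ref=g["q_ref"][i],
                        b=g["b"][i],
                        H=g["H"][i],
                        K=g["K"][i],
                        A=g["A"][i],
                    )
                )
            group_dbs.append(gdb)

    db = PartitionedDatabase(
        molecule=molecule,
        vacuo=vacuo,
        group_dbs=group_dbs,
        ledger=ledger,
        provenance=provenance,
    )
    if db.is_stale():
        warnings.warn(
            "loaded database contains references below the stored in vacuo "
            "energy; a vacuo rebase is pending",
            stacklevel=2,
        )
        db.provenance["stale"] = True
    return db
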