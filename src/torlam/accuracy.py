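"""Accuracy-assessment protocol for LAM databases.

Mirrors the standard validation procedure for conformational surrogates:
draw conformations uniformly over torsion space, discard those outside the
region of crystallographic relevance (energy rise above a cutoff, 20 kJ/mol
by default), and compare the surrogate against the oracle on the retained
set, reporting average absolute deviations (AAD) per property category,
the maximum energy error and the parity R^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lam import PartitionedDatabase, evaluate, wrap_deviation
from .molecule import MoleculeSpec
from .oracle import ConformationalModel, ConstrainedMinimumRecord, minimize_at

__all__ = [
    "AccuracyReport",
    "sample_uniform",
    "filter_relevant",
    "compare",
    "assess",
    "parity_frame",
]


@dataclass
class AccuracyReport:
    """Per-category error statistics of a LAM database against its oracle."""

    n_sampled: int
    n_retained: int
    cutoff: float  # kJ/mol relevance cutoff
    seed: int | None
    aad_energy: float  # kJ/mol
    aad_bond_length: float  # Angstrom (NaN if schema has none)
    aad_bond_angle: float  # degrees
    aad_torsion: float  # degrees, dependent (non-flexible) torsions
    aad_charge: float  # e
    max_abs_energy_error: float  # kJ/mol
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "n_sampled": self.n_sampled,
            "n_retained": self.n_retained,
            "cutoff_kj_mol": self.cutoff,
            "seed": self.seed,
            "aad_energy_kj_mol": self.aad_energy,
            "aad_bond_length_angstrom": self.aad_bond_length,
            "aad_bond_angle_deg": self.aad_bond_angle,
            "aad_torsion_deg": self.aad_torsion,
            "aad_charge_e": self.aad_charge,
            "max_abs_energy_error_kj_mol": self.max_abs_energy_error,
            "r_squared": self.r_squared,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["statistic\tvalue"]
        for k, v in self.to_dict().items():
            lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"


def sample_uniform(molecule: MoleculeSpec, n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. uniform torsion vectors over [0, 360)^l (degrees)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 360.0, size=(n, molecule.n_torsions))


def filter_relevant(
    model: ConformationalModel,
    samples: np.ndarray,
    vacuo_energy: float,
    cutoff: float = 20.0,
) -> list[tuple[np.ndarray, ConstrainedMinimumRecord]]:
    """Keep samples whose oracle energy rise is within the relevance cutoff.

    Runs the oracle at every sample and caches the full record with each
    retained conformation so downstream comparison reuses it.
    """
    if cutoff <= 0:
        raise ValueError("relevance cutoff must be positive")
    retained = []
    for theta in np.asarray(samples, dtype=float):
        record = minimize_at(model, theta)
        if record.energy - vacuo_energy <= cutoff:
            retained.append((record.theta, record))
    return retained


def _category_errors(
    molecule: MoleculeSpec, beta_lam: np.ndarray, beta_oracle: np.ndarray
) -> dict:
    out = {}
    for category in ("bond_length", "bond_angle", "torsion"):
        mask = molecule.category_mask(category)
        if not mask.any():
            out[category] = np.empty(0)
            continue
        diff = beta_lam[mask] - beta_oracle[mask]
        if category == "torsion":
            diff = wrap_deviation(beta_lam[mask], beta_oracle[mask])
        out[category] = np.abs(diff)
    return out


def compare(
    db: PartitionedDatabase,
    model: ConformationalModel,
    retained: Sequence[tuple[np.ndarray, ConstrainedMinimumRecord]],
    *,
    n_sampled: int | None = None,
    cutoff: float = 20.0,
    seed: int | None = None,
) -> AccuracyReport:
    """Aggregate LAM-vs-oracle errors over the retained conformations.

    Energy errors compare the surrogate's energy rise with the oracle's;
    dependent-DoF errors are split by schema category, with angular
    categories wrapped; the parity R^2 is the squared Pearson correlation
    of surrogate vs oracle energy rises.
    """
    if not retained:
        raise ValueError("retained sample set is empty")
    du_lam, du_oracle = [], []
    errs = {"bond_length": [], "bond_angle": [], "torsion": [], "charge": []}
    for theta, record in retained:
        result = evaluate(db, theta)
        du_lam.append(result.delta_U)
        du_oracle.append(record.energy - db.vacuo.U_vac)
        cat = _category_errors(db.molecule, result.beta, record.beta)
        for k in ("bond_length", "bond_angle", "torsion"):
            errs[k].append(cat[k])
        errs["charge"].append(np.abs(result.charges - record.charges))
    du_lam = np.array(du_lam)
    du_oracle = np.array(du_oracle)
    energy_err = np.abs(du_lam - du_oracle)

    def aad(values: list) -> float:
        flat = np.concatenate(values) if values else np.empty(0)
        return float(flat.mean()) if flat.size else float("nan")

    return AccuracyReport(
        n_sampled=int(n_sampled if n_sampled is not None else len(retained)),
        n_retained=len(retained),
        cutoff=float(cutoff),
        seed=seed,
        aad_energy=float(energy_err.mean()),
        aad_bond_length=aad(errs["bond_length"]),
        aad_bond_angle=aad(errs["bond_angle"]),
        aad_torsion=aad(errs["torsion"]),
        aad_charge=aad(errs["charge"]),
        max_abs_energy_error=float(energy_err.max()),
        r_squared=_parity_r_squared(du_oracle, du_lam),
    )


def _parity_r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; degenerate scatters score 1 iff exact."""
    if x.size < 2 or np.allclose(x, y, atol=1e-12):
        return 1.0
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def assess(
    db: PartitionedDatabase,
    model: ConformationalModel,
    n: int = 2000,
    cutoff: float = 20.0,
    seed: int = 0,
) -> AccuracyReport:
    """Full protocol: sample, filter by relevance, compare."""
    samples = sample_uniform(db.molecule, n, seed)
    retained = filter_relevant(model, samples, db.vacuo.U_vac, cutoff)
    if not retained:
        raise ValueError(
            f"no sample fell within the {cutoff} kJ/mol relevance cutoff; "
            "increase n or the cutoff"
        )
    return compare(db, model, retained, n_sampled=n, cutoff=cutoff, seed=seed)


def parity_frame(
    db: PartitionedDatabase,
    retained: Sequence[tuple[np.ndarray, ConstrainedMinimumRecord]],
) -> pd.DataFrame:
    """Parity-scatter data: oracle vs surrogate energy rise per sample."""
    rows = []
    for theta, record in retained:
        result = evaluate(db, theta)
        rows.append(
            {
                "delta_U_oracle": record.energy - db.vacuo.U_vac,
                "delta_U_lam": result.delta_U,
            }
        )
    return pd.DataFrame(rows)
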