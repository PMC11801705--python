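"""Conformational-model oracle contract.

A :class:`ConformationalModel` answers one question: given fixed values of
the flexible torsions, what are the constrained-minimum energy, the relaxed
dependent degrees of freedom, the atomic point charges, and all of their
derivatives with respect to the torsions?  In production this role is
played by an isolated-molecule quantum-chemistry minimization; here any
object satisfying the contract can be used, including the built-in
closed-form synthetic model and a finite-difference wrapper around an
arbitrary energy function.

Derivatives are those of the *reduced* energy, i.e. the energy already
minimized over the dependent degrees of freedom, so implicit-function
corrections are the oracle's responsibility.  All angles are degrees;
energies kJ/mol; derivative blocks are per degree.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .molecule import MoleculeSpec, wrap_angle

__all__ = [
    "ConstrainedMinimumRecord",
    "VacuoRecord",
    "ConformationalModel",
    "FiniteDifferenceModel",
    "OracleError",
    "minimize_at",
    "minimize_vacuo",
    "default_starts",
]


class OracleError(RuntimeError):
    """Raised when a conformational oracle fails or returns invalid data."""


@dataclass
class ConstrainedMinimumRecord:
    """Solution of one constrained minimization at fixed torsions.

    Attributes
    ----------
    theta
        Torsion values (degrees, wrapped to [0, 360)), shape ``(l,)``.
    energy
        Constrained-minimum energy, kJ/mol.
    beta
        Relaxed dependent-DoF values per the molecule schema, shape ``(M,)``.
    charges
        Atomic point charges (e), shape ``(A,)``.
    grad_energy
        d(energy)/d(theta), kJ/mol/deg, shape ``(l,)``.
    hess_energy
        Second-derivative matrix, kJ/mol/deg^2, shape ``(l, l)``, symmetric.
    jac_beta
        d(beta)/d(theta), schema units per degree, shape ``(M, l)``.
    jac_charges
        d(charges)/d(theta), e/deg, shape ``(A, l)``.
    """

    theta: np.ndarray
    energy: float
    beta: np.ndarray
    charges: np.ndarray
    grad_energy: np.ndarray
    hess_energy: np.ndarray
    jac_beta: np.ndarray
    jac_charges: np.ndarray

    def validate(self, molecule: MoleculeSpec, hess_tol: float = 1e-8) -> None:
        l, m, a = molecule.n_torsions, molecule.n_dependent, molecule.n_charges
        shapes = {
            "theta": (self.theta, (l,)),
            "beta": (self.beta, (m,)),
            "charges": (self.charges, (a,)),
            "grad_energy": (self.grad_energy, (l,)),
            "hess_energy": (self.hess_energy, (l, l)),
            "jac_beta": (self.jac_beta, (m, l)),
            "jac_charges": (self.jac_charges, (a, l)),
        }
        for name, (arr, shape) in shapes.items():
            if np.asarray(arr).shape != shape:
                raise OracleError(
                    f"record field {name} has shape {np.asarray(arr).shape}, "
                    f"expected {shape}"
                )
        if not np.isfinite(self.energy):
            raise OracleError("oracle returned a non-finite energy")
        asym = np.max(np.abs(self.hess_energy - self.hess_energy.T), initial=0.0)
        scale = max(1.0, float(np.max(np.abs(self.hess_energy), initial=0.0)))
        if asym > hess_tol * scale:
            raise OracleError(f"energy Hessian asymmetric beyond tolerance ({asym:g})")


@dataclass
class VacuoRecord:
    """The unconstrained in vacuo minimum anchoring all energy differences."""

    theta_vac: np.ndarray
    beta_vac: np.ndarray
    q_vac: np.ndarray
    U_vac: float

    def to_arrays(self) -> dict:
        return {
            "theta_vac": np.asarray(self.theta_vac, dtype=float),
            "beta_vac": np.asarray(self.beta_vac, dtype=float),
            "q_vac": np.asarray(self.q_vac, dtype=float),
            "U_vac": float(self.U_vac),
        }


class ConformationalModel(abc.ABC):
    """Oracle contract: constrained minimization at fixed torsions."""

    molecule: MoleculeSpec

    @abc.abstractmethod
    def minimize_at(self, theta: np.ndarray) -> ConstrainedMinimumRecord:
        """Return the constrained minimum and derivative blocks at ``theta``."""


def minimize_at(model: ConformationalModel, theta) -> ConstrainedMinimumRecord:
    """Constrained minimization at fixed torsions, with input validation.

    Wraps ``theta`` onto [0, 360), delegates to the model, and checks the
    returned record for shape consistency, Hessian symmetry and finiteness.
    """
    wrapped = model.molecule.validate_theta(theta)
    record = model.minimize_at(wrapped)
    record.validate(model.molecule)
    return record


def default_starts(
    molecule: MoleculeSpec, n: int = 16, seed: int = 0
) -> list[np.ndarray]:
    """Seeded quasi-random multi-start points covering torsion space.

    A scrambled Sobol' sequence over [0, 360)^l, matching the quasi-random
    sampling style used in crystal-structure global searches.
    """
    from scipy.stats import qmc

    sampler = qmc.Sobol(d=molecule.n_torsions, scramble=True, seed=seed)
    return list(360.0 * sampler.random(n))


def minimize_vacuo(
    model: ConformationalModel, starts: Sequence[np.ndarray]
) -> VacuoRecord:
    """Locate the in vacuo minimum by multi-start local minimization.

    Each start runs a BFGS descent of the reduced energy over the torsions
    (dependent DoFs relax implicitly inside ``minimize_at``); the lowest
    minimum found wins.  Raises :class:`OracleError` if every start fails.
    """
    starts = list(starts)
    if not starts:
        raise ValueError("at least one start point is required")

    def fun(theta):
        rec = minimize_at(model, theta)
        return rec.energy, rec.grad_energy

    best = None
    for x0 in starts:
        x0 = model.molecule.validate_theta(x0)
        try:
            res = optimize.minimize(fun, x0, jac=True, method="BFGS")
        except OracleError:
            continue
        if not np.isfinite(res.fun):
            continue
        # BFGS may stop with a precision-loss warning at an already-good
        # point; accept any finite result with a small gradient.
        if res.success or np.linalg.norm(res.jac) < 1e-5:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise OracleError("in vacuo minimization failed from every start point")
    record = minimize_at(model, wrap_angle(best.x))
    return VacuoRecord(
        theta_vac=record.theta,
        beta_vac=record.beta,
        q_vac=record.charges,
        U_vac=record.energy,
    )


class FiniteDifferenceModel(ConformationalModel):
    """Adapter deriving all derivative blocks by central finite differences.

    For oracles that can return energy, dependent DoFs and charges at fixed
    torsions but no derivatives.  Differences are wrap-aware: displaced
    torsions are mapped back onto [0, 360) before evaluation, which is
    exact for periodic surfaces.

    Parameters
    ----------
    molecule
        Torsion-space schema.
    evaluate
        Callable ``theta -> (energy, beta, charges)``.
    step
        Central-difference step in degrees (default 1.0, small relative to
        the 60-120 degree reference-grid spacings in use).
    """

    def __init__(
        self,
        molecule: MoleculeSpec,
        evaluate: Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]],
        step: float = 1.0,
    ):
        if step <= 0:
            raise ValueError("finite-difference step must be positive")
        self.molecule = molecule
        self._evaluate = evaluate
        self.step = float(step)

    def _eval(self, theta):
        energy, beta, charges = self._evaluate(wrap_angle(theta))
        return (
            float(energy),
            np.asarray(beta, dtype=float),
            np.asarray(charges, dtype=float),
        )

    def minimize_at(self, theta: np.ndarray) -> ConstrainedMinimumRecord:
        theta = wrap_angle(np.asarray(theta, dtype=float))
        l = self.molecule.n_torsions
        h = self.step
        e0, beta0, q0 = self._eval(theta)

        grad = np.zeros(l)
        hess = np.zeros((l, l))
        jac_beta = np.zeros((self.molecule.n_dependent, l))
        jac_q = np.zeros((self.molecule.n_charges, l))

        plus, minus = [], []
        for i in range(l):
            ei = np.zeros(l)
            ei[i] = h
            ep, bp, qp = self._eval(theta + ei)
            em, bm, qm = self._eval(theta - ei)
            plus.append(ep)
            minus.append(em)
            grad[i] = (ep - em) / (2 * h)
            hess[i, i] = (ep + em - 2 * e0) / h**2
            jac_beta[:, i] = (bp - bm) / (2 * h)
            jac_q[:, i] = (qp - qm) / (2 * h)

        for i in range(l):
            for j in range(i + 1, l):
                eij = np.zeros(l)
                eij[i] = h
                eij[j] = h
                epp, _, _ = self._eval(theta + eij)
                eij[j] = -h
                epm, _, _ = self._eval(theta + eij)
                eij[i] = -h
                emm, _, _ = self._eval(theta + eij)
                eij[j] = h
                emp, _, _ = self._eval(theta + eij)
                hess[i, j] = hess[j, i] = (epp - epm - emp + emm) / (4 * h**2)

        return ConstrainedMinimumRecord(
            theta=theta,
            energy=e0,
            beta=beta0,
            charges=q0,
            grad_energy=grad,
            hess_energy=hess,
            jac_beta=jac_beta,
            jac_charges=jac_q,
        )
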