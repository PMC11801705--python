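"""Closed-form synthetic conformational model.

Emulates the structure of an isolated-molecule quantum-chemistry oracle:
a smooth periodic torsional energy surface with optional cross-group
coupling, dependent degrees of freedom (bond lengths, bond angles,
non-flexible torsions) bound harmonically to torsion-dependent equilibria,
and atomic point charges varying smoothly with the torsions under a
total-charge-conservation constraint.

Because the dependent DoFs are harmonic about their equilibria, the
constrained minimization at fixed torsions has a closed-form solution: the
dependent DoFs sit exactly on their equilibrium map, the harmonic energy
vanishes, and the reduced energy and all derivative blocks are analytic.

Energy model (all angles in degrees):

    U(theta) = U0 + sum_t V_t(theta_t)
             + sum_(i,j) intra  a_ij cos(theta_i - theta_j + phi_ij)
             + eps * sum_(i,j) cross a_ij cos(theta_i - theta_j + phi_ij)

where each per-torsion potential V_t is a cosine series
A (1 + cos(m theta - phi)) and/or a wrapped quadratic bowl
(c/2) d(theta, theta0)^2.  Intra-group couplings join torsions of the same
torsional group; cross couplings join torsions of different groups and are
scaled by the dimensionless ``cross_coupling_epsilon``, so eps = 0 makes
the surface exactly additive over groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .molecule import MoleculeSpec, wrap_angle
from .oracle import ConformationalModel, ConstrainedMinimumRecord

__all__ = [
    "CosineTerm",
    "QuadraticBowl",
    "CouplingTerm",
    "SyntheticModelParams",
    "SyntheticConformationalModel",
    "make_synthetic_model",
]

_DEG = np.pi / 180.0


def _wrap_dev(theta, ref):
    d = np.mod(np.asarray(theta, dtype=float) - ref, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class CosineTerm:
    """Torsional cosine term ``A (1 + cos(m*theta - phase))`` (degrees)."""

    amplitude: float
    multiplicity: int
    phase: float = 0.0

    def __post_init__(self):
        if int(self.multiplicity) != self.multiplicity or self.multiplicity < 1:
            raise ValueError("cosine multiplicity must be a positive integer")

    def value(self, theta):
        x = _DEG * (self.multiplicity * theta - self.phase)
        return self.amplitude * (1.0 + np.cos(x))

    def d1(self, theta):
        x = _DEG * (self.multiplicity * theta - self.phase)
        return -self.amplitude * self.multiplicity * _DEG * np.sin(x)

    def d2(self, theta):
        x = _DEG * (self.multiplicity * theta - self.phase)
        return -self.amplitude * (self.multiplicity * _DEG) ** 2 * np.cos(x)


@dataclass(frozen=True)
class QuadraticBowl:
    """Quadratic well ``(c/2) (theta - center)^2`` in the canonical angle.

    Quadratic in the wrapped coordinate on [0, 360), so a second-order
    Taylor expansion reproduces it exactly wherever query and reference
    sit on the same side of the 0/360 seam; with full-circle reference
    grids the nearest reference always does.
    """

    center: float
    curvature: float  # kJ/mol/deg^2

    def __post_init__(self):
        if self.curvature < 0:
            raise ValueError("bowl curvature must be non-negative")

    def value(self, theta):
        d = np.asarray(theta, dtype=float) - self.center
        return 0.5 * self.curvature * d**2

    def d1(self, theta):
        return self.curvature * (np.asarray(theta, dtype=float) - self.center)

    def d2(self, theta):
        return self.curvature * np.ones_like(np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class CouplingTerm:
    """Pairwise torsion coupling ``a cos(theta_i - theta_j + phase)``."""

    i: int
    j: int
    amplitude: float
    phase: float = 0.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("coupling must join two distinct torsions")


_TERM_TAGS = {"cosine": CosineTerm, "bowl": QuadraticBowl}


def _term_to_dict(term) -> dict:
    for tag, cls in _TERM_TAGS.items():
        if isinstance(term, cls):
            return {"type": tag, **asdict(term)}
    raise TypeError(f"unknown torsion term {term!r}")


def _term_from_dict(d: Mapping):
    d = dict(d)
    cls = _TERM_TAGS[d.pop("type")]
    return cls(**d)


@dataclass
class SyntheticModelParams:
    """Full parameter set of the synthetic conformational model.

    Attributes
    ----------
    torsion_terms
        Per torsion, a tuple of :class:`CosineTerm` / :class:`QuadraticBowl`.
    intra_couplings, cross_couplings
        Pairwise couplings within a torsional group and across groups.
        Cross couplings are scaled by ``cross_coupling_epsilon``.
    base_energy
        Constant offset U0, kJ/mol (the model reports absolute energies).
    beta_base, beta_amp, beta_phase
        Dependent-DoF equilibrium map: ``beta_j(theta) = beta_base[j] +
        sum_t beta_amp[j,t] sin(theta_t - beta_phase[j,t])`` (degrees in,
        schema units out).
    charge_base, charge_amp, charge_phase
        Charge map ``q_a(theta) = charge_base[a] + sum_t charge_amp[a,t]
        sin(theta_t - charge_phase[t])``.  Each column of ``charge_amp``
        sums to zero and the phase is shared per torsion, so the total
        molecular charge is conserved exactly for all theta.
    map_kind
        ``"sinusoidal"`` (default) or ``"affine"``.  Affine maps drop the
        sine and use ``base + sum_t amp[:, t] * theta_t`` in the canonical
        angle coordinate; their Jacobians are constant, so the first-order
        LAM reconstruction of geometry and charges is exact.
    stiffness
        Harmonic constants binding each raw dependent DoF to its
        equilibrium (per schema-unit^2); they fix how sharply the geometry
        relaxes but do not enter the reduced energy, which is exactly zero
        strain at the constrained minimum.
    seed
        Seed used if the parameter set was generated randomly.
    """

    torsion_terms: tuple
    intra_couplings: tuple
    cross_couplings: tuple
    cross_coupling_epsilon: float
    base_energy: float
    beta_base: np.ndarray
    beta_amp: np.ndarray
    beta_phase: np.ndarray
    charge_base: np.ndarray
    charge_amp: np.ndarray
    charge_phase: np.ndarray
    stiffness: np.ndarray
    seed: int | None = None
    map_kind: str = "sinusoidal"

    def __post_init__(self):
        if self.map_kind not in ("sinusoidal", "affine"):
            raise ValueError("map_kind must be 'sinusoidal' or 'affine'")
        self.torsion_terms = tuple(tuple(ts) for ts in self.torsion_terms)
        self.intra_couplings = tuple(self.intra_couplings)
        self.cross_couplings = tuple(self.cross_couplings)
        for name in (
            "beta_base",
            "beta_amp",
            "beta_phase",
            "charge_base",
            "charge_amp",
            "charge_phase",
            "stiffness",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.stiffness <= 0):
            raise ValueError("stiffness constants must be positive")
        colsums = np.abs(self.charge_amp.sum(axis=0))
        if colsums.size and colsums.max() > 1e-9:
            raise ValueError(
                "charge_amp columns must sum to zero (total-charge conservation)"
            )

    def validate_for(self, molecule: MoleculeSpec) -> None:
        l, m, a = molecule.n_torsions, molecule.n_dependent, molecule.n_charges
        if len(self.torsion_terms) != l:
            raise ValueError("one torsion-term list required per torsion")
        if self.beta_base.shape != (m,) or self.beta_amp.shape != (m, l):
            raise ValueError("beta map shapes inconsistent with molecule schema")
        if self.beta_phase.shape != (m, l):
            raise ValueError("beta_phase shape inconsistent with molecule schema")
        if self.charge_base.shape != (a,) or self.charge_amp.shape != (a, l):
            raise ValueError("charge map shapes inconsistent with molecule schema")
        if self.charge_phase.shape != (l,):
            raise ValueError("charge_phase must have one entry per torsion")
        if self.stiffness.shape != (m,):
            raise ValueError("one stiffness constant required per dependent DoF")
        group_of = {}
        for gid, g in enumerate(molecule.groups):
            for i in g:
                group_of[i] = gid
        for c in self.intra_couplings:
            if group_of[c.i] != group_of[c.j]:
                raise ValueError(
                    f"intra coupling ({c.i},{c.j}) joins different groups"
                )
        for c in self.cross_couplings:
            if group_of[c.i] == group_of[c.j]:
                raise ValueError(
                    f"cross coupling ({c.i},{c.j}) joins the same group"
                )

    # -- randomized generation ---------------------------------------------

    @classmethod
    def randomized(
        cls,
        molecule: MoleculeSpec,
        seed: int,
        cross_coupling_epsilon: float = 0.0,
        amplitude_range: tuple[float, float] = (4.0, 12.0),
        intra_coupling_amplitude: float = 0.0,
        cross_coupling_amplitude: tuple[float, float] = (0.5, 2.0),
        quadratic: bool = False,
    ) -> "SyntheticModelParams":
        """Draw a deterministic random parameter set for a molecule.

        ``quadratic=True`` replaces the cosine torsional potentials with
        single quadratic bowls and switches the dependent-DoF and charge
        maps to affine form, so the LAM surrogate (second order in energy,
        first order in geometry and charges) is exact for the model.
        ``intra_coupling_amplitude > 0`` adds one coupling per adjacent
        torsion pair inside each multi-torsion group, emulating sterically
        interacting neighbours.
        """
        rng = np.random.default_rng(seed)
        l, m, a = molecule.n_torsions, molecule.n_dependent, molecule.n_charges

        terms = []
        for _ in range(l):
            if quadratic:
                terms.append(
                    (
                        QuadraticBowl(
                            center=float(rng.uniform(0, 360)),
                            curvature=float(rng.uniform(1e-3, 4e-3)),
                        ),
                    )
                )
            else:
                n_terms = int(rng.integers(1, 3))
                terms.append(
                    tuple(
                        CosineTerm(
                            amplitude=float(rng.uniform(*amplitude_range)),
                            multiplicity=int(rng.integers(1, 4)),
                            phase=float(rng.uniform(0, 360)),
                        )
                        for _ in range(n_terms)
                    )
                )

        intra = []
        if intra_coupling_amplitude > 0:
            for g in molecule.groups:
                for i, j in zip(g[:-1], g[1:]):
                    intra.append(
                        CouplingTerm(
                            i=int(i),
                            j=int(j),
                            amplitude=float(
                                intra_coupling_amplitude * rng.uniform(0.5, 1.5)
                            ),
                            phase=float(rng.uniform(0, 360)),
                        )
                    )

        cross = []
        for gi in range(molecule.n_groups):
            for gj in range(gi + 1, molecule.n_groups):
                i = int(rng.choice(molecule.groups[gi]))
                j = int(rng.choice(molecule.groups[gj]))
                cross.append(
                    CouplingTerm(
                        i=i,
                        j=j,
                        amplitude=float(rng.uniform(*cross_coupling_amplitude)),
                        phase=float(rng.uniform(0, 360)),
                    )
                )

        # Dependent-DoF equilibria: realistic base values and modulations
        # per category (lengths ~1.4 A +- 5 mA; angles ~110 deg +- 1.5 deg;
        # non-flexible torsions ~180 deg +- 6 deg).
        beta_base = np.empty(m)
        beta_amp = np.empty((m, l))
        stiffness = np.empty(m)
        for j, dof in enumerate(molecule.dependent_dofs):
            if dof.category == "bond_length":
                beta_base[j] = rng.uniform(1.3, 1.6)
                beta_amp[j] = rng.uniform(-0.005, 0.005, size=l)
                stiffness[j] = 3000.0
            elif dof.category == "bond_angle":
                beta_base[j] = rng.uniform(105.0, 125.0)
                beta_amp[j] = rng.uniform(-1.5, 1.5, size=l)
                stiffness[j] = 0.1
            else:
                beta_base[j] = rng.uniform(0.0, 360.0)
                beta_amp[j] = rng.uniform(-6.0, 6.0, size=l)
                stiffness[j] = 0.02
        beta_phase = rng.uniform(0, 360, size=(m, l))

        charge_base = rng.uniform(-0.5, 0.5, size=a)
        charge_base -= charge_base.mean()  # net-neutral molecule
        charge_amp = rng.uniform(-0.01, 0.01, size=(a, l))
        charge_amp -= charge_amp.mean(axis=0, keepdims=True)
        charge_phase = rng.uniform(0, 360, size=l)

        if quadratic:
            # affine maps: reinterpret amplitudes as per-degree slopes of
            # comparable overall swing (a sinusoid of amplitude A swings
            # about as much as a slope A/180 over the half-circle)
            beta_amp = beta_amp / 180.0
            charge_amp = charge_amp / 180.0

        return cls(
            torsion_terms=tuple(terms),
            intra_couplings=tuple(intra),
            cross_couplings=tuple(cross),
            cross_coupling_epsilon=float(cross_coupling_epsilon),
            base_energy=float(rng.uniform(-50.0, 50.0)),
            beta_base=beta_base,
            beta_amp=beta_amp,
            beta_phase=beta_phase,
            charge_base=charge_base,
            charge_amp=charge_amp,
            charge_phase=charge_phase,
            stiffness=stiffness,
            seed=int(seed),
            map_kind="affine" if quadratic else "sinusoidal",
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "synthetic",
            "torsion_terms": [
                [_term_to_dict(t) for t in ts] for ts in self.torsion_terms
            ],
            "intra_couplings": [asdict(c) for c in self.intra_couplings],
            "cross_couplings": [asdict(c) for c in self.cross_couplings],
            "cross_coupling_epsilon": float(self.cross_coupling_epsilon),
            "base_energy": float(self.base_energy),
            "beta_base": self.beta_base.tolist(),
            "beta_amp": self.beta_amp.tolist(),
            "beta_phase": self.beta_phase.tolist(),
            "charge_base": self.charge_base.tolist(),
            "charge_amp": self.charge_amp.tolist(),
            "charge_phase": self.charge_phase.tolist(),
            "stiffness": self.stiffness.tolist(),
            "seed": self.seed,
            "map_kind": self.map_kind,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticModelParams":
        return cls(
            torsion_terms=tuple(
                tuple(_term_from_dict(t) for t in ts) for ts in d["torsion_terms"]
            ),
            intra_couplings=tuple(
                CouplingTerm(**c) for c in d.get("intra_couplings", [])
            ),
            cross_couplings=tuple(
                CouplingTerm(**c) for c in d.get("cross_couplings", [])
            ),
            cross_coupling_epsilon=float(d["cross_coupling_epsilon"]),
            base_energy=float(d.get("base_energy", 0.0)),
            beta_base=d["beta_base"],
            beta_amp=d["beta_amp"],
            beta_phase=d["beta_phase"],
            charge_base=d["charge_base"],
            charge_amp=d["charge_amp"],
            charge_phase=d["charge_phase"],
            stiffness=d["stiffness"],
            seed=d.get("seed"),
            map_kind=d.get("map_kind", "sinusoidal"),
        )


class SyntheticConformationalModel(ConformationalModel):
    """Oracle with closed-form constrained minima and analytic derivatives."""

    def __init__(self, molecule: MoleculeSpec, params: SyntheticModelParams):
        params.validate_for(molecule)
        self.molecule = molecule
        self.params = params

    # -- reduced energy -----------------------------------------------------

    def reduced_energy(self, theta) -> float:
        theta = wrap_angle(theta)
        p = self.params
        u = p.base_energy
        for t, terms in enumerate(p.torsion_terms):
            for term in terms:
                u += float(term.value(theta[t]))
        for c, scale in self._couplings():
            u += scale * c.amplitude * np.cos(_DEG * (theta[c.i] - theta[c.j] + c.phase))
        return float(u)

    def reduced_gradient(self, theta) -> np.ndarray:
        theta = wrap_angle(theta)
        p = self.params
        g = np.zeros(self.molecule.n_torsions)
        for t, terms in enumerate(p.torsion_terms):
            for term in terms:
                g[t] += float(term.d1(theta[t]))
        for c, scale in self._couplings():
            s = scale * c.amplitude * _DEG * np.sin(
                _DEG * (theta[c.i] - theta[c.j] + c.phase)
            )
            g[c.i] -= s
            g[c.j] += s
        return g

    def reduced_hessian(self, theta) -> np.ndarray:
        theta = wrap_angle(theta)
        p = self.params
        l = self.molecule.n_torsions
        h = np.zeros((l, l))
        for t, terms in enumerate(p.torsion_terms):
            for term in terms:
                h[t, t] += float(term.d2(theta[t]))
        for c, scale in self._couplings():
            cc = scale * c.amplitude * _DEG**2 * np.cos(
                _DEG * (theta[c.i] - theta[c.j] + c.phase)
            )
            h[c.i, c.i] -= cc
            h[c.j, c.j] -= cc
            h[c.i, c.j] += cc
            h[c.j, c.i] += cc
        return h

    def _couplings(self):
        p = self.params
        for c in p.intra_couplings:
            yield c, 1.0
        for c in p.cross_couplings:
            yield c, p.cross_coupling_epsilon

    # -- dependent DoFs and charges ----------------------------------------

    def beta_equilibrium(self, theta) -> np.ndarray:
        theta = wrap_angle(theta)
        p = self.params
        if p.map_kind == "affine":
            return p.beta_base + p.beta_amp @ theta
        x = _DEG * (theta[None, :] - p.beta_phase)
        return p.beta_base + (p.beta_amp * np.sin(x)).sum(axis=1)

    def beta_jacobian(self, theta) -> np.ndarray:
        theta = wrap_angle(theta)
        p = self.params
        if p.map_kind == "affine":
            return np.array(p.beta_amp)
        x = _DEG * (theta[None, :] - p.beta_phase)
        return p.beta_amp * _DEG * np.cos(x)

    def charges_at(self, theta) -> np.ndarray:
        theta = wrap_angle(theta)
        p = self.params
        if p.map_kind == "affine":
            return p.charge_base + p.charge_amp @ theta
        x = _DEG * (theta[None, :] - p.charge_phase[None, :])
        return p.charge_base + (p.charge_amp * np.sin(x)).sum(axis=1)

    def charges_jacobian(self, theta) -> np.ndarray:
        theta = wrap_angle(theta)
        p = self.params
        if p.map_kind == "affine":
            return np.array(p.charge_amp)
        x = _DEG * (theta[None, :] - p.charge_phase[None, :])
        return p.charge_amp * _DEG * np.cos(x)

    # -- oracle contract ----------------------------------------------------

    def minimize_at(self, theta: np.ndarray) -> ConstrainedMinimumRecord:
        theta = wrap_angle(np.asarray(theta, dtype=float))
        return ConstrainedMinimumRecord(
            theta=theta,
            energy=self.reduced_energy(theta),
            beta=self.beta_equilibrium(theta),
            charges=self.charges_at(theta),
            grad_energy=self.reduced_gradient(theta),
            hess_energy=self.reduced_hessian(theta),
            jac_beta=self.beta_jacobian(theta),
            jac_charges=self.charges_jacobian(theta),
        )


def make_synthetic_model(
    molecule: MoleculeSpec, params: SyntheticModelParams
) -> SyntheticConformationalModel:
    """Build the synthetic oracle; deterministic for a given parameter set."""
    return SyntheticConformationalModel(molecule, params)
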