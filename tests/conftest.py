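import numpy as np
import pytest

from torlam import (
    MoleculeSpec,
    DependentDof,
    TorsionGrid,
    build_partitioned_database,
    make_fixture,
    make_synthetic_model,
)
from torlam.synthetic import CosineTerm, SyntheticModelParams


@pytest.fixture(scope="session")
def one_torsion_molecule():
    return MoleculeSpec(
        torsion_names=("t1",),
        groups=((0,),),
        dependent_dofs=(DependentDof("r1", "bond_length", "angstrom"),),
        charge_labels=("q1", "q2"),
    )


def cosine_params(molecule, terms_per_torsion, **overrides):
    """Hand-built synthetic parameters with trivial beta/charge maps."""
    m, l, a = molecule.n_dependent, molecule.n_torsions, molecule.n_charges
    defaults = dict(
        torsion_terms=tuple(tuple(ts) for ts in terms_per_torsion),
        intra_couplings=(),
        cross_couplings=(),
        cross_coupling_epsilon=0.0,
        base_energy=0.0,
        beta_base=np.full(m, 1.4),
        beta_amp=np.full((m, l), 0.003),
        beta_phase=np.zeros((m, l)),
        charge_base=np.linspace(-0.2, 0.2, a),
        charge_amp=np.tile(np.linspace(-0.004, 0.004, a)[:, None], (1, l)),
        charge_phase=np.zeros(l),
        stiffness=np.full(m, 100.0),
    )
    defaults.update(overrides)
    params = SyntheticModelParams(**defaults)
    params.charge_amp = params.charge_amp - params.charge_amp.mean(
        axis=0, keepdims=True
    )
    return params


@pytest.fixture(scope="session")
def two_well_model(one_torsion_molecule):
    """1D surface with wells near 90 (higher) and 270 (lower) degrees."""
    params = cosine_params(
        one_torsion_molecule,
        [(CosineTerm(8.0, 2, 0.0), CosineTerm(2.0, 1, 90.0))],
    )
    return make_synthetic_model(one_torsion_molecule, params)


@pytest.fixture(scope="session")
def fig1_db():
    """Two one-torsion groups, 60-degree wraparound grids (6 refs each)."""
    molecule, params, grids = make_fixture("two-torsion")
    model = make_synthetic_model(molecule, params)
    db = build_partitioned_database(model, molecule, grids, seed=1)
    return model, db


@pytest.fixture(scope="session")
def quad_affine_db():
    """Uncoupled quadratic/affine model for which the LAM is exact."""
    molecule, _, grids = make_fixture("two-torsion")
    params = SyntheticModelParams.randomized(
        molecule, seed=5, cross_coupling_epsilon=0.0, quadratic=True
    )
    model = make_synthetic_model(molecule, params)
    db = build_partitioned_database(model, molecule, grids, seed=1)
    return model, db
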