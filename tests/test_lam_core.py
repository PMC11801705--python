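"""LAM fitting, nearest-reference lookup, additivity evaluation, rebase."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torlam import (
    GroupDatabase,
    ReferenceRecord,
    TorsionGrid,
    build_partitioned_database,
    build_full_database,
    evaluate,
    evaluate_group,
    fit_reference,
    make_fixture,
    make_synthetic_model,
    minimize_at,
    nearest_reference,
    rebase_vacuo,
    wrap_deviation,
)
from torlam.oracle import minimize_vacuo
from torlam.synthetic import CosineTerm, QuadraticBowl, SyntheticModelParams

from conftest import cosine_params


@pytest.mark.parametrize(
    "theta,ref,expected",
    [
        (104.0, 90.0, 14.0),
        (350.0, 10.0, -20.0),
        (42.0, 42.0, 0.0),
        (0.0, 180.0, 180.0),  # antipode maps to +180, not -180
        (270.0, 90.0, 180.0),
    ],
)
def test_wrap_deviation_examples(theta, ref, expected):
    assert wrap_deviation(theta, ref) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    theta=st.floats(-1000, 1000),
    ref=st.floats(-1000, 1000),
    turns=st.integers(-3, 3),
)
def test_wrap_deviation_is_congruent_and_bounded(theta, ref, turns):
    d = float(wrap_deviation(theta, ref))
    assert -180.0 < d <= 180.0
    assert abs((theta - ref - d) % 360.0) % 360.0 == pytest.approx(0.0, abs=1e-6)
    # adding full turns to either argument changes nothing
    assert float(wrap_deviation(theta + 360 * turns, ref)) == pytest.approx(
        d, abs=1e-6
    )


def _lookup_db():
    gdb = GroupDatabase(group_id=0, member_indices=np.array([0]))
    for k, p in enumerate([30.0, 90.0, 150.0, 210.0, 270.0, 330.0]):
        gdb.records.append(
            ReferenceRecord(
                group_id=0,
                theta_ref=[p],
                U_ref=float(k),
                beta_ref=np.zeros(1),
                q_ref=np.zeros(1),
                b=np.zeros(1),
                H=np.zeros((1, 1)),
                K=np.zeros((1, 1)),
                A=np.zeros((1, 1)),
            )
        )
    return gdb


@pytest.mark.parametrize(
    "query,expected_angle",
    [(104.0, 90.0), (235.0, 210.0), (359.0, 330.0)],
)
def test_nearest_reference_on_sixty_degree_grid(query, expected_angle):
    gdb = _lookup_db()
    idx = nearest_reference(gdb, [query])
    assert gdb.records[idx].theta_ref[0] == expected_angle


def test_nearest_reference_tie_breaks_to_lowest_index():
    gdb = _lookup_db()
    # 60 is equidistant from 30 and 90; the earlier record wins
    assert nearest_reference(gdb, [60.0]) == 0


def test_nearest_reference_rejects_bad_shapes_and_empty_db():
    gdb = _lookup_db()
    with pytest.raises(ValueError):
        nearest_reference(gdb, [0.0, 0.0])
    with pytest.raises(ValueError):
        nearest_reference(GroupDatabase(group_id=1, member_indices=np.array([0])), [0.0])


def test_duplicate_reference_points_rejected():
    gdb = _lookup_db()
    with pytest.raises(ValueError):
        gdb.add_record(gdb.records[0])


def test_lam_reproduces_its_own_center_exactly(fig1_db):
    model, db = fig1_db
    for gdb in db.group_dbs:
        for rec in gdb.records:
            dU, dbeta, dq = evaluate_group(rec, rec.theta_ref, db.vacuo)
            assert dU == pytest.approx(rec.U_ref - db.vacuo.U_vac, abs=1e-12)
            np.testing.assert_allclose(
                dbeta, rec.beta_ref - db.vacuo.beta_vac, atol=1e-12
            )
            np.testing.assert_allclose(dq, rec.q_ref - db.vacuo.q_vac, atol=1e-12)


def test_fitted_hessian_equals_bowl_curvature(one_torsion_molecule):
    curvature = 0.004
    params = cosine_params(
        one_torsion_molecule, [()],
        torsion_terms=((QuadraticBowl(center=150.0, curvature=curvature),),),
    )
    model = make_synthetic_model(one_torsion_molecule, params)
    vac = minimize_vacuo(model, [np.array([140.0])])
    rec = fit_reference(model, one_torsion_molecule, 0, [200.0], vac)
    assert rec.H[0, 0] == pytest.approx(curvature, abs=1e-12)
    # and the quadratic group LAM is exact away from the center
    for q in (170.0, 210.0, 250.0):
        dU, _, _ = evaluate_group(rec, [q], vac)
        oracle = minimize_at(model, [q]).energy - vac.U_vac
        assert dU == pytest.approx(oracle, abs=1e-10)


def test_cosine_group_on_sixty_degree_grid_regression_bound(one_torsion_molecule):
    # frozen bound: max |LAM - oracle| over a 1-degree scan for a pure
    # m=3 cosine of amplitude 5 on the 60-degree offset-30 grid
    params = cosine_params(
        one_torsion_molecule, [(CosineTerm(5.0, 3, 0.0),)]
    )
    model = make_synthetic_model(one_torsion_molecule, params)
    vac = minimize_vacuo(model, [np.array([60.0])])
    grid = [30.0, 90.0, 150.0, 210.0, 270.0, 330.0]
    gdb = GroupDatabase(group_id=0, member_indices=np.array([0]))
    for p in grid:
        gdb.add_record(fit_reference(model, one_torsion_molecule, 0, [p], vac))
    worst = 0.0
    for q in np.arange(0.0, 360.0, 1.0):
        rec = gdb.records[nearest_reference(gdb, [q])]
        dU, _, _ = evaluate_group(rec, [q], vac)
        oracle = minimize_at(model, [q]).energy - vac.U_vac
        worst = max(worst, abs(dU - oracle))
    assert worst <= 2.8540 + 1e-3


def test_partitioned_evaluation_reports_per_group_provenance(fig1_db):
    model, db = fig1_db
    result = evaluate(db, [104.0, 235.0])
    chosen = {
        c.group_id: db.group_db(c.group_id).records[c.reference_index].theta_ref[0]
        for c in result.per_group
    }
    assert chosen == {0: 90.0, 1: 210.0}
    assert result.delta_U == pytest.approx(
        sum(c.delta_U for c in result.per_group), abs=1e-12
    )


def test_single_group_database_degenerates_to_plain_lam():
    molecule, params, grids = make_fixture("two-torsion")
    params.cross_couplings = ()  # same surface under either grouping
    model = make_synthetic_model(molecule, params)
    merged = molecule.as_single_group()
    model_merged = make_synthetic_model(merged, params)
    db_full = build_full_database(model, molecule, grids, seed=1)
    db_single = build_partitioned_database(model_merged, merged, grids, seed=1)
    rng = np.random.default_rng(6)
    for theta in rng.uniform(0, 360, (20, 2)):
        a = evaluate(db_full, theta)
        b = evaluate(db_single, theta)
        assert a.delta_U == pytest.approx(b.delta_U, abs=1e-12)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-12)


def test_partitioned_evaluation_exact_on_quadratic_affine_model(quad_affine_db):
    model, db = quad_affine_db
    rng = np.random.default_rng(0)
    for theta in rng.uniform(0, 360, (100, 2)):
        result = evaluate(db, theta)
        oracle = minimize_at(model, theta)
        assert result.delta_U == pytest.approx(
            oracle.energy - db.vacuo.U_vac, abs=1e-8
        )
        np.testing.assert_allclose(result.beta, oracle.beta, atol=1e-8)
        np.testing.assert_allclose(result.charges, oracle.charges, atol=1e-8)


def test_partitioning_error_decomposes_into_single_group_errors():
    # with no cross-group coupling, the partitioned-evaluation energy
    # error equals the sum of the per-group LAM errors: the partitioning
    # itself contributes nothing
    molecule, _, grids = make_fixture("paraben-like")
    params = SyntheticModelParams.randomized(
        molecule, seed=9, cross_coupling_epsilon=0.0, intra_coupling_amplitude=3.0
    )
    model = make_synthetic_model(molecule, params)
    db = build_partitioned_database(model, molecule, grids, seed=1)
    rng = np.random.default_rng(8)
    for theta in rng.uniform(0, 360, (100, 3)):
        result = evaluate(db, theta)
        total_err = result.delta_U - (
            minimize_at(model, theta).energy - db.vacuo.U_vac
        )
        group_err_sum = 0.0
        for gid, contrib in enumerate(result.per_group):
            idx = molecule.group_indices(gid)
            solo = np.array(db.vacuo.theta_vac)
            solo[idx] = theta[idx]
            oracle_g = minimize_at(model, solo).energy - db.vacuo.U_vac
            group_err_sum += contrib.delta_U - oracle_g
        assert total_err == pytest.approx(group_err_sum, abs=1e-9)


def test_rebase_noop_when_no_lower_minimum(fig1_db):
    model, db = fig1_db
    with pytest.warns(UserWarning):
        same = rebase_vacuo(db, model, db.vacuo.theta_vac)
    assert same is db


def test_rebase_adopts_lower_well_and_restores_nonnegative_deltas(
    one_torsion_molecule, two_well_model
):
    # initialize the database deliberately at the higher well near 90
    vac_high = minimize_vacuo(two_well_model, [np.array([85.0])])
    gdb = GroupDatabase(group_id=0, member_indices=np.array([0]))
    grid = [30.0, 90.0, 150.0, 210.0, 270.0, 330.0]
    for p in grid:
        gdb.add_record(
            fit_reference(two_well_model, one_torsion_molecule, 0, [p], vac_high)
        )
    from torlam import PartitionedDatabase

    db = PartitionedDatabase(
        molecule=one_torsion_molecule, vacuo=vac_high, group_dbs=[gdb]
    )
    assert db.is_stale()  # references near 270 undercut the 90-well energy
    ledger_before = db.ledger.total
    rebased = rebase_vacuo(db, two_well_model, [260.0])
    assert rebased.vacuo.U_vac < db.vacuo.U_vac
    assert not rebased.is_stale()
    for rec in rebased.group_db(0).records:
        assert rec.U_ref >= rebased.vacuo.U_vac - 1e-9
    # one refit per reference plus the confirming vacuo minimization
    assert rebased.ledger.total - ledger_before == len(grid) + 1
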