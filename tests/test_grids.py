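"""Grid dialects, database construction, call accounting, adaptive variant."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torlam import (
    TorsionGrid,
    adaptive_refine,
    build_full_database,
    build_partitioned_database,
    build_uniform_grid,
    grid_group_sizes,
    make_fixture,
    make_synthetic_model,
    percent_reduction,
    projected_call_counts,
    validation_max_error,
    wrap_angle,
)
from torlam.synthetic import CosineTerm, SyntheticModelParams

from conftest import cosine_params


class TestGridDialects:
    def test_wraparound_sixty_degree_offset_thirty(self):
        g = TorsionGrid.wraparound(60.0, offset=30.0)
        assert g.points == (30.0, 90.0, 150.0, 210.0, 270.0, 330.0)

    @pytest.mark.parametrize(
        "lower,inc,upper,expected",
        [
            (60.0, 120.0, 300.0, (60.0, 180.0, 300.0)),
            (0.0, 180.0, 180.0, (0.0, 180.0)),
            (-30.0, 120.0, 210.0, (-30.0, 90.0, 210.0)),
            (120.0, 30.0, 240.0, (120.0, 150.0, 180.0, 210.0, 240.0)),
        ],
    )
    def test_bounded_inclusive_endpoints(self, lower, inc, upper, expected):
        assert TorsionGrid.bounded(lower, inc, upper).points == expected

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TorsionGrid.bounded(0.0, 50.0, 120.0)  # span not divisible
        with pytest.raises(ValueError):
            TorsionGrid.wraparound(70.0)  # 360 not divisible
        with pytest.raises(ValueError):
            TorsionGrid.explicit([])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        inc=st.sampled_from([30.0, 45.0, 60.0, 90.0, 120.0, 180.0]),
        offset=st.floats(0.0, 29.0),
    )
    def test_bounded_spec_covering_circle_equals_wraparound(self, inc, offset):
        wrap = TorsionGrid.wraparound(inc, offset=offset)
        bound = TorsionGrid.bounded(offset, inc, 360.0 - inc + offset)
        assert np.allclose(sorted(wrap.points), sorted(wrap_angle(bound.points)))

    def test_cartesian_product_lexicographic(self):
        grids = [TorsionGrid.bounded(60.0, 120.0, 300.0)] * 3
        pts = build_uniform_grid(grids)
        assert pts.shape == (27, 3)
        np.testing.assert_array_equal(pts[0], [60.0, 60.0, 60.0])
        np.testing.assert_array_equal(pts[1], [60.0, 60.0, 180.0])
        np.testing.assert_array_equal(pts[-1], [300.0, 300.0, 300.0])

    def test_dict_round_trip(self):
        g = TorsionGrid.bounded(-30.0, 120.0, 210.0)
        assert TorsionGrid.from_dict(g.to_dict()) == g
        assert TorsionGrid.from_dict(
            {"dialect": "wraparound", "increment": 60, "offset": 30}
        ).points == TorsionGrid.wraparound(60.0, 30.0).points


class TestCallAccounting:
    def test_two_group_sixty_degree_build_needs_thirteen_minimizations(self, fig1_db):
        _, db = fig1_db
        assert db.ledger.total == 13
        assert db.ledger.get("vacuo") == 1
        assert [len(g.records) for g in db.group_dbs] == [6, 6]

    def test_three_torsion_partitioned_vs_full_counts(self):
        molecule, params, grids = make_fixture("paraben-like")
        model = make_synthetic_model(molecule, params)
        part = build_partitioned_database(model, molecule, grids, seed=1)
        full = build_full_database(model, molecule, grids, seed=1)
        assert part.ledger.total == 43  # 6 + 36 + 1
        assert full.ledger.total == 217  # 6^3 + 1
        assert full.n_references == 216
        assert percent_reduction(217, 43) == pytest.approx(80.18, abs=0.01)

    def test_narrow_grid_counts_and_reduction(self):
        molecule, params, grids = make_fixture("paracetamol-like")
        proj = projected_call_counts(molecule, grids)
        assert proj.group_sizes == (3, 25)
        assert proj.partitioned_total == 29  # 3 + 5*5 + 1
        assert proj.full_total == 76  # 3*5*5 + 1
        assert round(proj.reduction_percent) == 62

    def test_eight_torsion_restricted_counts(self):
        molecule, params, grids = make_fixture("xx-restricted")
        proj = projected_call_counts(molecule, grids)
        assert proj.group_sizes == (8, 16)
        assert proj.partitioned_total == 25
        assert proj.full_total == 129  # 2^7 + 1

    def test_eight_torsion_wide_initial_grid_sizes(self):
        molecule, _, grids = make_fixture("xx-like")
        assert grid_group_sizes(molecule, grids) == [27, 162]

    def test_adaptive_size_projection_totals(self):
        proj = projected_call_counts(group_sizes=[334, 8461])
        assert proj.partitioned_total == 8796
        assert proj.full_equivalent == 334 * 8461  # ~2.8 million

    def test_full_equivalent_for_large_groups(self):
        proj = projected_call_counts(group_sizes=[1148, 4121])
        assert proj.full_equivalent == 4730908  # ~4.7 million

    def test_single_group_projection_coincides(self):
        proj = projected_call_counts(group_sizes=[12])
        assert proj.partitioned_total == proj.full_total == 13

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(sizes=st.lists(st.integers(1, 50), min_size=1, max_size=5))
    def test_ledger_arithmetic_for_any_grid_shape(self, sizes):
        proj = projected_call_counts(group_sizes=sizes)
        assert proj.partitioned_total == sum(sizes) + 1
        assert proj.full_equivalent == math.prod(sizes)

    @pytest.mark.parametrize(
        "full,part,expected",
        [(217, 43, 80.18), (76, 29, 61.84), (100, 100, 0.0)],
    )
    def test_percent_reduction(self, full, part, expected):
        assert percent_reduction(full, part) == pytest.approx(expected, abs=0.01)

    def test_records_follow_grid_points_in_order(self, fig1_db):
        _, db = fig1_db
        refs = [r.theta_ref[0] for r in db.group_dbs[0].records]
        assert refs == [30.0, 90.0, 150.0, 210.0, 270.0, 330.0]

    def test_empty_grid_guard(self):
        molecule, params, grids = make_fixture("two-torsion")
        model = make_synthetic_model(molecule, params)
        with pytest.raises(ValueError):
            build_partitioned_database(model, molecule, {"t1": grids["t1"]}, seed=1)


def _coarse_cosine_setup(one_torsion_molecule):
    params = cosine_params(one_torsion_molecule, [(CosineTerm(6.0, 3, 0.0),)])
    model = make_synthetic_model(one_torsion_molecule, params)
    grids = {"t1": TorsionGrid.wraparound(120.0, offset=60.0)}
    db = build_partitioned_database(model, one_torsion_molecule, grids, seed=1)
    return model, db


class TestAdaptiveRefinement:
    def test_exact_surrogate_converges_immediately(self, quad_affine_db):
        model, db = quad_affine_db
        refined = adaptive_refine(model, db, 0, seed=3, sweep_size=32)
        info = refined.group_db(0).provenance["adaptive"]
        assert info["converged"]
        assert len(refined.group_db(0).records) == len(db.group_db(0).records)
        assert info["history"][0]["added"] == 0

    def test_coarse_cosine_grid_refined_below_tolerance(self, one_torsion_molecule):
        model, db = _coarse_cosine_setup(one_torsion_molecule)
        before = validation_max_error(model, db, 0, step=1.0, relevance_cutoff=20.0)
        assert before > 5.0  # the 120-degree grid is deliberately too coarse
        refined = adaptive_refine(
            model, db, 0, delta_star=5.0, delta_star_star=20.0, seed=7
        )
        after = validation_max_error(model, refined, 0, step=1.0, relevance_cutoff=20.0)
        assert refined.group_db(0).provenance["adaptive"]["converged"]
        assert after <= 5.0
        assert after <= before

    def test_refinement_keeps_all_initial_points(self, one_torsion_molecule):
        model, db = _coarse_cosine_setup(one_torsion_molecule)
        refined = adaptive_refine(model, db, 0, seed=7)
        initial = {r.theta_ref[0] for r in db.group_db(0).records}
        final = {r.theta_ref[0] for r in refined.group_db(0).records}
        assert initial <= final
        assert len(final) > len(initial)

    def test_refinement_deterministic_for_seed(self, one_torsion_molecule):
        model, db = _coarse_cosine_setup(one_torsion_molecule)
        a = adaptive_refine(model, db, 0, seed=11)
        b = adaptive_refine(model, db, 0, seed=11)
        np.testing.assert_array_equal(
            a.group_db(0).theta_refs(), b.group_db(0).theta_refs()
        )
        assert a.ledger.counts == b.ledger.counts

    def test_budget_exhaustion_flags_non_convergence(self, one_torsion_molecule):
        model, db = _coarse_cosine_setup(one_torsion_molecule)
        refined = adaptive_refine(
            model, db, 0, delta_star=0.0001, candidate_budget=8, sweep_size=8, seed=7
        )
        assert not refined.group_db(0).provenance["adaptive"]["converged"]
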