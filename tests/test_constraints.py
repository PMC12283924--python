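import numpy as np
import pytest

from softtet import _kernels
from softtet.constraints import (
    ConstraintSet,
    DistanceConstraint,
    ShapeMatchCluster,
    TetElasticConstraint,
    VolumeConstraint,
    apply_position_update,
    best_fit_transform,
    build_constraints,
    deformation_gradient,
    eval_distance,
    eval_neo_deviatoric,
    eval_neo_hydrostatic,
    eval_volume,
    make_cluster,
    rest_shape_matrix,
    shape_match_corrections,
    xpbd_delta_lambda,
)
from softtet.material import Material
from softtet.tet_mesh import TetMesh

from conftest import UNIT_TET_VERTS

TET_IDS = np.array([0, 1, 2, 3])


def _tet_elastic(rest=UNIT_TET_VERTS, offset=0.0):
    Dm = rest_shape_matrix(rest, TET_IDS)
    return TetElasticConstraint(
        ids=TET_IDS,
        inv_rest_shape=np.linalg.inv(Dm),
        rest_volume=abs(np.linalg.det(Dm)) / 6.0,
        rest_offset=offset,
    )


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# Constraint families as (constructor, evaluator, ids) for parametrized tests.
def _family(name):
    if name == "distance":
        c = DistanceConstraint(0, 1, rest_length=1.0)
        return c, eval_distance, np.array([c.i, c.j])
    if name == "volume":
        c = VolumeConstraint(TET_IDS, rest_volume=1.0 / 6.0)
        return c, eval_volume, c.ids
    if name == "neo_hydro":
        c = _tet_elastic()
        return c, eval_neo_hydrostatic, c.ids
    c = _tet_elastic()
    return c, eval_neo_deviatoric, c.ids


FAMILIES = ["distance", "volume", "neo_hydro", "neo_dev"]


class TestValues:
    def test_distance_axis_aligned(self):
        c = DistanceConstraint(0, 1, rest_length=1.0)
        value, grads = eval_distance(c, np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert value == pytest.approx(1.0)
        assert grads[0] == pytest.approx([-1.0, 0.0, 0.0])
        assert grads[1] == pytest.approx([1.0, 0.0, 0.0])

    def test_coincident_pair_skipped(self):
        c = DistanceConstraint(0, 1, rest_length=1.0)
        assert eval_distance(c, np.zeros((2, 3))) is None

    def test_volume_rest_and_scaled(self):
        c = VolumeConstraint(TET_IDS, rest_volume=1.0 / 6.0)
        assert eval_volume(c, UNIT_TET_VERTS)[0] == pytest.approx(0.0)
        centroid = UNIT_TET_VERTS.mean(axis=0)
        doubled = centroid + 2.0 * (UNIT_TET_VERTS - centroid)
        assert eval_volume(c, doubled)[0] == pytest.approx(7.0 / 6.0)

    def test_deformation_gradient_cases(self):
        c = _tet_elastic()
        assert deformation_gradient(c, UNIT_TET_VERTS) == pytest.approx(np.eye(3))
        assert deformation_gradient(c, 2.0 * UNIT_TET_VERTS) == pytest.approx(
            2.0 * np.eye(3)
        )
        R = _random_rotation(np.random.default_rng(7))
        F = deformation_gradient(c, UNIT_TET_VERTS @ R.T)
        assert F == pytest.approx(R)
        assert np.linalg.det(F) == pytest.approx(1.0)

    @pytest.mark.parametrize("s,expected", [(1.0, 0.0), (2.0, 7.0), (0.5, -0.875)])
    def test_hydrostatic_uniform_scale(self, s, expected):
        c = _tet_elastic()
        value, _ = eval_neo_hydrostatic(c, s * UNIT_TET_VERTS)
        assert value == pytest.approx(expected)

    def test_hydrostatic_rest_offset(self):
        c = _tet_elastic(offset=0.25)
        assert eval_neo_hydrostatic(c, UNIT_TET_VERTS)[0] == pytest.approx(-0.25)

    @pytest.mark.parametrize("s", [1.0, 2.0, 0.3])
    def test_deviatoric_homogeneity(self, s):
        c = _tet_elastic()
        value, _ = eval_neo_deviatoric(c, s * UNIT_TET_VERTS)
        assert value == pytest.approx(s * np.sqrt(3.0))


class TestGradients:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_central_differences(self, family):
        """Analytic gradients agree with central finite differences on 100
        seeded random configurations to 1e-6 relative."""
        rng = np.random.default_rng(42)
        c, evaluate, ids = _family(family)
        for _ in range(100):
            pos = np.zeros((4, 3))
            pos[ids] = UNIT_TET_VERTS[: len(ids)] + 0.3 * rng.standard_normal(
                (len(ids), 3)
            )
            res = evaluate(c, pos)
            if res is None:
                continue
            _, grads = res
            h = 1e-6
            fd = np.zeros_like(grads)
            for k, v in enumerate(ids):
                for axis in range(3):
                    for sign, store in ((1, 1.0), (-1, -1.0)):
                        p = pos.copy()
                        p[v, axis] += sign * h
                        fd[k, axis] += store * evaluate(c, p)[0]
            fd /= 2 * h
            scale = max(np.abs(grads).max(), 1e-12)
            assert np.abs(grads - fd).max() / scale < 1e-6

    @pytest.mark.parametrize("family", FAMILIES)
    def test_translation_invariance_and_zero_sum(self, family):
        rng = np.random.default_rng(3)
        c, evaluate, ids = _family(family)
        pos = np.zeros((4, 3))
        pos[ids] = UNIT_TET_VERTS[: len(ids)] + 0.2 * rng.standard_normal((len(ids), 3))
        value, grads = evaluate(c, pos)
        shifted = pos + np.array([0.4, -1.3, 2.2])
        value2, _ = evaluate(c, shifted)
        assert value2 == pytest.approx(value, rel=1e-9, abs=1e-12)
        assert grads.sum(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_rotation_invariance(self, family):
        rng = np.random.default_rng(11)
        c, evaluate, ids = _family(family)
        pos = np.zeros((4, 3))
        pos[ids] = UNIT_TET_VERTS[: len(ids)] + 0.2 * rng.standard_normal((len(ids), 3))
        value, _ = evaluate(c, pos)
        R = _random_rotation(rng)
        value2, _ = evaluate(c, pos @ R.T)
        assert value2 == pytest.approx(value, rel=1e-9, abs=1e-12)

    def test_deviatoric_force_consistency(self, soft_material):
        """-alpha_D^-1 C_D grad(C_D) equals the analytic deviatoric force -mu*V*F
        mapped through the rest-shape inverse."""
        rng = np.random.default_rng(5)
        c = _tet_elastic()
        mu = soft_material.lame_mu
        V = c.rest_volume
        c.alpha_d = 1.0 / (mu * V)
        pos = UNIT_TET_VERTS + 0.2 * rng.standard_normal((4, 3))
        value, grads = eval_neo_deviatoric(c, pos)
        force_constraint = -(1.0 / c.alpha_d) * value * grads
        F = deformation_gradient(c, pos)
        G = F @ c.inv_rest_shape.T
        force_analytic = -mu * V * np.vstack([-G.T.sum(axis=0), G.T])
        assert force_constraint == pytest.approx(force_analytic, rel=1e-9)


class TestShapeMatching:
    def _cluster(self, rng, n=8):
        rest = rng.standard_normal((n, 3))
        masses = rng.uniform(0.5, 2.0, n)
        com = (masses[:, None] * rest).sum(axis=0) / masses.sum()
        return ShapeMatchCluster(
            member_ids=np.arange(n),
            rest_offsets=rest - com,
            member_masses=masses,
            stiffness=1.0,
        ), rest

    def test_rigid_recovery_exact(self):
        rng = np.random.default_rng(0)
        cluster, rest = self._cluster(rng)
        R0 = _random_rotation(rng)
        t0 = np.array([0.3, -0.2, 1.0])
        moved = rest @ R0.T + t0
        R, T = best_fit_transform(cluster, moved)
        assert R == pytest.approx(R0, abs=1e-10)
        assert R @ R.T == pytest.approx(np.eye(3), abs=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert shape_match_corrections(cluster, moved) == pytest.approx(
            np.zeros_like(moved), abs=1e-10
        )

    def test_pure_translation_gives_identity(self):
        rng = np.random.default_rng(1)
        cluster, rest = self._cluster(rng)
        R, T = best_fit_transform(cluster, rest + np.array([5.0, 0.0, -2.0]))
        assert R == pytest.approx(np.eye(3), abs=1e-12)

    def test_reflection_contamination_yields_proper_rotation(self):
        rng = np.random.default_rng(2)
        cluster, rest = self._cluster(rng)
        mirrored = rest.copy()
        mirrored[:, 0] *= -1  # reflection: naive fit would give det = -1
        R, _ = best_fit_transform(cluster, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_corrections_reach_best_fit_pose(self):
        rng = np.random.default_rng(3)
        cluster, rest = self._cluster(rng)
        pos = rest + 0.05 * rng.standard_normal(rest.shape)
        R, T = best_fit_transform(cluster, pos)
        dx = shape_match_corrections(cluster, pos)
        corrected = pos + dx
        goal = cluster.rest_offsets @ R.T + T
        assert corrected == pytest.approx(goal, abs=1e-12)

    def test_momentum_conservation(self):
        rng = np.random.default_rng(4)
        cluster, rest = self._cluster(rng)
        pos = rest + 0.1 * rng.standard_normal(rest.shape)
        dx = shape_match_corrections(cluster, pos)
        total = (cluster.member_masses[:, None] * dx).sum(axis=0)
        assert total == pytest.approx(np.zeros(3), abs=1e-12)

    def test_zero_stiffness_no_motion(self):
        rng = np.random.default_rng(5)
        cluster, rest = self._cluster(rng)
        cluster.stiffness = 0.0
        pos = rest + 0.1 * rng.standard_normal(rest.shape)
        assert shape_match_corrections(cluster, pos) == pytest.approx(
            np.zeros_like(pos)
        )


class TestXpbdUpdate:
    def test_hand_case(self):
        # C=1, two unit-inverse-mass vertices, unit gradients, hard constraint
        grads = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        dl = xpbd_delta_lambda(1.0, grads, np.ones(2), 0.0, 0.0)
        assert dl == pytest.approx(-0.5)

    def test_zero_violation(self):
        grads = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert xpbd_delta_lambda(0.0, grads, np.ones(2), 0.0, 0.0) == 0.0

    def test_infinite_compliance_limit(self):
        grads = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        dl = xpbd_delta_lambda(1.0, grads, np.ones(2), 1e12, 0.0)
        assert abs(dl) < 1e-11

    def test_all_pinned_skipped(self):
        grads = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert xpbd_delta_lambda(1.0, grads, np.zeros(2), 0.0, 0.0) is None

    def test_position_update_respects_pinning(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        grads = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        apply_position_update(1.0, grads, np.array([0.0, 1.0]), pos, np.array([0, 1]))
        assert pos[0] == pytest.approx([0.0, 0, 0])
        assert pos[1] == pytest.approx([3.0, 0, 0])

    def test_one_projection_restores_rest_length(self):
        c = DistanceConstraint(0, 1, rest_length=1.0)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        value, grads = eval_distance(c, pos)
        dl = xpbd_delta_lambda(value, grads, np.ones(2), 0.0, 0.0)
        apply_position_update(dl, grads, np.ones(2), pos, np.array([0, 1]))
        assert np.linalg.norm(pos[0] - pos[1]) == pytest.approx(1.0, abs=1e-12)

    def test_equal_mass_projection_preserves_centroid(self):
        rng = np.random.default_rng(9)
        for family in FAMILIES:
            c, evaluate, ids = _family(family)
            pos = np.zeros((4, 3))
            pos[ids] = UNIT_TET_VERTS[: len(ids)] + 0.2 * rng.standard_normal(
                (len(ids), 3)
            )
            before = pos[ids].mean(axis=0)
            value, grads = evaluate(c, pos)
            dl = xpbd_delta_lambda(value, grads, np.ones(len(ids)), 1e-3, 0.0)
            apply_position_update(dl, grads, np.ones(len(ids)), pos, ids)
            assert pos[ids].mean(axis=0) == pytest.approx(before, abs=1e-12)


class TestKernelConsistency:
    """The numba solver kernels must reproduce the numpy reference path."""

    def _reference_sweep(self, cs, pos, w, h):
        from softtet.constraints import project_constraint

        for k in range(len(cs.t_rest_vol)):
            c = TetElasticConstraint(
                ids=cs.t_ids[k],
                inv_rest_shape=cs.t_inv_rest[k],
                rest_volume=cs.t_rest_vol[k],
                alpha_h=cs.t_alpha_h[k],
                alpha_d=cs.t_alpha_d[k],
                rest_offset=cs.t_offset[k],
                lambda_h=cs.t_lambda_h[k],
                lambda_d=cs.t_lambda_d[k],
            )
            project_constraint(c, pos, w, h, kind="hydro")
            project_constraint(c, pos, w, h, kind="dev")
            cs.t_lambda_h[k] = c.lambda_h
            cs.t_lambda_d[k] = c.lambda_d
        for k in range(len(cs.v_rest)):
            c = VolumeConstraint(
                cs.v_ids[k], cs.v_rest[k], cs.v_alpha[k], cs.v_lambda[k]
            )
            project_constraint(c, pos, w, h)
            cs.v_lambda[k] = c.lambda_acc
        for k in range(len(cs.d_rest)):
            c = DistanceConstraint(
                cs.d_ids[k, 0], cs.d_ids[k, 1], cs.d_rest[k], cs.d_alpha[k],
                cs.d_lambda[k],
            )
            project_constraint(c, pos, w, h)
            cs.d_lambda[k] = c.lambda_acc

    def test_kernels_match_reference(self, small_box, soft_material):
        rng = np.random.default_rng(12)
        cs_a = build_constraints(small_box, soft_material)
        cs_b = build_constraints(small_box, soft_material)
        w = small_box.inv_mass
        pos0 = small_box.rest_positions + 3e-3 * rng.standard_normal(
            small_box.rest_positions.shape
        )
        h = 1e-3
        pos_kernel = pos0.copy()
        _kernels.project_neo_pass(
            pos_kernel, w, cs_a.t_ids, cs_a.t_inv_rest, cs_a.t_offset,
            cs_a.t_alpha_h / h**2, cs_a.t_alpha_d / h**2,
            cs_a.t_lambda_h, cs_a.t_lambda_d, _kernels.MODE_XPBD, 0.0, 0.0,
        )
        _kernels.project_volume_pass(
            pos_kernel, w, cs_a.v_ids, cs_a.v_rest, cs_a.v_alpha / h**2,
            cs_a.v_lambda, _kernels.MODE_XPBD, 0.0,
        )
        _kernels.project_distance_pass(
            pos_kernel, w, cs_a.d_ids, cs_a.d_rest, cs_a.d_alpha / h**2,
            cs_a.d_lambda, _kernels.MODE_XPBD, 0.0,
        )
        pos_ref = pos0.copy()
        self._reference_sweep(cs_b, pos_ref, w, h)
        assert pos_kernel == pytest.approx(pos_ref, rel=1e-12, abs=1e-14)
        assert cs_a.d_lambda == pytest.approx(cs_b.d_lambda, rel=1e-12)
        assert cs_a.t_lambda_h == pytest.approx(cs_b.t_lambda_h, rel=1e-12)
        assert cs_a.t_lambda_d == pytest.approx(cs_b.t_lambda_d, rel=1e-12)


class TestBuildConstraints:
    def test_unit_tet_counts(self, unit_tet, soft_material):
        cs = build_constraints(
            unit_tet, soft_material, shape_matching=True, shape_clusters="global"
        )
        assert cs.counts == {
            "distance": 6,
            "volume": 1,
            "tet_elastic": 1,
            "shape_clusters": 1,
        }

    def test_cluster_rest_offsets_centered(self, small_box, soft_material):
        cluster = make_cluster(
            small_box, np.arange(small_box.n_vertices), stiffness=0.5
        )
        weighted = (cluster.member_masses[:, None] * cluster.rest_offsets).sum(axis=0)
        assert weighted == pytest.approx(np.zeros(3), abs=1e-12)

    def test_rest_correction_offset(self, unit_tet, soft_material):
        cs = build_constraints(unit_tet, soft_material, rest_correction=True)
        expected = soft_material.lame_mu / soft_material.lame_lambda
        assert cs.t_offset[0] == pytest.approx(expected)

    def test_grid_clusters_cover_vertices(self, small_box, soft_material):
        cs = build_constraints(
            small_box, soft_material, shape_matching=True,
            shape_clusters="grid", cluster_cells=2,
        )
        covered = np.concatenate([c.member_ids for c in cs.clusters])
        assert set(covered) == set(range(small_box.n_vertices))
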