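"""Rigid intensity registration, emulated-manual model, and BBR."""
import numpy as np
import pytest

import aslreg as ar
from aslreg.registration import BBRConfig, RegistrationError, _bbr_vertex_terms
from aslreg.volume import centered_affine


class TestRigidRegister:
    def test_self_registration_recovers_identity(self, phantom):
        structural, _, _ = phantom
        res = ar.rigid_register(structural, structural)
        mm, deg = ar.transform_residual(ar.RigidTransform.identity(), res.transform)
        assert mm < 0.05 and deg < 0.05
        assert res.converged

    def test_recovers_known_offset(self, fast_spec, phantom, cbf_truth, acq_params):
        """CBF moving image acquired under a (3 mm, 4 deg) pose offset is
        registered back within 0.5 mm / 0.5 deg."""
        structural, labels, _ = phantom
        true_t = ar.RigidTransform((4.0, -2.0, 3.0), (3.0, -2.0, 1.5))
        acq = ar.generate_asl_series(
            labels, cbf_truth, acq_params, fast_spec,
            true_transform=true_t, rng=np.random.default_rng(0),
        )
        cbf = ar.quantify_series(acq.series, acq.m0, acq_params)
        res = ar.rigid_register(cbf.volume, structural)
        mm, deg = ar.transform_residual(res.transform, true_t)
        assert mm < 0.5 and deg < 0.5

    def test_descent_contract(self, moved_participant, phantom):
        structural, _, _ = phantom
        res = ar.rigid_register(moved_participant["cbf"].volume, structural)
        assert res.final_cost <= res.initial_cost

    def test_no_overlap_flagged(self, phantom):
        structural, _, _ = phantom
        far = ar.RigidTransform((0, 0, 0), (1e4, 0, 0))
        with pytest.raises(RegistrationError, match="overlap"):
            ar.rigid_register(structural, structural, init=far)


class TestEmulateManual:
    def test_zero_sd_returns_truth(self):
        t = ar.RigidTransform((3, 2, 1), (4, 5, 6))
        out = ar.emulate_manual(t, operator_sd=(0.0, 0.0), seed=9)
        assert np.allclose(out.matrix, t.matrix, atol=1e-12)

    def test_same_seed_same_perturbation(self):
        t = ar.RigidTransform((1, 2, 3), (1, 1, 1))
        a = ar.emulate_manual(t, (1.0, 1.0), seed=5)
        b = ar.emulate_manual(t, (1.0, 1.0), seed=5)
        c = ar.emulate_manual(t, (1.0, 1.0), seed=6)
        assert np.array_equal(a.matrix, b.matrix)
        assert not np.allclose(a.matrix, c.matrix)

    def test_rms_displacement_matches_error_propagation(self):
        """For operator sd (1 mm, 1 deg) the RMS displacement of a point at
        radius r from the rotation center is sqrt(3*sd_t^2 + 2*r^2*sd_r^2)
        (small-angle propagation); Monte-Carlo agrees within 5%."""
        truth = ar.RigidTransform()
        r = 80.0
        point = np.array([[r, 0.0, 0.0]])
        sd_mm, sd_deg = 1.0, 1.0
        disp = []
        for seed in range(1500):
            m = ar.emulate_manual(truth, (sd_mm, sd_deg), seed=seed)
            disp.append(np.linalg.norm(m.apply_points(point) - point))
        rms = np.sqrt(np.mean(np.square(disp)))
        sd_rad = np.deg2rad(sd_deg)
        expected = np.sqrt(3 * sd_mm**2 + 2 * r**2 * sd_rad**2)
        assert abs(rms - expected) / expected < 0.05


@pytest.fixture(scope="module")
def step_volume(fast_spec):
    """Sharp GM/WM step across the boundary on a 1 mm grid, so samples
    2 mm off the interface are interpolation-exact."""
    from aslreg.phantom import shell_implicit

    shape = (100, 100, 84)
    vol = ar.Volume(np.zeros(shape), centered_affine(shape, (1.0, 1.0, 1.0)))
    pts = vol.world_grid()
    inside = shell_implicit(
        pts, fast_spec.wm_axes(), fast_spec.boundary_bump_amplitude
    ) <= 0
    data = np.where(inside, 20.0, 60.0).reshape(shape)
    return ar.Volume(data, vol.affine)


class TestBBRCost:
    def test_aligned_step_matches_analytic_minimum(self, step_volume, phantom):
        """With a clean 60/20 step the percent contrast is exactly
        Q = 100*40/(40+eps) at every vertex, so the cost equals
        1 - tanh(slope*Q) in closed form."""
        _, _, boundary = phantom
        cfg = BBRConfig()
        got = ar.bbr_cost(ar.RigidTransform.identity(), step_volume, boundary, cfg)
        q = 100.0 * (60.0 - 20.0) / (0.5 * (60.0 + 20.0) + cfg.eps)
        expected = 1.0 - np.tanh(cfg.slope * q)
        assert abs(got - expected) < 1e-6

    def test_misaligned_cost_strictly_greater(self, step_volume, phantom):
        _, _, boundary = phantom
        at_truth = ar.bbr_cost(ar.RigidTransform.identity(), step_volume, boundary)
        shifted = ar.bbr_cost(
            ar.RigidTransform((0, 0, 0), (5.0, 0, 0)), step_volume, boundary
        )
        assert shifted > at_truth

    def test_pervertex_terms_match_independent_sampler(self, moved_participant):
        """Recompute 10 random vertices' cost terms with an independently
        written trilinear sampler; agreement to 1e-9."""
        cbf = moved_participant["cbf"].volume
        boundary = moved_participant["boundary"]
        t = moved_participant["true_transform"]
        cfg = BBRConfig()
        terms, valid = _bbr_vertex_terms(t, cbf, boundary, cfg)

        def trilinear(vol, p):
            ijk = np.linalg.inv(vol.affine) @ np.append(p, 1.0)
            i0 = np.floor(ijk[:3]).astype(int)
            f = ijk[:3] - i0
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((1 - f[0]) if dx == 0 else f[0]) * \
                            ((1 - f[1]) if dy == 0 else f[1]) * \
                            ((1 - f[2]) if dz == 0 else f[2])
                        acc += w * vol.data[i0[0] + dx, i0[1] + dy, i0[2] + dz]
            return acc

        inv = np.linalg.inv(t.matrix)
        rng = np.random.default_rng(0)
        for vi in rng.choice(np.flatnonzero(valid), 10, replace=False):
            v, n = boundary.vertices[vi], boundary.normals[vi]
            vals = []
            for sgn in (+1, -1):
                p_fixed = v + sgn * cfg.offset_distance * n
                p_mov = (inv @ np.append(p_fixed, 1.0))[:3]
                vals.append(trilinear(cbf, p_mov))
            q = 100.0 * (vals[0] - vals[1]) / (0.5 * (vals[0] + vals[1]) + cfg.eps)
            expect = 1.0 - np.tanh(cfg.slope * cfg.contrast_sign * q)
            assert abs(terms[vi] - expect) < 1e-9

    def test_vertex_order_invariance(self, moved_participant):
        cbf = moved_participant["cbf"].volume
        b = moved_participant["boundary"]
        t = moved_participant["true_transform"]
        perm = np.random.default_rng(1).permutation(b.n_vertices)
        shuffled = ar.BoundarySurface(b.vertices[perm], b.normals[perm], b.faces)
        assert abs(ar.bbr_cost(t, cbf, b) - ar.bbr_cost(t, cbf, shuffled)) < 1e-12

    def test_mostly_out_of_volume_rejected(self, moved_participant):
        cbf = moved_participant["cbf"].volume
        b = moved_participant["boundary"]
        far = ar.RigidTransform((0, 0, 0), (500.0, 0, 0))
        with pytest.raises(RegistrationError, match="invalid"):
            ar.bbr_cost(far, cbf, b)


class TestBBRRefine:
    def test_truth_init_stays_near_truth(self, moved_participant):
        res = ar.bbr_refine(
            moved_participant["true_transform"],
            moved_participant["cbf"].volume,
            moved_participant["boundary"],
        )
        mm, deg = ar.transform_residual(res.transform, moved_participant["true_transform"])
        assert mm < 0.2 and deg < 0.2

    def test_reduces_perturbed_init_residual(self, moved_participant):
        truth = moved_participant["true_transform"]
        pert = ar.RigidTransform((2.0, 0, -2.0), (2.0, -2.0, 0)).compose(truth)
        init_mm, init_deg = ar.transform_residual(pert, truth)
        res = ar.bbr_refine(
            pert, moved_participant["cbf"].volume, moved_participant["boundary"],
            method="manual+BBR",
        )
        mm, deg = ar.transform_residual(res.transform, truth)
        assert mm < init_mm and deg < init_deg
        assert res.converged

    def test_two_initializations_converge_together(self, moved_participant, phantom):
        """Manual-initialized and FLIRT-initialized refinements land within
        0.5 mm / 0.5 deg of each other on a clean phantom."""
        structural, _, _ = phantom
        truth = moved_participant["true_transform"]
        cbf = moved_participant["cbf"].volume
        boundary = moved_participant["boundary"]
        manual = ar.emulate_manual(truth, (1.0, 1.0), seed=3)
        flirt = ar.rigid_register(cbf, structural)
        a = ar.bbr_refine(manual, cbf, boundary, method="manual+BBR")
        b = ar.bbr_refine(flirt.transform, cbf, boundary, method="FLIRT+BBR")
        mm, deg = ar.transform_residual(a.transform, b.transform)
        assert mm < 0.5 and deg < 0.5
        assert a.method == "manual+BBR" and b.method == "FLIRT+BBR"

    def test_dof12_affine_refinement_runs(self, moved_participant):
        res = ar.bbr_refine(
            moved_participant["true_transform"],
            moved_participant["cbf"].volume,
            moved_participant["boundary"],
            BBRConfig(dof=12, max_iter=10),
        )
        assert res.final_cost <= res.initial_cost
        mm, deg = ar.transform_residual(
            res.transform, moved_participant["true_transform"]
        )
        assert mm < 1.0 and deg < 1.0

    def test_invalid_init_raises(self, moved_participant):
        far = ar.RigidTransform((0, 0, 0), (500.0, 0, 0))
        with pytest.raises(RegistrationError, match="initialization"):
            ar.bbr_refine(
                far, moved_participant["cbf"].volume, moved_participant["boundary"]
            )
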