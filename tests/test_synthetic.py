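"""Forward kinetic simulation, exact-identity construction, cohorts, phantoms."""

import dataclasses

import numpy as np
import pytest

import fdopaquant as fq
from fdopaquant.synthetic import REFERENCE_KINETICS


class TestInputFunction:
    def test_null_shape_gives_zero_curve(self):
        t = np.linspace(0.1, 90, 50)
        curve = fq.simulate_input_function(fq.BolusShape(A=0, B=0), t)
        assert np.all(curve.values == 0)

    def test_bolus_starts_at_zero(self):
        curve = fq.simulate_input_function(fq.BolusShape(), np.array([0.0, 1.0, 2.0]))
        assert curve.values[0] == 0.0

    def test_peak_location_matches_grid_search(self):
        shape = fq.BolusShape()
        dense = np.arange(1, 600_000) * 1e-4  # 0.0001-min grid over 60 min
        t_peak_oracle = dense[np.argmax(shape(dense))]
        # analytic curve evaluated on the same grid must peak at the same spot
        curve = fq.simulate_input_function(shape, dense)
        assert dense[np.argmax(curve.values)] == t_peak_oracle

    def test_negative_shape_rejected(self):
        with pytest.raises(ValueError):
            fq.BolusShape(A=-1.0)


def rk4_oracle(plasma, params, scheme, dt=1.0 / 600.0):
    """Fixed-step (0.1 s) Runge-Kutta integration of the two-tissue model.

    Independent of the production path (adaptive stiff solver): plain RK4 on
    the state [C_free, C_trap, integral of total], with the fine grid chosen
    so every frame edge lies exactly on a step.
    """
    K1, k2, k3 = params.K1, params.k2, params.k3
    edges = scheme.edges_min
    n = int(round(edges[-1] / dt))

    def f(t, y):
        cp = plasma.concentration(t)
        return np.array([K1 * cp - (k2 + k3) * y[0], k3 * y[0], y[0] + y[1]])

    y = np.zeros(3)
    cum = np.zeros(n + 1)
    for i in range(n):
        t = i * dt
        k_1 = f(t, y)
        k_2 = f(t + dt / 2, y + dt / 2 * k_1)
        k_3 = f(t + dt / 2, y + dt / 2 * k_2)
        k_4 = f(t + dt, y + dt * k_3)
        y = y + dt / 6 * (k_1 + 2 * k_2 + 2 * k_3 + k_4)
        cum[i + 1] = y[2]
    idx = np.rint(edges / dt).astype(int)
    assert np.allclose(idx * dt, edges, atol=1e-12), "frame edges must lie on the grid"
    return np.diff(cum[idx]) / scheme.durations_min


class TestTissueTAC:
    def test_no_uptake(self, plasma, full_scheme):
        tac = fq.simulate_tissue_tac(plasma, fq.KineticParams(0.0, 0.3, 0.1), full_scheme)
        assert np.all(tac.values == 0)

    def test_steady_state_ratio_is_k1_over_k2(self):
        # constant plasma level, reference model: C_t/C_p -> K1/k2
        scheme = fq.build_framing("1x600,9x6000")  # out to 15.1 h
        t = scheme.mid_times_min
        plasma = fq.PlasmaCurve(times=t, values=np.full_like(t, 20.0))
        params = fq.KineticParams(K1=0.4, k2=0.25, k3=0.0)
        tac = fq.simulate_tissue_tac(plasma, params, scheme)
        assert tac.values[-1] / 20.0 == pytest.approx(0.4 / 0.25, rel=1e-3)

    @pytest.mark.parametrize(
        "params",
        [
            fq.KineticParams(0.25, 0.25, 0.017),
            fq.KineticParams(0.5, 0.5, 0.0),
            fq.KineticParams(0.3, 0.15, 0.08),
        ],
    )
    def test_matches_rk4_oracle(self, plasma, full_scheme, params):
        got = fq.simulate_tissue_tac(plasma, params, full_scheme).values
        want = rk4_oracle(plasma, params, full_scheme)
        assert np.allclose(got, want, rtol=1e-3, atol=1e-9 * want.max())


class TestPatlakExactConstruction:
    def test_identity_case(self, reference_tac):
        out = fq.construct_patlak_exact_tac(reference_tac, ki=0.0, v=1.0)
        assert np.allclose(out.values, reference_tac.values, rtol=1e-15)

    def test_constant_reference_is_linear_in_time(self):
        # running integral of a constant c under the origin-triangle rule is
        # c*(t - t0/2) past the first mid-time, so the output is linear in t
        scheme = fq.build_framing("10x60")
        c = 5.0
        ref = fq.TimeActivityCurve(scheme, np.full(10, c), decay_corrected=True)
        out = fq.construct_patlak_exact_tac(ref, ki=0.02, v=1.5)
        t = scheme.mid_times_min
        expected = (0.02 * (t - t[0] / 2) + 1.5) * c
        expected[0] = (0.02 * t[0] / 2 + 1.5) * c
        assert np.allclose(out.values, expected, rtol=1e-14)

    def test_zero_reference_rejected(self, full_scheme):
        ref = fq.TimeActivityCurve(full_scheme, np.zeros(41))
        with pytest.raises(ValueError):
            fq.construct_patlak_exact_tac(ref, 0.01, 1.0)


def zero_noise_config(**kw):
    cfg = fq.CohortConfig(
        ki_contra_sd=0.0,
        severity_sd={0: 0.0, 7: 0.0, 14: 0.0, 28: 0.0},
        da_contra_sd=0.0,
        da_link=fq.LinkParams(1.2, -20.0, 0.0),
        rot_link=fq.LinkParams(-0.035, 4.0, 0.0),
        **kw,
    )
    return cfg


class TestCohort:
    def test_degenerate_noise_makes_groups_identical(self):
        recs = fq.simulate_cohort(zero_noise_config(seed=7))
        by_dose = {}
        for r in recs:
            by_dose.setdefault(r.dose_ug, []).append(r)
        for dose, group in by_dose.items():
            if dose == 0:
                continue  # control rotations stay Poisson even at zero link noise
            first = group[0]
            for r in group[1:]:
                assert (r.ki_ipsi, r.ki_contra, r.da_ipsi, r.da_contra, r.rotations) == (
                    first.ki_ipsi,
                    first.ki_contra,
                    first.da_ipsi,
                    first.da_contra,
                    first.rotations,
                )

    def test_unlesioned_controls_are_symmetric(self):
        recs = fq.simulate_cohort(zero_noise_config(seed=11))
        for r in recs:
            if r.dose_ug == 0:
                assert r.ki_ipsi == pytest.approx(r.ki_contra, rel=1e-15)

    def test_link_recovery_by_regression(self):
        # the steep 2.5 slope maps (0, 100] onto s in (0.08, 0.48]; group
        # severities sit >= 3 SD inside that band so neither clip censors
        cfg = fq.CohortConfig(
            group_sizes={0: 200, 7: 200, 14: 200, 28: 200},
            severity_mean={0: 1.0, 7: 0.38, 14: 0.28, 28: 0.20},
            severity_sd={0: 0.02, 7: 0.03, 14: 0.03, 28: 0.025},
            da_link=fq.LinkParams(2.5, -20.0, 6.0),
            seed=42,
        )
        recs = fq.simulate_cohort(cfg)
        lesioned = [r for r in recs if r.dose_ug != 0]
        x = np.array([100.0 * r.ki_ipsi / r.ki_contra for r in lesioned])
        y = np.array([100.0 * r.da_ipsi / r.da_contra for r in lesioned])
        reg = fq.linear_regression(x, y)
        assert abs(reg.slope - 2.5) < 3 * reg.stderr_slope
        assert abs(reg.intercept - (-20.0)) < 3 * reg.stderr_intercept

    def test_seed_reproducibility_bytes(self, tmp_path):
        from fdopaquant import io as fio

        cfg = fq.CohortConfig(seed=99)
        for name in ("a.tsv", "b.tsv"):
            fio.write_cohort(fq.simulate_cohort(cfg), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_mean_asymmetry_monotone_in_dose(self):
        cfg = fq.CohortConfig(group_sizes={0: 60, 7: 60, 14: 60, 28: 60}, seed=5)
        recs = fq.simulate_cohort(cfg)
        means = []
        for dose in sorted(cfg.group_sizes):
            vals = [r.ki_ipsi / r.ki_contra for r in recs if r.dose_ug == dose]
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_zero_group_size_rejected(self):
        cfg = fq.CohortConfig(group_sizes={0: 0, 7: 6})
        with pytest.raises(ValueError, match="group size"):
            fq.simulate_cohort(cfg)


class TestPhantom:
    def test_noiseless_voxels_equal_tac(self, rng):
        scheme = fq.build_framing("4x60")
        tacs = {
            lab: fq.TimeActivityCurve(scheme, rng.uniform(1, 9, 4), decay_corrected=True)
            for lab in (1, 2, 3)
        }
        ph = fq.generate_phantom(scheme, tacs, noise_cv=0.0, seed=0)
        for lab in (1, 2, 3):
            region = ph.frames[ph.mask == lab]
            assert np.array_equal(region, np.broadcast_to(tacs[lab].values, region.shape))
        assert np.all(ph.frames[ph.mask == 0] == 0)

    def test_voi_mean_within_standard_error(self):
        # 10,000+ voxel region: the VOI mean must sit within 5 SE of the truth
        scheme = fq.build_framing("2x30,2x300")
        mask = np.ones((25, 25, 17), dtype=np.int16)
        nvox = int(mask.sum())
        assert nvox >= 10_000
        values = np.array([5.0, 8.0, 12.0, 9.0])
        tac = fq.TimeActivityCurve(scheme, values, decay_corrected=True)
        noise_cv = 0.1
        ph = fq.generate_phantom(scheme, {1: tac}, noise_cv=noise_cv, seed=1, mask=mask)
        got = fq.extract_voi_tac(ph, 1).values
        w = scheme.durations_min / scheme.durations_min.mean()
        se = noise_cv * values / np.sqrt(w) / np.sqrt(nvox)
        assert np.all(np.abs(got - values) < 5 * se)

    def test_length_mismatch_rejected(self, rng):
        scheme = fq.build_framing("4x60")
        wrong = fq.TimeActivityCurve(fq.build_framing("3x60"), rng.uniform(1, 2, 3))
        with pytest.raises(ValueError):
            fq.generate_phantom(scheme, {1: wrong, 2: wrong, 3: wrong})

    def test_negative_noise_rejected(self, rng):
        scheme = fq.build_framing("4x60")
        tac = fq.TimeActivityCurve(scheme, rng.uniform(1, 2, 4))
        with pytest.raises(ValueError):
            fq.generate_phantom(scheme, {1: tac, 2: tac, 3: tac}, noise_cv=-0.1)

    def test_round_trip_through_nifti(self, tmp_path, rng):
        from fdopaquant import io as fio

        scheme = fq.build_framing("4x60")
        tacs = {
            lab: fq.TimeActivityCurve(scheme, rng.uniform(1, 9, 4), decay_corrected=True)
            for lab in (1, 2, 3)
        }
        ph = fq.generate_phantom(scheme, tacs, noise_cv=0.05, seed=2)
        fio.save_phantom(ph, tmp_path)
        back = fio.load_phantom(
            tmp_path / "image.nii", tmp_path / "mask.nii", tmp_path / "timing.tsv"
        )
        assert back.scheme == ph.scheme
        assert np.array_equal(back.mask, ph.mask)
        # image stored as float32
        assert np.allclose(back.frames, ph.frames, rtol=1e-6)
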