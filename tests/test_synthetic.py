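"""Frame schedule, 2TCM forward model and population/phantom generators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pbifkit import (
    FrameSchedule,
    KineticParams,
    PopulationConfig,
    default_schedule,
    feng_eval,
    feng_fit,
    generate_phantom,
    generate_population,
    patlak_fit,
    patlak_transform,
    simulate_tissue_tac,
)
from pbifkit.synthetic import UniformPrior, _conv_exp_with_exp, tissue_concentration


class TestDefaultSchedule:
    def test_frame_count_and_span(self, schedule62):
        assert schedule62.n_frames == 62
        assert schedule62.total_seconds == 3900.0  # 65 min

    def test_first_two_frames_are_ten_seconds(self, schedule62):
        assert schedule62.duration_s[0] == 10.0
        assert schedule62.duration_s[1] == 10.0

    def test_bit_stability(self, schedule62):
        again = default_schedule()
        assert np.array_equal(again.start_s, schedule62.start_s)
        assert np.array_equal(again.duration_s, schedule62.duration_s)

    def test_rejects_gapped_frames(self):
        with pytest.raises(ValueError, match="contiguous"):
            FrameSchedule(np.array([0.0, 20.0]), np.array([10.0, 10.0]))

    def test_rejects_nonpositive_durations(self):
        with pytest.raises(ValueError, match="positive"):
            FrameSchedule(np.array([0.0, 10.0]), np.array([10.0, 0.0]))


class TestTissueForwardModel:
    def test_pure_blood_voxel_equals_aif(self, schedule62, printed_params):
        kp = KineticParams(K1=0.1, k2=0.2, k3=0.05, vB=1.0 - 1e-12)
        tac = simulate_tissue_tac(printed_params, kp, schedule62)
        aif = feng_eval(printed_params, schedule62.mid_min)
        assert np.allclose(tac.value, aif, rtol=1e-9, atol=1e-12)

    def test_constant_input_reversible_steady_state(self):
        # unit-step input, k3=0: Ct(t) = K1*(1-e^(-k2 t))/k2 -> K1/k2
        K1, k2 = 0.1, 0.2
        conv = _conv_exp_with_exp(1.0, 0.0, k2, np.array([200.0]))
        assert K1 * conv[0] == pytest.approx(K1 / k2, rel=1e-10)

    def test_patlak_slope_matches_closed_form_ki(self, schedule62, printed_params):
        aif = printed_params.scaled(550.0)
        kp = KineticParams(K1=0.1, k2=0.25, k3=0.08, vB=0.0)
        tac = simulate_tissue_tac(aif, kp, schedule62)
        res = patlak_fit(patlak_transform(tac, aif), t_star=45.0)
        assert res.ki == pytest.approx(kp.ki, rel=0.02)
        assert kp.ki == pytest.approx(0.02424, rel=1e-3)

    def test_closed_form_convolution_matches_stiff_ode(self, schedule62, printed_params):
        aif = printed_params.scaled(550.0)
        kp = KineticParams(K1=0.12, k2=0.3, k3=0.06, vB=0.04)

        def rhs(t, y):
            cp = feng_eval(aif, t)
            return [kp.K1 * cp - (kp.k2 + kp.k3) * y[0], kp.k3 * y[0]]

        t = schedule62.mid_min
        late = t > 2.0
        sol = solve_ivp(rhs, (0.0, 65.0), [0.0, 0.0], t_eval=t[late], method="Radau",
                        rtol=1e-10, atol=1e-12, max_step=0.1)
        oracle = (1 - kp.vB) * sol.y.sum(axis=0) + kp.vB * feng_eval(aif, t[late])
        ours = tissue_concentration(aif, kp, t)[late]
        assert np.allclose(ours, oracle, rtol=5e-3)

    def test_vb_mixing_is_convex_combination(self, schedule62, printed_params):
        aif = printed_params.scaled(550.0)
        lo = KineticParams(K1=0.1, k2=0.25, k3=0.08, vB=0.0)
        hi = KineticParams(K1=0.1, k2=0.25, k3=0.08, vB=0.3)
        t = schedule62.mid_min
        pure_tissue = tissue_concentration(aif, lo, t)
        blood = feng_eval(aif, t)
        mixed = tissue_concentration(aif, hi, t)
        assert np.allclose(mixed, 0.7 * pure_tissue + 0.3 * blood, rtol=1e-12)

    def test_reversible_tracer_patlak_slope_vanishes(self, schedule62, printed_params):
        aif = printed_params.scaled(550.0)
        kp = KineticParams(K1=0.1, k2=0.2, k3=0.0, vB=0.0)
        tac = simulate_tissue_tac(aif, kp, schedule62)
        points = patlak_transform(tac, aif)
        slopes = [abs(patlak_fit(points, ts).ki) for ts in (20.0, 35.0, 50.0)]
        assert np.all(np.diff(slopes) < 0)
        assert slopes[-1] < 1e-3 * kp.K1

    def test_zero_rate_sum_rejected(self, schedule62, printed_params):
        with pytest.raises(ValueError):
            KineticParams(K1=0.1, k2=0.0, k3=0.0)


class TestGeneratePopulation:
    def test_same_seed_is_bit_identical(self):
        a = generate_population(3, seed=5)
        b = generate_population(3, seed=5)
        for sa, sb in zip(a, b):
            assert sa.true_aif == sb.true_aif
            assert np.array_equal(sa.idif.value, sb.idif.value)
            for lab in sa.labels:
                assert np.array_equal(sa.tac(lab).value, sb.tac(lab).value)

    def test_zero_variability_yields_identical_subjects(self):
        point = UniformPrior(K1=(0.1, 0.1), k2=(0.25, 0.25), k3=(0.08, 0.08), vB=(0.05, 0.05))
        config = PopulationConfig(
            cv=0.0, noise_level=0.0, delay_range=(0.7, 0.7),
            tumor_prior=point, gray_matter_prior=point, n_tumors=1,
        )
        subjects = generate_population(3, config, seed=0)
        ref = subjects[0]
        expected = tissue_concentration(
            ref.true_aif, KineticParams(0.1, 0.25, 0.08, 0.05), ref.schedule.mid_min
        )
        for sub in subjects:
            assert sub.true_aif == ref.true_aif
            assert np.array_equal(sub.tac("tumor_1").value, ref.tac("tumor_1").value)
        assert np.allclose(ref.tac("tumor_1").value, expected, rtol=1e-12)

    def test_mean_drawn_delay_near_range_midpoint(self):
        config = PopulationConfig(noise_level=0.0)
        subjects = generate_population(16, config, seed=2)
        delays = np.array([s.true_aif.tau for s in subjects])
        lo, hi = config.delay_range
        sem = (hi - lo) / np.sqrt(12) / np.sqrt(len(delays))
        assert abs(delays.mean() - 0.5 * (lo + hi)) < 2 * sem

    def test_noiseless_idif_fit_recovers_drawn_params(self):
        """Full loop: generated subjects' IDIFs refit to their drawn AIF parameters."""
        config = PopulationConfig(noise_level=0.0, idif_noise=False)
        for i, sub in enumerate(generate_population(2, config, seed=21)):
            fit = feng_fit(sub.idif, seed=i)
            for name in ("tau", "A1", "A2", "A3", "lam1", "lam2", "lam3"):
                assert getattr(fit.params, name) == pytest.approx(
                    getattr(sub.true_aif, name), rel=0.01
                )

    def test_invalid_prior_bounds_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            UniformPrior(K1=(0.3, 0.1), k2=(0.1, 0.2), k3=(0.01, 0.1), vB=(0.0, 0.1))


@pytest.fixture(scope="module")
def subject():
    config = PopulationConfig(noise_level=0.0, idif_noise=False)
    return generate_population(1, config, seed=9)[0]


class TestGeneratePhantom:
    def test_noiseless_regions_carry_exact_tacs(self, subject):
        volume, labels, truth = generate_phantom(subject, dims=(16, 16, 16))
        for lab in np.unique(labels):
            voxels = volume[labels == lab]
            assert np.allclose(voxels, voxels[0], rtol=0, atol=0)
        blood = volume[labels == 1][0]
        assert np.allclose(blood, feng_eval(subject.true_aif, subject.schedule.mid_min))

    def test_label_histogram_matches_geometry(self, subject):
        volume, labels, _ = generate_phantom(subject, dims=(16, 16, 16))
        counts = np.bincount(labels.ravel())
        assert counts.sum() == 16**3
        assert np.all(counts[1:] > 0)  # every configured region placed

    def test_too_small_dims_rejected(self, subject):
        with pytest.raises(ValueError, match="too small"):
            generate_phantom(subject, dims=(4, 4, 4))
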