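"""Coil combination, eddy-current compensation, spectral registration, DAS/DO."""

import numpy as np
import pytest
from dataclasses import replace

from gabapipe.core import Fid, SpectralAxis, TransientSet
from gabapipe.preprocess import (
    VARIANTS,
    PipelineVariant,
    combine_coils,
    das_align,
    do_align,
    eddy_current_correct,
    estimate_coil_weights,
    run_pipeline,
    spectral_register,
)
from gabapipe.synthetic import (
    ArtifactSpec,
    CohortSpec,
    clean_edit_fids,
    simulate_transient_set,
)


def single_coil_set(axis, on, off, water):
    data = np.stack([water, on, off])[None, :, :]
    return TransientSet(
        data=data, edit_states=("water_reference", "on", "off"), axis=axis
    )


class TestCoilWeights:
    def _set_with(self, axis, water_per_coil, noise_rng=None, noise_chol=None):
        n_coils = len(water_per_coil)
        n_trans = 6
        data = np.zeros((n_coils, 1 + n_trans, axis.n_points), dtype=complex)
        for i, w in enumerate(water_per_coil):
            data[i, 0, :] = w
        if noise_rng is not None:
            z = noise_rng.standard_normal(
                (n_coils, n_trans + 1, axis.n_points)
            ) + 1j * noise_rng.standard_normal((n_coils, n_trans + 1, axis.n_points))
            data += np.einsum("ij,jtk->itk", noise_chol, z) / np.sqrt(2)
        states = ("water_reference",) + ("on", "off") * (n_trans // 2)
        return TransientSet(data=data, edit_states=states, axis=axis)

    def test_identity_noise_equal_water_gives_equal_weights(self, axis):
        rng = np.random.default_rng(0)
        ts = self._set_with(axis, [10.0, 10.0], rng, np.eye(2))
        w = estimate_coil_weights(ts).weights
        assert abs(w[0] - w[1]) / abs(w[0]) < 0.2

    def test_identity_noise_weights_proportional_to_signal(self, axis):
        rng = np.random.default_rng(1)
        ts = self._set_with(axis, [20.0, 10.0], rng, np.eye(2))
        w = estimate_coil_weights(ts).weights
        assert abs(w[0]) / abs(w[1]) == pytest.approx(2.0, rel=0.25)

    def test_correlated_noise_matches_hand_inverted_oracle(self, axis):
        # N = [[1, .5], [.5, 1]], s = (1, 1): N^-1 s = (2/3, 2/3)
        rng = np.random.default_rng(2)
        chol = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        ts = self._set_with(axis, [50.0, 50.0], rng, chol)
        cw = estimate_coil_weights(ts)
        expect = np.linalg.solve(cw.noise_correlation, cw.water_amplitudes)
        assert np.allclose(cw.weights, expect)
        # and the estimated covariance approximates the true one
        assert cw.noise_correlation[0, 1].real == pytest.approx(0.5, abs=0.1)
        assert np.allclose(cw.weights.real / 50.0, 2.0 / 3.0, atol=0.1)

    def test_combined_water_has_zero_phase_at_t0(self, axis):
        rng = np.random.default_rng(3)
        sens = np.array([1.0 * np.exp(0.7j), 0.8 * np.exp(-1.2j)])
        ts = self._set_with(axis, 50.0 * sens, rng, np.eye(2))
        cw = estimate_coil_weights(ts)
        combined = combine_coils(ts, cw)
        phase0 = np.angle(combined.water_fid(0).samples[:4].mean())
        assert abs(phase0) < 0.05

    def test_single_coil_identity(self, axis):
        rng = np.random.default_rng(4)
        ts = self._set_with(axis, [5.0], rng, np.eye(1))
        cw = estimate_coil_weights(ts)
        combined = combine_coils(ts, cw)
        # single-coil combination is a positive rescaling
        scale = cw.weights[0].conjugate()
        assert np.allclose(combined.data[0], ts.data[0] * scale)

    def test_combination_snr_beats_best_single_coil(self, hippocampus):
        axis = SpectralAxis(n_points=512, dwell_time=1 / 4000)
        wins = 0
        for seed in range(10):
            cohort = CohortSpec(n_on=4, n_off=4, n_coils=4, random_seed=seed)
            ts, _ = simulate_transient_set(
                cohort, hippocampus, ArtifactSpec.none(), 1, 1, axis
            )
            combined = combine_coils(ts, estimate_coil_weights(ts))

            def water_snr(samples):
                peak = np.abs(np.fft.fft(samples)).max()
                tail = samples[-64:]
                noise = np.std(np.concatenate([tail.real, tail.imag]))
                return peak / noise

            snr_combined = water_snr(combined.data[0, 0])
            best_single = max(water_snr(ts.data[c, 0]) for c in range(4))
            wins += snr_combined >= best_single
        assert wins == 10


class TestEddyCurrentCorrection:
    def test_zero_phase_water_is_identity(self, axis):
        t = axis.time_axis
        fid = Fid(np.exp(2j * np.pi * 100 * t - 20 * t), axis)
        water = Fid(1000.0 * np.exp(-30 * t), axis)
        out = eddy_current_correct(fid, water)
        assert np.allclose(out.samples, fid.samples)

    def test_shared_phase_cancels_to_machine_precision(self, axis):
        t = axis.time_axis
        phi = 1.2 * np.exp(-t / 0.015) + 0.3 * np.sin(2 * np.pi * 3 * t)
        clean = np.exp(2j * np.pi * 200 * t - 25 * t)
        fid = Fid(clean * np.exp(1j * phi), axis)
        water = Fid(800.0 * np.exp(-10 * t) * np.exp(1j * phi), axis)
        out = eddy_current_correct(fid, water)
        assert np.allclose(out.samples, clean, atol=1e-9)

    def test_random_smooth_phase_residual_below_tolerance(self, axis):
        t = axis.time_axis
        rng = np.random.default_rng(0)
        for _ in range(20):
            coeffs = rng.normal(size=4)
            phi = sum(c * np.cos(2 * np.pi * (k + 1) * t) for k, c in enumerate(coeffs))
            clean = np.exp(-15 * t)
            fid = Fid(clean * np.exp(1j * phi), axis)
            water = Fid(500 * clean * np.exp(1j * phi), axis)
            out = eddy_current_correct(fid, water)
            residual = np.angle(out.samples[:512] / clean[:512])
            assert np.max(np.abs(residual)) < 1e-6

    def test_all_zero_water_rejected(self, axis):
        fid = Fid(np.ones(axis.n_points), axis)
        with pytest.raises(ValueError, match="zero"):
            eddy_current_correct(fid, Fid(np.zeros(axis.n_points), axis))

    def test_noisy_tail_phase_is_frozen_not_amplified(self, axis):
        # water decays into noise; correction must not inject wild phase there
        t = axis.time_axis
        rng = np.random.default_rng(1)
        noise = 0.1 * (rng.standard_normal(axis.n_points)
                       + 1j * rng.standard_normal(axis.n_points))
        water = Fid(100 * np.exp(-60 * t) + noise, axis)
        fid = Fid(np.exp(-15 * t), axis)
        out = eddy_current_correct(fid, water)
        assert np.all(np.isfinite(out.samples))
        # beyond the freeze point the applied phase is constant
        applied = np.angle(fid.samples[-100:] / out.samples[-100:])
        assert np.ptp(applied) < 1e-9


class TestSpectralRegistration:
    def test_reference_itself_maps_to_zero(self, axis, hippocampus):
        _, off = clean_edit_fids(hippocampus, axis)
        _, res = spectral_register([off], off)
        assert abs(res.phases[0]) < 1e-6
        assert abs(res.frequencies[0]) < 1e-6

    def test_noise_free_offsets_recovered_exactly(self, axis, hippocampus):
        _, off = clean_edit_fids(hippocampus, axis)
        t = axis.time_axis
        for phi0, f0 in ((0.4, 1.5), (-0.9, -3.0), (0.05, 7.0)):
            shifted = Fid(off.samples * np.exp(-1j * phi0 - 2j * np.pi * f0 * t), axis)
            _, res = spectral_register([shifted], off)
            assert res.phases[0] == pytest.approx(phi0, abs=1e-6)
            assert res.frequencies[0] == pytest.approx(f0, abs=1e-6)

    def test_objective_never_worse_than_uncorrected(self, axis, hippocampus):
        rng = np.random.default_rng(0)
        _, off = clean_edit_fids(hippocampus, axis)
        noisy = Fid(off.samples + 0.5 * (rng.standard_normal(axis.n_points)
                                         + 1j * rng.standard_normal(axis.n_points)), axis)
        n_fit = int(0.1 / axis.dwell_time)
        _, res = spectral_register([noisy], off)
        base = np.linalg.norm(noisy.samples[:n_fit] - off.samples[:n_fit])
        assert res.objectives[0] <= base + 1e-9

    def test_drift_recovery_at_realistic_snr(self, axis2048, hippocampus):
        # injected random-walk drifts on edit-off transients recovered from
        # noisy data well below the drift step size
        err_p, err_f = [], []
        for seed in range(4):
            cohort = CohortSpec(random_seed=seed, n_on=16, n_off=16)
            ts, gt = simulate_transient_set(
                cohort, hippocampus, ArtifactSpec(eddy_amplitude=0), 1, 1, axis2048
            )
            ts1 = combine_coils(ts, estimate_coil_weights(ts))
            off_fids = [ts1.fid(0, i) for i in ts1.off_indices]
            ref = Fid(np.mean([f.samples for f in off_fids], axis=0), axis2048)
            _, res = spectral_register(off_fids, ref)
            ep = res.phases + gt.phase_offsets[1::2]
            ef = res.frequencies + gt.frequency_offsets[1::2]
            err_p.append(ep - ep.mean())
            err_f.append(ef - ef.mean())
        assert np.sqrt(np.mean(np.concatenate(err_p) ** 2)) < 0.03
        assert np.sqrt(np.mean(np.concatenate(err_f) ** 2)) < 0.3


class TestDifferenceArtifactSuppression:
    def test_identical_inputs_give_zero_correction(self, axis, hippocampus):
        _, off = clean_edit_fids(hippocampus, axis)
        _, (phi, f) = das_align(off, off)
        assert abs(phi) < 1e-6 and abs(f) < 1e-6

    def test_pure_offset_recovered(self, axis, hippocampus):
        _, off = clean_edit_fids(hippocampus, axis)
        t = axis.time_axis
        shifted = Fid(off.samples * np.exp(0.2j + 2j * np.pi * 1.0 * t), axis)
        _, (phi, f) = das_align(shifted, off)
        assert phi == pytest.approx(-0.2, abs=1e-6)
        assert f == pytest.approx(-1.0, abs=1e-6)
        _, (phi2, f2) = do_align(shifted, off)
        assert phi2 == pytest.approx(-0.2, abs=1e-3)
        assert f2 == pytest.approx(-1.0, abs=1e-3)

    def test_das_suppresses_creatine_subtraction_artifact(self, axis, hippocampus):
        # creatine-only scenario: an on/off frequency offset leaves a large
        # 3.03 ppm residual that DAS must remove almost completely
        cr_only = replace(
            hippocampus,
            resonances=tuple(
                r for r in hippocampus.resonances
                if r.edit_behavior == "off_only" and r.edit_on_scale == 1.0
            ),
        )
        on, off = clean_edit_fids(cr_only, axis)
        t = axis.time_axis
        on_shifted = Fid(on.samples * np.exp(2j * np.pi * 1.0 * t), axis)
        ppm = axis.ppm_axis
        band = (ppm > 2.9) & (ppm < 3.2)

        def residual(diff):
            return np.abs(diff.spectrum()[band]).max()

        before = residual(on_shifted - off)
        corrected, _ = das_align(on_shifted, off)
        after = residual(corrected - off)
        assert after < 0.2 * before

    def test_das_and_do_agree_on_drift_corrupted_cohorts(self, axis, hippocampus):
        # low measurement noise so a well-defined residual correction exists;
        # the remaining spread reflects the two objectives (L2 vs L1)
        agree = 0
        n = 10
        for seed in range(n):
            cohort = CohortSpec(random_seed=seed, n_coils=2, n_on=16, n_off=16,
                                noise_sd=0.05)
            ts, _ = simulate_transient_set(
                cohort, hippocampus, ArtifactSpec(eddy_amplitude=0), 1, 1, axis
            )
            ts1 = combine_coils(ts, estimate_coil_weights(ts))
            das = run_pipeline(ts1, VARIANTS["SR+DAS"]).das_correction
            do = run_pipeline(ts1, VARIANTS["SR+DO"]).das_correction
            if abs(das[0] - do[0]) < 0.1 and abs(das[1] - do[1]) < 0.5:
                agree += 1
        assert agree >= 9

    def test_span_outside_axis_rejected(self, axis, hippocampus):
        _, off = clean_edit_fids(hippocampus, axis)
        with pytest.raises(ValueError, match="span"):
            das_align(off, off, span_ppm=(40.0, 50.0))


class TestRunPipeline:
    def test_variant_labels(self):
        assert VARIANTS["plain"].label == "plain"
        assert VARIANTS["ECC+SR+DAS"].label == "ECC+SR+DAS"
        with pytest.raises(ValueError, match="registration"):
            PipelineVariant(ecc=False, sr=False, das_mode="das")

    def test_plain_artifact_free_difference_has_no_creatine(self, axis, hippocampus):
        cohort = CohortSpec(n_on=2, n_off=2, n_coils=1, noise_sd=0.0,
                            coil_sensitivities=(1 + 0j,), random_seed=0,
                            water_residual_fraction=0.0)
        ts, _ = simulate_transient_set(
            cohort, hippocampus, ArtifactSpec.none(), 1, 1, axis
        )
        pair = run_pipeline(ts, VARIANTS["plain"])
        # project the difference onto the pure creatine FID: off_only content
        # cancels exactly
        from gabapipe.synthetic import make_basis_fid

        tcr = next(r for r in hippocampus.resonances if r.name == "tCr")
        b = make_basis_fid(tcr, axis).samples
        overlap = abs(np.vdot(b, pair.diff_fid.samples)) / np.linalg.norm(b) ** 2
        # compare with the genuine GABA overlap, which must dominate
        gaba = next(r for r in hippocampus.resonances if r.name == "GABA_A")
        g = make_basis_fid(gaba, axis).samples
        gaba_overlap = abs(np.vdot(g, pair.diff_fid.samples)) / np.linalg.norm(g) ** 2
        assert gaba_overlap > 1.5 * overlap

    def test_provenance_round_trips(self, axis, hippocampus):
        cohort = CohortSpec(n_on=2, n_off=2, n_coils=1, random_seed=0)
        ts, _ = simulate_transient_set(cohort, hippocampus, ArtifactSpec(), 1, 1, axis)
        for name, variant in VARIANTS.items():
            pair = run_pipeline(ts, variant)
            assert pair.variant == variant
            assert pair.variant.label == (name if name != "plain" else "plain")

    def test_multicoil_input_rejected(self, axis, hippocampus):
        cohort = CohortSpec(n_on=1, n_off=1, n_coils=2, random_seed=0)
        ts, _ = simulate_transient_set(cohort, hippocampus, ArtifactSpec(), 1, 1, axis)
        with pytest.raises(ValueError, match="coil-combined"):
            run_pipeline(ts, VARIANTS["SR"])

    def test_drift_residual_ordering_plain_sr_das(self, axis, hippocampus):
        # noise-free drift-corrupted, non-edited resonances only: the
        # subtraction artifact shrinks strictly from plain to SR to SR+DAS
        cr_only = replace(
            hippocampus,
            resonances=tuple(
                r for r in hippocampus.resonances
                if r.edit_behavior == "off_only" and r.edit_on_scale == 1.0
            ),
        )
        ppm = axis.ppm_axis
        band = (ppm > 2.9) & (ppm < 3.2)
        wins = 0
        for seed in range(8):
            cohort = CohortSpec(random_seed=seed, n_coils=1, noise_sd=0.0,
                                coil_sensitivities=(1 + 0j,), n_on=16, n_off=16)
            ts, _ = simulate_transient_set(
                cohort, cr_only, ArtifactSpec(eddy_amplitude=0), 1, 1, axis
            )
            res = {}
            for v in ("plain", "SR", "SR+DAS"):
                pair = run_pipeline(ts, VARIANTS[v])
                res[v] = np.abs(pair.diff_fid.spectrum()[band]).max()
            if res["plain"] > res["SR"] >= res["SR+DAS"]:
                wins += 1
        assert wins == 8

    def test_subtraction_linearity(self, axis, hippocampus):
        cohort = CohortSpec(n_on=2, n_off=2, n_coils=1, random_seed=5)
        ts, _ = simulate_transient_set(cohort, hippocampus, ArtifactSpec.none(), 1, 1, axis)
        pair = run_pipeline(ts, VARIANTS["plain"])
        scaled = TransientSet(
            data=3.0 * ts.data, edit_states=ts.edit_states, axis=ts.axis
        )
        pair3 = run_pipeline(scaled, VARIANTS["plain"])
        assert np.allclose(pair3.diff_fid.samples, 3.0 * pair.diff_fid.samples)
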