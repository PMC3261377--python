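"""Undersampling, average estimation, CS solver, post-processing."""

import json

import numpy as np
import pytest
import tifffile

from cscine import (
    CineSeries,
    KSpaceCine,
    ReconConfig,
    SamplingPattern,
    average_from_undersampled,
    butterworth_filter,
    cs_objective,
    cs_reconstruct,
    export_magnitude,
    fft2c,
    generate_candidate,
    generate_phantom,
    ifft2c,
    image_to_kspace,
    lines_per_frame,
    retrospective_undersample,
    select_pattern,
    temporal_average,
    zerofill,
)
from conftest import make_sparse_fixture


def _random_kspace(rng, n_frames=4, n=16):
    frames = rng.normal(size=(n_frames, n, n)) + 1j * rng.normal(size=(n_frames, n, n))
    return image_to_kspace(CineSeries(frames)), frames


def test_undersample_r1_is_identity(rng):
    ks, _ = _random_kspace(rng)
    pat = generate_candidate(16, 4, 1, seed=0)
    und = retrospective_undersample(ks, pat)
    assert np.array_equal(und.samples, ks.samples)


def test_undersample_line_counts(rng):
    ks, _ = _random_kspace(rng)
    pat = generate_candidate(16, 4, 2, seed=1)
    und = retrospective_undersample(ks, pat)
    nonzero_lines = (np.abs(und.samples).sum(axis=2) > 0).sum(axis=1)
    assert (nonzero_lines == lines_per_frame(16, 2)).all()
    retained = np.count_nonzero(np.abs(und.samples))
    assert retained == 4 * lines_per_frame(16, 2) * 16


def test_undersample_dimension_mismatch_rejected(rng):
    ks, _ = _random_kspace(rng)
    with pytest.raises(ValueError, match="match"):
        retrospective_undersample(ks, generate_candidate(32, 4, 2, seed=0))


def test_average_fully_sampled_equals_temporal_average(rng):
    ks, frames = _random_kspace(rng)
    pat = generate_candidate(16, 4, 1, seed=0)
    avg = average_from_undersampled(retrospective_undersample(ks, pat))
    expected = temporal_average(CineSeries(ifft2c(ks.samples)))
    np.testing.assert_allclose(avg, expected, atol=1e-12)


def test_average_static_object_recovered_exactly(rng):
    obj = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
    series = CineSeries(np.repeat(obj[None], 6, axis=0))
    ks = image_to_kspace(series)
    pat = generate_candidate(16, 6, 2, seed=3)
    avg = average_from_undersampled(retrospective_undersample(ks, pat))
    np.testing.assert_allclose(avg, obj, atol=1e-12)


def test_average_single_measurement_line_taken_unchanged(rng):
    ks, _ = _random_kspace(rng, n_frames=2, n=4)
    mask = np.array([[1, 1, 1, 1], [0, 1, 1, 1]], dtype=np.uint8)
    pat = SamplingPattern(mask=mask, R=1.0, sigma=1.0, seed=0)
    und = retrospective_undersample(ks, pat)
    composite_k = fft2c(average_from_undersampled(und))
    np.testing.assert_allclose(composite_k[0], ks.samples[0, 0], atol=1e-12)


def test_average_coverage_violation_raises(rng):
    ks, _ = _random_kspace(rng, n_frames=2, n=4)
    mask = np.ones((2, 4), dtype=np.uint8)
    mask[:, 2] = 0
    pat = SamplingPattern(mask=mask, R=1.0, sigma=1.0, seed=0)
    with pytest.raises(ValueError, match="never measured"):
        average_from_undersampled(ks, pat)


def test_r1_reconstruction_equals_inverse_fft(rng):
    ks, frames = _random_kspace(rng)
    pat = generate_candidate(16, 4, 1, seed=0)
    rec = cs_reconstruct(retrospective_undersample(ks, pat))
    rel = np.linalg.norm(rec.frames - frames) / np.linalg.norm(frames)
    assert rel < 1e-6


def test_reconstruction_is_data_consistent(rng):
    """Residual RMS at measured locations <= the zero-filled init's (zero)."""
    ks, _ = _random_kspace(rng)
    pat = generate_candidate(16, 4, 2, seed=7)
    und = retrospective_undersample(ks, pat)
    rec = cs_reconstruct(und)
    resid = pat.mask[:, :, None] * fft2c(rec.frames) - und.samples
    scale = np.abs(und.samples).max()
    assert np.sqrt(np.mean(np.abs(resid) ** 2)) < 1e-10 * scale


def test_objective_not_above_zero_filled_initialization(rng):
    ks, _ = _random_kspace(rng)
    pat = generate_candidate(16, 4, 2, seed=7)
    und = retrospective_undersample(ks, pat)
    avg = average_from_undersampled(und)
    x0 = avg[None] + ifft2c(pat.mask[:, :, None] * (und.samples - fft2c(avg)[None]))
    rec = cs_reconstruct(und)
    mu = ReconConfig().mu
    assert cs_objective(und, pat, rec, mu) <= cs_objective(und, pat, CineSeries(x0), mu)


def _centered_unitary_dft(n):
    c = n // 2
    j = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(j - c, j - c) / n) / np.sqrt(n)


def test_centered_dft_matrix_matches_package_transform(rng):
    x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
    W = _centered_unitary_dft(8)
    np.testing.assert_allclose(W @ x @ W.T, fft2c(x), atol=1e-12)


def test_solver_objective_matches_independent_reference(rng):
    """Proximal-gradient oracle with an explicit DFT matrix, tight tolerance.

    The solver (pure Lagrangian mode) must land within 0.5% of the
    reference minimum of mu*||s||_1 + 1/2*||M F s - b||_2^2.
    """
    n, n_frames, mu = 8, 4, 0.5
    ks, _ = _random_kspace(rng, n_frames=n_frames, n=n)
    pat = generate_candidate(n, n_frames, 2, seed=2)
    und = retrospective_undersample(ks, pat)
    avg = average_from_undersampled(und)

    W = _centered_unitary_dft(n)
    F2 = np.kron(W, W)  # acts on row-major flattened images
    b_all = pat.mask[:, :, None] * (und.samples - fft2c(avg)[None])
    ref_obj = 0.0
    for f in range(n_frames):
        sel = np.repeat(pat.mask[f].astype(bool), n)
        A = F2[sel]
        b = b_all[f].reshape(-1)[sel]
        step = 1.0 / np.linalg.norm(A, 2) ** 2
        s = np.zeros(n * n, complex)
        for _ in range(20000):
            g = A.conj().T @ (A @ s - b)
            u = s - step * g
            m = np.abs(u)
            s = u * np.maximum(m - mu * step, 0) / np.where(m > 0, m, 1)
        ref_obj += mu * np.abs(s).sum() + 0.5 * np.sum(np.abs(A @ s - b) ** 2)

    cfg = ReconConfig(outer_loops=1, final_dc=False, tol=1e-12, max_iters=5000)
    rec = cs_reconstruct(und, config=cfg)
    obj = cs_objective(und, pat, rec, mu, average=avg)
    assert obj <= ref_obj * 1.005
    assert obj >= ref_obj * 0.995


def test_sparse_dynamic_scene_recovered_at_r3():
    truth, _ = make_sparse_fixture(n=64, n_frames=20)
    ks = image_to_kspace(CineSeries(truth), noise_sd=0.0)
    pat = select_pattern(64, 20, 3, sigma=64.0, n_candidates=50, seed=11)
    rec = cs_reconstruct(retrospective_undersample(ks, pat))
    nrmse = np.linalg.norm(rec.frames - truth) / np.linalg.norm(truth)
    assert nrmse < 0.01


def test_noiseless_phantom_r1_pipeline_exact(tiny_phantom_spec):
    series, _ = generate_phantom(tiny_phantom_spec)
    ks = image_to_kspace(series[0], noise_sd=0.0)
    pat = generate_candidate(64, 10, 1, seed=0)
    rec = cs_reconstruct(retrospective_undersample(ks, pat))
    nrmse = np.linalg.norm(rec.frames - series[0].frames) / np.linalg.norm(series[0].frames)
    assert nrmse < 1e-3


def test_zerofill_identity_and_geometry(rng):
    series = CineSeries(
        rng.normal(size=(2, 16, 16)) + 0j, pixel_size_mm=0.1
    )
    assert np.array_equal(zerofill(series, 1).frames, series.frames)
    z = zerofill(series, 2)
    assert z.frames.shape == (2, 32, 32)
    assert z.pixel_size_mm == pytest.approx(0.05)


def test_zerofill_preserves_total_intensity(rng):
    k = fft2c(rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16)))
    img1 = ifft2c(k)
    img2 = ifft2c(zerofill(k, 2))
    assert img2.sum() == pytest.approx(img1.sum(), rel=1e-10)


def test_zerofill_rejects_bad_factor(rng):
    with pytest.raises(ValueError):
        zerofill(np.zeros((4, 4), complex), 0)


def test_butterworth_gain_properties():
    n, order, cutoff = 64, 3, 0.5
    k = np.ones((n, n), complex)
    filt = butterworth_filter(k, order=order, cutoff=cutoff)
    gain = np.abs(filt)
    c = n // 2
    assert gain[c, c] == pytest.approx(1.0)
    # half-power point: radius = cutoff * Nyquist -> gain 1/sqrt(2)
    assert gain[c, c + int(cutoff * c)] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
    radial = gain[c, c:]
    assert (np.diff(radial) <= 1e-15).all()


@pytest.mark.parametrize("order", [1, 3, 5])
def test_butterworth_half_power_independent_of_order(order):
    k = np.ones((32, 32), complex)
    gain = np.abs(butterworth_filter(k, order=order, cutoff=0.25))
    assert gain[16, 16 + 4] == pytest.approx(1 / np.sqrt(2), rel=1e-12)


def test_export_magnitude_roundtrip(tmp_path, rng):
    frames = rng.normal(size=(5, 16, 16)) + 1j * rng.normal(size=(5, 16, 16))
    series = CineSeries(frames)
    path = tmp_path / "mag.tif"
    scale = export_magnitude(series, path)
    with tifffile.TiffFile(path) as tf:
        assert len(tf.pages) == 5
        desc = json.loads(tf.pages[0].description)
        data = tf.asarray()
    assert desc["scale_to_uint16"] == scale
    assert (data >= 0).all()
    np.testing.assert_allclose(
        data / scale, np.abs(frames), atol=1.0 / scale
    )
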