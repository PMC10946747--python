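"""Phantom anatomy, tissue parameters, coils, signal model and noise."""

import numpy as np
import pytest

import radstar.phantom as ph
import radstar.trajectory as tj

from conftest import flood_fill_components


def test_anatomy_deterministic_and_complete():
    a = ph.make_anatomy(256, 7)
    b = ph.make_anatomy(256, 7)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert set(np.unique(a.labels)) == {0, 1, 2, 3, 4}
    assert np.mean(a.labels > 0) >= 0.20
    assert ph.make_anatomy(256, 8).labels.tolist() != a.labels.tolist()


def test_anatomy_regions_connected_small_grid():
    """Each tissue forms a single 4-connected region, even at 32x32."""
    a = ph.make_anatomy(32, 1)
    for label in (1, 2, 3, 4):
        mask = a.labels == label
        assert mask.any(), f"label {label} missing at 32x32"
        assert flood_fill_components(mask) == 1, f"label {label} fragmented"


def test_anatomy_rejects_tiny_grid():
    with pytest.raises(ValueError):
        ph.make_anatomy(16, 0)


def test_tissue_parameters():
    p = ph.assign_tissue_params(ph.make_anatomy(64, 3))
    assert np.all(p.t2star_ms[p.labels == ph.LABEL_GM] == 84.0)
    assert np.all(p.t2star_ms[p.labels == ph.LABEL_WM] == 66.0)
    assert np.all(p.t2star_ms[p.labels == ph.LABEL_CSF] == 2000.0)
    assert np.all(p.m0[p.labels > 0] == 100.0)
    assert np.all(p.m0[p.labels == 0] == 0.0)
    # tissue homogeneity: zero variance within each label
    for label in (1, 2, 3, 4):
        assert np.var(p.t2star_ms[p.labels == label]) == 0.0


def test_unknown_label_rejected():
    a = ph.make_anatomy(32, 0)
    a.labels[0, 0] = 9
    with pytest.raises(ValueError, match="unknown label"):
        ph.assign_tissue_params(a)


def test_multiecho_signal_model():
    p = ph.assign_tissue_params(ph.make_anatomy(64, 2))
    te = [0.0, 5.0, 20.0, 40.0]
    x = ph.simulate_multiecho_images(p, te)
    # TE = 0 -> image equals M0
    np.testing.assert_array_equal(x.images[0].real, p.m0)
    # closed-form checks at representative tissues
    gm = p.labels == ph.LABEL_GM
    np.testing.assert_allclose(
        x.images[1].real[gm], 100 * np.exp(-5 / 84), rtol=1e-12
    )
    csf = p.labels == ph.LABEL_CSF
    np.testing.assert_allclose(
        x.images[3].real[csf], 100 * np.exp(-40 / 2000), rtol=1e-12
    )
    # exact pixelwise model, zero phase
    with np.errstate(divide="ignore"):
        expected = p.m0[None] * np.exp(
            -np.asarray(te)[:, None, None]
            / np.where(p.t2star_ms > 0, p.t2star_ms, np.inf)
        )
    np.testing.assert_array_equal(x.images.real, expected)
    assert np.all(x.images.imag == 0)
    # magnitudes strictly decreasing across echoes on tissue (TE increasing)
    tissue = p.labels > 0
    mags = np.abs(x.images)[1:, tissue]
    assert np.all(np.diff(mags, axis=0) < 0)


def test_negative_echo_time_rejected():
    p = ph.assign_tissue_params(ph.make_anatomy(32, 0))
    with pytest.raises(ValueError):
        ph.simulate_multiecho_images(p, [-1.0, 5.0])


def test_coil_maps_cover_and_are_smooth():
    sens = ph.simulate_coils(8, 128)
    assert sens.maps.shape == (8, 128, 128)
    # positive root-sum-of-squares over a centered disc of radius 0.45 N
    c = np.arange(128) - 64
    xx, yy = np.meshgrid(c, c, indexing="ij")
    disc = np.hypot(xx, yy) < 0.45 * 128
    assert np.all(sens.rss()[disc] > 0)
    # band-limited: energy above 8 cycles/FOV below 1% per coil; a Hann
    # window separates genuine spectral content from periodization leakage
    w = np.hanning(128)
    window = np.outer(w, w)
    r = np.hypot(xx, yy)
    for m in sens.maps:
        spec = np.abs(np.fft.fftshift(np.fft.fft2(m * window))) ** 2
        assert spec[r > 8].sum() / spec.sum() < 0.01
    # uniform option: ideal all-ones coil
    uni = ph.simulate_coils(1, 32, uniform=True)
    np.testing.assert_array_equal(uni.maps, np.ones((1, 32, 32)))


def test_noise_level_zero_is_identity_and_std_scales():
    p = ph.assign_tissue_params(ph.make_anatomy(64, 1))
    traj = tj.golden_angle_spokes(100, 128, 64, 2)
    cfg = ph.PhantomConfig(
        noise_level=0, seed=0, echo_times_ms=(5.0, 10.0), grid_size=64, n_coils=4
    )
    ks, *_ = ph.simulate_acquisition(cfg, traj, phantom=p)
    same = ph.add_noise(ks, 0.0, seed=3)
    np.testing.assert_array_equal(same.samples, ks.samples)

    noisy = ph.add_noise(ks, 0.5, seed=3)
    sigma_expected = 0.5 * np.mean(np.abs(ks.samples[0])) / 100.0
    delta = noisy.samples - ks.samples
    assert delta.size >= 1e5
    for comp in (delta.real, delta.imag):
        assert abs(np.std(comp) / sigma_expected - 1) < 0.02
    # determinism by seed
    again = ph.add_noise(ks, 0.5, seed=3)
    np.testing.assert_array_equal(noisy.samples, again.samples)


@pytest.mark.parametrize("level", [0.0, 0.1, 0.5, 1.0])
def test_study_noise_grid_accepted(level):
    ph.PhantomConfig(noise_level=level, seed=0)
    with pytest.raises(ValueError):
        ph.PhantomConfig(noise_level=-0.1, seed=0)
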