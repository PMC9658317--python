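"""CiSSA: weighted autocovariances, circulant spectrum, RC decomposition,
sub-band extraction, and the periodogram diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cissacsp as cc
from cissacsp.cissa import SubBandPlan


def dense_circulant(c):
    """Explicit circulant matrix with first row c0, c1, ..., c_{L-1}."""
    L = len(c)
    return np.array([np.roll(c, i) for i in range(L)])


# ---------------------------------------------------------------------------
# weighted autocovariance
# ---------------------------------------------------------------------------

def test_weighted_autocovariance_hand_values():
    c = cc.weighted_autocovariance([1.0, 2.0, 3.0, 4.0], 2)
    np.testing.assert_allclose(c, [7.5, 20.0 / 3.0])
    np.testing.assert_allclose(cc.weighted_autocovariance([1.0, 1.0, 1.0, 1.0], 2), [1.0, 1.0])
    assert cc.weighted_autocovariance(np.zeros(10), 4).tolist() == [0.0] * 4


def test_weighted_autocovariance_rejects_long_window():
    with pytest.raises(ValueError, match="L"):
        cc.weighted_autocovariance(np.ones(4), 4)


# ---------------------------------------------------------------------------
# circulant spectrum
# ---------------------------------------------------------------------------

def test_identity_circulant_has_unit_eigenvalues():
    model = cc.circulant_spectrum(np.r_[1.0, np.zeros(7)], 100.0)
    np.testing.assert_allclose(model.lam, np.ones(8))


def test_two_by_two_eigenvalues_match_dense_solve():
    model = cc.circulant_spectrum([7.5, 20.0 / 3.0], 100.0)
    np.testing.assert_allclose(np.sort(model.lam), np.sort(np.linalg.eigvalsh(
        np.array([[7.5, 20 / 3], [20 / 3, 7.5]]))), rtol=1e-12)


def test_frequency_map():
    s = np.random.default_rng(0).standard_normal(300)
    model = cc.circulant_spectrum(cc.weighted_autocovariance(s, 25), 100.0)
    assert model.f[0] == 0.0
    assert model.f[2] == pytest.approx(8.0)  # third eigendirection at 8 Hz
    assert np.all(np.diff(model.f) > 0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16), L=st.integers(2, 32))
def test_circulant_eigen_oracle_and_fourier_eigenvectors(seed, L):
    """Dense eigensolve of the explicit circulant matrix agrees with the DFT
    route, and the unit Fourier vectors are eigenvectors."""
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(4 * L + 7)
    c = cc.weighted_autocovariance(s, L)
    model = cc.circulant_spectrum(c, 100.0)
    CL = dense_circulant(c)
    scale = max(1.0, np.abs(model.lam).max())
    np.testing.assert_allclose(
        np.sort(model.lam), np.sort(np.linalg.eigvalsh(CL)), atol=1e-8 * scale
    )
    j = np.arange(L)
    for k in (0, 1, L // 2):
        u = np.exp(-2j * np.pi * j * k / L) / np.sqrt(L)
        np.testing.assert_allclose(CL @ u, model.lam[k] * u, atol=1e-8 * scale)
    # conjugate symmetry lam_k = lam_{L-k}
    np.testing.assert_allclose(model.lam[1:], model.lam[1:][::-1], atol=1e-8 * scale)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def test_decompose_zero_input_gives_zero_rcs():
    for _, rc in cc.decompose(np.zeros(50), 10, 100.0):
        assert np.all(rc == 0)


def test_decompose_completeness_random_series():
    rng = np.random.default_rng(5)
    for _ in range(5):
        s = rng.standard_normal(rng.integers(40, 300))
        L = int(rng.integers(2, min(40, s.size - 1)))
        rcs = cc.decompose(s, L, 100.0)
        total = np.sum([rc for _, rc in rcs], axis=0)
        np.testing.assert_allclose(total, s, atol=1e-9 * np.abs(s).max())


def test_decompose_is_linear():
    rng = np.random.default_rng(6)
    s1, s2 = rng.standard_normal((2, 200))
    a, b = 2.5, -1.25
    combo = cc.decompose(a * s1 + b * s2, 20, 100.0)
    d1, d2 = cc.decompose(s1, 20, 100.0), cc.decompose(s2, 20, 100.0)
    for (f, rc), (_, rc1), (_, rc2) in zip(combo, d1, d2):
        np.testing.assert_allclose(rc, a * rc1 + b * rc2, atol=1e-9)


def test_pure_tone_concentrates_at_its_rc():
    t = np.arange(350) / 100.0
    rcs = cc.decompose(np.cos(2 * np.pi * 8 * t), 25, 100.0)
    energies = {f: np.sum(rc**2) for f, rc in rcs}
    assert energies[8.0] / sum(energies.values()) >= 0.99


# ---------------------------------------------------------------------------
# sub-band plans and band extraction
# ---------------------------------------------------------------------------

def test_subband_plan_printed_edges():
    plan = cc.make_subband_plan(6, 30, 4, 100.0, 25)
    assert plan.bands == [(6, 10), (10, 14), (14, 18), (18, 22), (22, 26), (26, 30)]
    assert plan.fb == 4.0


def test_subband_plan_single_band_and_errors():
    assert cc.make_subband_plan(6, 10, 4, 100.0, 25).B == 1
    with pytest.raises(ValueError, match="not divisible"):
        cc.make_subband_plan(6, 31, 4, 100.0, 25)
    with pytest.raises(ValueError, match="fs/L"):
        cc.make_subband_plan(6, 30, 4, 100.0, 20)


def test_two_tone_separation():
    t = np.arange(350) / 100.0
    tone8, tone20 = np.cos(2 * np.pi * 8 * t), np.cos(2 * np.pi * 20 * t)
    plan = cc.make_subband_plan(6, 30, 4, 100.0, 25)
    dec = cc.extract_subbands(tone8 + tone20, plan, 25, 100.0)
    assert np.corrcoef(dec.bands[0], tone8)[0, 1] >= 0.99
    assert np.corrcoef(dec.bands[3], tone20)[0, 1] >= 0.99


def test_band_without_rc_center_is_zero():
    plan = SubBandPlan(bands=[(1.0, 3.0)], fb=2.0)  # no RC centre in [1, 3) Hz
    s = np.random.default_rng(0).standard_normal(200)
    dec = cc.extract_subbands(s, plan, 25, 100.0)
    assert np.all(dec.bands[0] == 0)
    np.testing.assert_allclose(dec.bands[0] + dec.residual, s, atol=1e-9)


def test_band_completeness_on_noise():
    rng = np.random.default_rng(1)
    s = rng.standard_normal(350)
    plan = cc.make_subband_plan(6, 30, 4, 100.0, 25)
    dec = cc.extract_subbands(s, plan, 25, 100.0)
    total = np.sum(dec.bands, axis=0) + dec.residual
    np.testing.assert_allclose(total, s, atol=1e-9 * np.abs(s).max())


def test_band_energy_leakage_documented():
    """Tone at an RC frequency leaks <=1%; a tone on the band edge (midway
    between RC centres) splits between the two adjacent bands."""
    t = np.arange(350) / 100.0
    plan = cc.make_subband_plan(6, 30, 4, 100.0, 25)

    dec = cc.extract_subbands(np.cos(2 * np.pi * 8 * t), plan, 25, 100.0)
    energies = np.array([np.sum(b**2) for b in dec.bands])
    total = energies.sum() + np.sum(dec.residual**2)
    assert 1 - energies[0] / total <= 0.01

    dec = cc.extract_subbands(np.cos(2 * np.pi * 10 * t), plan, 25, 100.0)
    energies = np.array([np.sum(b**2) for b in dec.bands])
    total = energies.sum() + np.sum(dec.residual**2)
    for frac in (energies[0] / total, energies[1] / total):
        assert 0.35 <= frac <= 0.65
    assert (energies[0] + energies[1]) / total >= 0.90


def test_batch_band_filter_matches_single_series():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((3, 2, 200))
    plan = cc.make_subband_plan(6, 30, 4, 100.0, 25)
    batch = cc.band_filter(x, plan, 25, 100.0)
    single = cc.extract_subbands(x[1, 0], plan, 25, 100.0)
    for b in range(plan.B):
        np.testing.assert_allclose(batch[b, 1, 0], single.bands[b], atol=1e-12)


# ---------------------------------------------------------------------------
# periodogram diagnostic
# ---------------------------------------------------------------------------

def test_periodogram_peak_and_parseval():
    rng = np.random.default_rng(3)
    t = np.arange(350) / 100.0
    f, p = cc.periodogram_psd(np.sin(2 * np.pi * 8 * t), 100.0)
    assert f[np.argmax(p)] == pytest.approx(8.0, abs=f[1] - f[0])

    s = rng.standard_normal(333)
    f, p = cc.periodogram_psd(s, 100.0)
    df = f[1] - f[0]
    assert np.sum(p) * df == pytest.approx(np.mean(s**2), rel=1e-6)


def test_periodogram_white_noise_is_flat_on_average():
    rng = np.random.default_rng(4)
    spectra = []
    for _ in range(50):
        _, p = cc.periodogram_psd(rng.standard_normal(256), 100.0)
        spectra.append(p[1:-1])  # drop DC / Nyquist half-bins
    mean = np.mean(spectra, axis=0)
    bins = np.array_split(mean, 10)
    avgs = np.array([b.mean() for b in bins])
    assert avgs.max() / avgs.min() < 1.5
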