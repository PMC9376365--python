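import numpy as np
import pandas as pd
import pytest

from alphaconn.connectivity import (
    NuisanceDesign,
    acompcor,
    build_nuisance,
    connectivity,
    denoise,
    framewise_displacement,
    motion_expand,
    scrub_mask,
    session_connectivity,
)
from alphaconn.cohort import SubjectSpec
from alphaconn.synth_bold import BOLDGenParams, synth_bold


def subj(sid="e4m001"):
    return SubjectSpec(sid, 55.0, "W", "E4minus", true_iapf=10.0)


# ---------------------------------------------------------------- motion
def test_motion_expand_shape_and_content():
    rng = np.random.default_rng(0)
    m = rng.standard_normal((50, 6))
    out = motion_expand(m)
    assert out.shape == (50, 24)
    np.testing.assert_array_equal(out[:, :6], m)
    np.testing.assert_array_equal(out[:, 12:18], out[:, :6] ** 2)
    assert (motion_expand(np.zeros((10, 6))) == 0).all()


def test_motion_expand_ramp_derivative_constant():
    m = np.zeros((20, 6))
    m[:, 0] = np.arange(20) * 0.5  # linear drift in x
    out = motion_expand(m)
    deriv = out[:, 6]
    assert deriv[0] == 0
    assert np.allclose(deriv[1:], 0.5)


def test_motion_expand_rejects_wrong_shape():
    with pytest.raises(ValueError):
        motion_expand(np.zeros((10, 5)))


# ---------------------------------------------------------------- FD / scrub
def test_fd_formula():
    m = np.zeros((10, 6))
    assert (framewise_displacement(m) == 0).all()
    m[5, 0] = 1.0  # 1 mm jump in, then out
    fd = framewise_displacement(m)
    assert fd[5] == pytest.approx(1.0)
    assert fd[6] == pytest.approx(1.0)
    m2 = np.zeros((10, 6))
    m2[5, 3] = 0.01  # 0.01 rad rotation at 50 mm radius
    assert framewise_displacement(m2)[5] == pytest.approx(0.5)


def test_scrub_at_97th_percentile():
    fd = np.arange(100, dtype=float)  # 100 distinct values
    censored, spikes = scrub_mask(fd)
    assert censored.sum() == 3
    assert spikes.shape == (100, 3)
    assert spikes.sum(axis=0).tolist() == [1, 1, 1]


def test_scrub_constant_fd_censors_nothing():
    censored, spikes = scrub_mask(np.ones(50))
    assert censored.sum() == 0
    assert spikes.shape == (50, 0)


def test_scrub_percentile_zero():
    fd = np.array([0.0, 1.0, 1.0, 2.0])
    censored, _ = scrub_mask(fd, percentile=0)
    assert censored.tolist() == [False, True, True, True]


# ---------------------------------------------------------------- aCompCor
def test_acompcor_counts_and_rank():
    rng = np.random.default_rng(1)
    t = 100
    # rank-2 WM block: 2 components explain everything
    basis = rng.standard_normal((t, 2))
    wm = basis @ rng.standard_normal((2, 6))
    csf = rng.standard_normal((t, 7))
    comps = acompcor({"wm": wm, "csf": csf}, k_per_tissue=2)
    assert comps.shape == (t, 4)
    resid = wm - wm.mean(0) - comps[:, :2] @ np.linalg.lstsq(
        comps[:, :2], wm - wm.mean(0), rcond=None)[0]
    assert np.abs(resid).max() < 1e-9

    noise = pd.DataFrame(
        np.hstack([rng.standard_normal((t, 8)), rng.standard_normal((t, 8))]),
        columns=[f"WM{i}" for i in range(8)] + [f"CSF{i}" for i in range(8)],
    )
    assert acompcor(noise, k_per_tissue=5).shape == (t, 10)


def test_acompcor_sign_flip_irrelevant_for_residualization():
    rng = np.random.default_rng(2)
    t = 80
    comps = acompcor({"wm": rng.standard_normal((t, 6))}, k_per_tissue=3)
    y = rng.standard_normal((t, 2))
    design_a = NuisanceDesign(comps, [f"c{i}" for i in range(3)])
    design_b = NuisanceDesign(comps * np.array([-1, 1, -1]), [f"c{i}" for i in range(3)])
    ra = denoise(y, design_a, band=None)
    rb = denoise(y, design_b, band=None)
    np.testing.assert_allclose(ra.to_numpy(), rb.to_numpy(), atol=1e-10)


def test_acompcor_zero_variance_block_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        acompcor({"wm": np.ones((50, 5))}, k_per_tissue=2)


# ---------------------------------------------------------------- denoise
def test_exact_linear_combination_gives_zero_residual():
    rng = np.random.default_rng(3)
    cols = rng.standard_normal((100, 4))
    design = NuisanceDesign(cols, [f"c{i}" for i in range(4)])
    y = cols @ rng.standard_normal(4) + 2.5
    resid = denoise(y[:, None], design, band=None)
    assert np.abs(resid.to_numpy()).max() < 1e-9


def test_residuals_orthogonal_to_design(bold_params):
    sess = synth_bold(subj(), bold_params)
    design = build_nuisance(sess)
    resid = denoise(sess.roi, design, band=None).to_numpy()
    for j in range(design.columns.shape[1]):
        col = design.columns[:, j]
        for k in range(resid.shape[1]):
            r = np.corrcoef(col, resid[:, k])[0, 1]
            assert abs(r) < 1e-10


def test_bandpass_attenuates_out_of_band_tone():
    n = 1200
    t = np.arange(n) * 1.5
    y = np.sin(2 * np.pi * 0.2 * t)[:, None]
    design = NuisanceDesign(np.zeros((n, 0)), [])
    out = denoise(y, design, band=(0.01, 0.1), tr=1.5).to_numpy()
    # steady-state response: central segment, clear of filtfilt edge transients
    mid = slice(n // 4, 3 * n // 4)
    attenuation_db = 20 * np.log10(
        np.sqrt((y[mid] ** 2).mean()) / np.sqrt((out[mid] ** 2).mean())
    )
    assert attenuation_db >= 20


def test_denoising_recovers_planted_coupling_better_than_raw():
    params = BOLDGenParams(seed=11, nuisance_amp=1.5)
    truth_err_raw, truth_err_den = [], []
    for i in range(5):
        sess = synth_bold(subj(f"e4m{i + 1:03d}"), params)
        truth = sess.truth["coupling"].to_numpy()
        iu = np.triu_indices(truth.shape[0], 1)
        raw = np.corrcoef(sess.roi.to_numpy(), rowvar=False)
        conn, _ = session_connectivity(sess)
        den = np.tanh(conn.z.to_numpy())
        truth_err_raw.append(np.sqrt(((raw[iu] - truth[iu]) ** 2).mean()))
        truth_err_den.append(np.sqrt(((den[iu] - truth[iu]) ** 2).mean()))
    assert np.mean(truth_err_den) < np.mean(truth_err_raw)


# ---------------------------------------------------------------- connectivity
def test_fisher_z_values_and_symmetry():
    rng = np.random.default_rng(4)
    y = rng.standard_normal((200, 4))
    conn = connectivity(y, labels=list("abcd"))
    z = conn.z.to_numpy()
    r = np.corrcoef(y, rowvar=False)
    iu = np.triu_indices(4, 1)
    np.testing.assert_allclose(z[iu], np.arctanh(r[iu]), atol=1e-12)
    np.testing.assert_allclose(z, z.T, atol=0, equal_nan=True)


def test_identical_rois_capped_and_flagged():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(100)
    y = np.column_stack([x, x, rng.standard_normal(100)])
    conn = connectivity(y, labels=["a", "a2", "b"])
    assert conn.z.loc["a", "a2"] == 6.0
    assert conn.capped.loc["a", "a2"]


def test_zero_variance_roi_flagged_undefined():
    rng = np.random.default_rng(6)
    y = np.column_stack([np.ones(100), rng.standard_normal(100)])
    conn = connectivity(y, labels=["flat", "b"])
    assert np.isnan(conn.z.loc["flat", "b"])
    assert not conn.defined.loc["flat", "b"]


def test_too_few_volumes_rejected():
    with pytest.raises(ValueError):
        connectivity(np.random.default_rng(0).standard_normal((20, 3)))


def test_censored_volumes_have_zero_leverage(bold_params):
    sess = synth_bold(subj(), bold_params)
    conn_a, design = session_connectivity(sess)
    assert design.censored.sum() > 0
    # corrupt every censored volume's ROI values
    sess.roi.iloc[np.flatnonzero(design.censored)] = 999.0
    conn_b, _ = session_connectivity(sess)
    pd.testing.assert_frame_equal(conn_a.z, conn_b.z)


def test_null_z_calibration():
    """Edge z on coupling-free sessions: mean ~0, variance ~1/(n-3)."""
    rng = np.random.default_rng(7)
    t = 120
    zs = []
    for _ in range(200):
        y = rng.standard_normal((t, 6))
        zs.append(connectivity(y).z.to_numpy()[np.triu_indices(6, 1)])
    zs = np.concatenate(zs)
    expected_var = 1.0 / (t - 3)
    assert abs(zs.mean()) < 3 * np.sqrt(expected_var / len(zs))
    assert abs(zs.var() / expected_var - 1) < 0.10
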