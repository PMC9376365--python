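"""ROI-to-ROI resting-state connectivity with CONN-style denoising.

The nuisance model per session comprises 24 head-motion parameters (the six
realignment parameters, their backward-difference temporal derivatives and
the squares of those twelve), ten aCompCor principal-component time courses
(five from white matter, five from CSF) and one spike regressor per censored
volume (volumes whose framewise displacement exceeds the within-session 97th
percentile).  ROI series are residualized on this design plus an intercept,
band-pass filtered to 0.01-0.1 Hz (zero-phase Butterworth order 2), and
pairwise Pearson-correlated over the uncensored volumes; correlations are
Fisher-transformed (z = atanh r, capped at +/-6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from alphaconn.synth_bold import ROISession

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.01, 0.1)
Z_CAP = 6.0
FD_PERCENTILE = 97.0
HEAD_RADIUS_MM = 50.0


def motion_expand(motion6: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Expand 6 realignment parameters to the 24-parameter motion model.

    Columns: the 6 parameters, their backward-difference derivatives (first
    row zero), and the squares of those 12.
    """
    arr = np.asarray(motion6, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected a volumes x 6 motion block, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    deriv = np.zeros_like(arr)
    deriv[1:] = np.diff(arr, axis=0)
    block12 = np.hstack([arr, deriv])
    return np.hstack([block12, block12**2])


def framewise_displacement(
    motion6: np.ndarray | pd.DataFrame, head_radius: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style FD: sum of |backward differences|, rotations scaled to mm.

    ``FD(t) = sum|d trans| + head_radius * sum|d rot|``; ``FD(0) = 0``.
    Rotations are assumed in radians, translations in mm.
    """
    arr = np.asarray(motion6, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected a volumes x 6 motion block, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(arr, axis=0))
    fd = np.zeros(arr.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd


def scrub_mask(fd: np.ndarray, percentile: float = FD_PERCENTILE) -> tuple[np.ndarray, np.ndarray]:
    """Censor volumes whose FD strictly exceeds the within-session percentile.

    Returns ``(censored, spikes)``: a boolean mask and one indicator column
    per censored volume (spike regressors, so filtering stays on a regular
    temporal grid instead of deleting rows).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    threshold = np.percentile(fd, percentile)
    censored = fd > threshold
    idx = np.flatnonzero(censored)
    spikes = np.zeros((fd.size, idx.size))
    spikes[idx, np.arange(idx.size)] = 1.0
    return censored, spikes


def acompcor(
    noise_series: pd.DataFrame | dict[str, np.ndarray], k_per_tissue: int = 5
) -> np.ndarray:
    """aCompCor: top-k principal component time courses per tissue.

    ``noise_series`` is either a DataFrame whose columns are prefixed ``WM``
    / ``CSF`` or a mapping tissue name -> volumes x voxels array.  Components
    are computed on the column-centred block, scaled to unit variance and
    ordered by explained variance; the per-tissue blocks are concatenated.
    """
    if isinstance(noise_series, pd.DataFrame):
        tissues = {}
        for prefix in ("WM", "CSF"):
            cols = [c for c in noise_series.columns if c.upper().startswith(prefix)]
            if cols:
                tissues[prefix.lower()] = noise_series[cols].to_numpy(dtype=float)
        if not tissues:
            raise ValueError("no WM/CSF-prefixed columns in noise series")
    else:
        tissues = {k: np.asarray(v, dtype=float) for k, v in noise_series.items()}

    blocks = []
    for name, block in tissues.items():
        t = block.shape[0]
        if t <= k_per_tissue:
            raise ValueError(f"{name}: need more volumes than components ({t} <= {k_per_tissue})")
        centred = block - block.mean(axis=0)
        if np.allclose(centred, 0):
            raise ValueError(f"{name}: zero-variance tissue block")
        # left singular vectors = PC time courses, ordered by singular value
        u, s, _ = np.linalg.svd(centred, full_matrices=False)
        k = min(k_per_tissue, (s > 1e-12 * s[0]).sum())
        comps = u[:, :k]
        comps = comps / comps.std(axis=0)
        if k < k_per_tissue:  # degenerate rank: pad nothing, keep what exists
            logger.warning("%s: only %d non-null components available", name, k)
        blocks.append(comps)
    return np.hstack(blocks)


@dataclass
class NuisanceDesign:
    """Session-level nuisance regressor block."""

    columns: np.ndarray  # volumes x k
    names: list[str]
    censored: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        if self.columns.shape[1] != len(self.names):
            raise ValueError("one name per design column required")
        if self.censored.size == 0:
            self.censored = np.zeros(self.columns.shape[0], dtype=bool)


def build_nuisance(
    session: ROISession,
    k_per_tissue: int = 5,
    fd_percentile: float = FD_PERCENTILE,
    head_radius: float = HEAD_RADIUS_MM,
) -> NuisanceDesign:
    """Assemble the full design: 24 motion + 2k aCompCor + spike columns."""
    motion24 = motion_expand(session.motion)
    motion_names = [f"motion{i + 1}" for i in range(24)]
    comp = acompcor(session.noise, k_per_tissue)
    comp_names = [f"acompcor{i + 1}" for i in range(comp.shape[1])]
    fd = framewise_displacement(session.motion, head_radius)
    censored, spikes = scrub_mask(fd, fd_percentile)
    spike_names = [f"spike{v + 1}" for v in np.flatnonzero(censored)]
    columns = np.hstack([motion24, comp, spikes])
    names = motion_names + comp_names + spike_names
    # constant or duplicated columns carry no information and break rank checks
    keep, seen = [], set()
    for j in range(columns.shape[1]):
        col = columns[:, j]
        if np.ptp(col) == 0:
            logger.warning("dropping constant nuisance column %s", names[j])
            continue
        sig = col.tobytes()
        if sig in seen:
            logger.warning("dropping duplicate nuisance column %s", names[j])
            continue
        seen.add(sig)
        keep.append(j)
    return NuisanceDesign(columns[:, keep], [names[j] for j in keep], censored)


def denoise(
    roi_series: pd.DataFrame | np.ndarray,
    design: NuisanceDesign,
    band: tuple[float, float] | None = DEFAULT_BAND,
    tr: float = 1.5,
) -> pd.DataFrame:
    """Residualize ROI series on the nuisance design, then band-pass filter.

    Residuals are exactly orthogonal to every design column before filtering.
    ``band=None`` skips the filter.  A rank-deficient design is handled by the
    least-squares pseudoinverse with a logged warning.
    """
    roi = pd.DataFrame(roi_series).copy()
    y = roi.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(y)), design.columns])
    if x.shape[0] != y.shape[0]:
        raise ValueError("design rows must equal ROI volumes")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        logger.warning("rank-deficient nuisance design (rank %d of %d)", rank, x.shape[1])
    resid = y - x @ beta
    # one step of iterative refinement: the 24-parameter motion block (raw,
    # derivative and squared terms) is ill-conditioned enough that a single
    # projection can leave residual correlations near 1e-10
    resid -= x @ np.linalg.lstsq(x, resid, rcond=None)[0]
    if band is not None:
        nyq = 1.0 / (2.0 * tr)
        low, high = band
        if not 0 < low < high < nyq:
            raise ValueError(f"band {band} invalid for TR {tr} s (Nyquist {nyq:.3f} Hz)")
        sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
        resid = signal.sosfiltfilt(sos, resid, axis=0)
    return pd.DataFrame(resid, columns=roi.columns, index=roi.index)


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z ROI x ROI connectivity with validity flags."""

    z: pd.DataFrame
    defined: pd.DataFrame  # False where an ROI had zero variance
    capped: pd.DataFrame  # True where |atanh r| was clipped to the cap
    n_usable: int

    @property
    def labels(self) -> list[str]:
        return list(self.z.columns)

    def to_edges(self) -> pd.DataFrame:
        """Long-format upper-triangle edge table (roi_i, roi_j, z)."""
        labels = self.labels
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rows.append(
                    {
                        "roi_i": labels[i],
                        "roi_j": labels[j],
                        "z": self.z.iloc[i, j],
                        "defined": bool(self.defined.iloc[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def connectivity(
    denoised: pd.DataFrame | np.ndarray,
    censored: np.ndarray | None = None,
    labels: list[str] | None = None,
    z_cap: float = Z_CAP,
    min_volumes: int = 30,
) -> ConnectivityMatrix:
    """Pairwise Pearson r over uncensored volumes, Fisher-transformed.

    ``z = atanh(r)`` capped at ``+/-z_cap``; zero-variance ROIs yield
    undefined (NaN) entries flagged in ``defined``.
    """
    df = pd.DataFrame(denoised)
    if labels is not None:
        df.columns = labels
    y = df.to_numpy(dtype=float)
    if censored is not None:
        y = y[~np.asarray(censored, dtype=bool)]
    n = y.shape[0]
    if n < min_volumes:
        raise ValueError(f"only {n} usable volumes (< {min_volumes})")
    sd = y.std(axis=0)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    near_one = np.abs(r) >= 1.0 - 1e-15
    z = np.empty_like(r)
    valid = ~np.isnan(r)
    z[~valid] = np.nan
    z[valid & ~near_one] = np.arctanh(r[valid & ~near_one])
    z[valid & near_one] = np.sign(r[valid & near_one]) * z_cap
    capped = np.zeros_like(r, dtype=bool)
    capped[valid] = np.abs(z[valid]) >= z_cap
    z = np.clip(z, -z_cap, z_cap)
    np.fill_diagonal(z, np.nan)
    cols = list(df.columns)
    return ConnectivityMatrix(
        z=pd.DataFrame(z, index=cols, columns=cols),
        defined=pd.DataFrame(valid, index=cols, columns=cols),
        capped=pd.DataFrame(capped, index=cols, columns=cols),
        n_usable=n,
    )


def session_connectivity(
    session: ROISession,
    k_per_tissue: int = 5,
    band: tuple[float, float] | None = DEFAULT_BAND,
    fd_percentile: float = FD_PERCENTILE,
) -> tuple[ConnectivityMatrix, NuisanceDesign]:
    """Full per-session chain: nuisance design -> denoise -> connectivity."""
    design = build_nuisance(session, k_per_tissue, fd_percentile)
    resid = denoise(session.roi, design, band=band, tr=session.tr)
    conn = connectivity(resid, censored=design.censored)
    return conn, design
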