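"""Synthetic ROI BOLD sessions with genotype-dependent planted couplings.

ROI series are drawn from a multivariate normal whose correlation matrix is
``I + C(genotype)``, where ``C`` is a sparse, symmetric coupling matrix.  The
default couplings plant positive interhemispheric visual/parietal/salience
edges in epsilon-4 carriers and a negative left-hippocampus - right-posterior-
parietal edge in non-carriers only, matching the sign structure the group
contrasts are meant to recover.  Shared low-frequency nuisance components
contaminate both the ROI and the noise-ROI (WM/CSF) series, and a bounded
random-walk motion trace leaks into the ROI signal — this is what aCompCor and
motion regression have to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from alphaconn.cohort import E4MINUS, E4PLUS, SubjectSpec, subject_rng

#: ROI set covering the edges named by the group contrasts
DEFAULT_ROI_LABELS = [
    "Hippocampus l", "PPC r", "VisLat r", "PO l", "PO r", "PP l",
    "iLOC r", "Salience SMG r", "aPaHC l", "LPFC l", "SFG r",
    "Amygdala l", "aITG l", "aITG r", "SubCalC", "MidFG r",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _coupling_frame(labels: list[str], edges: dict[tuple[str, str], float]) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in edges.items():
        if a not in labels or b not in labels:
            raise KeyError(f"edge ({a}, {b}) not in ROI labels")
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def default_couplings(labels: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Genotype-keyed coupling matrices with the default planted edges."""
    labels = labels or list(DEFAULT_ROI_LABELS)
    e4plus_edges = {
        ("aITG r", "SubCalC"): 0.22,
        ("iLOC r", "PO l"): 0.25,
        ("iLOC r", "PP l"): 0.21,
        ("VisLat r", "PO r"): 0.26,
        ("VisLat r", "PO l"): 0.29,
        ("VisLat r", "Salience SMG r"): 0.28,
        ("aPaHC l", "LPFC l"): 0.20,
        ("Hippocampus l", "PPC r"): 0.0,
    }
    e4minus_edges = {
        ("Hippocampus l", "PPC r"): -0.25,
        ("aPaHC l", "SFG r"): -0.24,
        ("aPaHC l", "MidFG r"): -0.20,
        ("SFG r", "Amygdala l"): -0.17,
    }
    return {
        E4PLUS: _coupling_frame(labels, e4plus_edges),
        E4MINUS: _coupling_frame(labels, e4minus_edges),
    }


@dataclass
class BOLDGenParams:
    """Generative parameters for ROI BOLD sessions.

    ``coupling_by_genotype`` maps genotype to a symmetric zero-diagonal matrix
    of planted correlations; ``nuisance_amp`` scales the shared physiological
    components and ``motion_leak`` the motion bleed-through into ROI series.
    """

    tr: float = 1.5
    n_volumes: int = 400
    roi_labels: list[str] = field(default_factory=lambda: list(DEFAULT_ROI_LABELS))
    noise_roi_counts: dict[str, int] = field(default_factory=lambda: {"wm": 8, "csf": 8})
    coupling_by_genotype: dict[str, pd.DataFrame] | None = None
    n_nuisance_components: int = 3
    nuisance_amp: float = 0.8
    nuisance_smooth_vol: float = 8.0  # Gaussian kernel width of components, volumes
    motion_scale: float = 0.02  # mm innovation SD of the translation walk
    motion_spike_prob: float = 0.02
    motion_leak: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.coupling_by_genotype is None:
            self.coupling_by_genotype = default_couplings(self.roi_labels)

    def coupling(self, genotype: str) -> pd.DataFrame:
        mat = self.coupling_by_genotype[genotype].loc[self.roi_labels, self.roi_labels]
        arr = mat.to_numpy()
        if not np.allclose(arr, arr.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.abs(np.diag(arr)) > 0):
            raise ValueError("coupling matrix must have a zero diagonal")
        if np.any(np.abs(arr) >= 1):
            raise ValueError("couplings must lie in (-1, 1)")
        return mat


@dataclass
class ROISession:
    """One subject's extracted BOLD data: ROI, noise-ROI and motion series."""

    roi: pd.DataFrame  # volumes x ROI
    noise: pd.DataFrame  # volumes x (WM + CSF), columns prefixed WM/CSF
    motion: pd.DataFrame  # volumes x 6
    tr: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.roi)
        if len(self.noise) != n or len(self.motion) != n:
            raise ValueError("ROI, noise and motion blocks must have equal volume counts")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return len(self.roi)


def _smooth_components(rng: np.random.Generator, t: int, k: int, width: float) -> np.ndarray:
    """k slowly varying unit-variance nuisance time courses (t x k)."""
    raw = rng.standard_normal((t + 8 * int(width), k))
    kernel_x = np.arange(-4 * int(width), 4 * int(width) + 1)
    kernel = np.exp(-(kernel_x**2) / (2.0 * width**2))
    kernel /= kernel.sum()
    comps = np.column_stack(
        [np.convolve(raw[:, j], kernel, mode="same")[4 * int(width): 4 * int(width) + t]
         for j in range(k)]
    )
    comps -= comps.mean(axis=0)
    sd = comps.std(axis=0)
    sd[sd == 0] = 1.0
    return comps / sd


def _bounded_walk(rng: np.random.Generator, t: int, scale: float, spike_prob: float) -> np.ndarray:
    """Mean-reverting random walk with occasional spikes (t values)."""
    steps = rng.standard_normal(t) * scale
    spikes = rng.random(t) < spike_prob
    steps[spikes] *= 8.0
    out = np.empty(t)
    level = 0.0
    for i in range(t):  # OU-style decay keeps the walk bounded
        level = 0.95 * level + steps[i]
        out[i] = level
    return out


def synth_bold(subject: SubjectSpec, params: BOLDGenParams) -> ROISession:
    """Generate one subject's ROI BOLD session with known planted couplings.

    Deterministic given ``(params.seed, subject.id)``.  The realized coupling
    matrix is stored in ``session.truth["coupling"]``.
    """
    t = params.n_volumes
    if t < 50:
        raise ValueError("n_volumes must be at least 50")
    rng = subject_rng(params.seed, subject.id, "bold")
    labels = params.roi_labels
    p = len(labels)

    coupling = params.coupling(subject.genotype)
    corr = np.eye(p) + coupling.to_numpy()
    # guard: planted couplings must form a valid correlation matrix
    min_eig = np.linalg.eigvalsh(corr).min()
    if min_eig <= 1e-8:
        raise ValueError(f"coupling matrix is not positive definite (min eig {min_eig:.3g})")
    chol = np.linalg.cholesky(corr)
    roi = rng.standard_normal((t, p)) @ chol.T

    # shared nuisance components: contaminate ROI and noise-ROI series alike
    k = params.n_nuisance_components
    comps = _smooth_components(rng, t, k, params.nuisance_smooth_vol) if k else np.zeros((t, 0))
    if k:
        roi_load = rng.normal(0.0, params.nuisance_amp, size=(k, p))
        roi = roi + comps @ roi_load

    n_wm = params.noise_roi_counts.get("wm", 0)
    n_csf = params.noise_roi_counts.get("csf", 0)
    noise_labels = [f"WM{i + 1}" for i in range(n_wm)] + [f"CSF{i + 1}" for i in range(n_csf)]
    noise = rng.normal(0.0, 0.3, size=(t, n_wm + n_csf))
    if k and noise.shape[1]:
        noise_load = rng.normal(0.0, max(params.nuisance_amp, 0.5), size=(k, n_wm + n_csf))
        noise = noise + comps @ noise_load

    # bounded-walk motion; rotations ~ rad at 1/50 of the translation scale
    motion = np.column_stack(
        [_bounded_walk(rng, t, params.motion_scale, params.motion_spike_prob) for _ in range(3)]
        + [_bounded_walk(rng, t, params.motion_scale / 50.0, params.motion_spike_prob)
           for _ in range(3)]
    )
    if params.motion_leak > 0:
        mz = motion - motion.mean(axis=0)
        sd = mz.std(axis=0)
        sd[sd == 0] = 1.0
        mz = mz / sd
        leak = rng.normal(0.0, params.motion_leak, size=(6, p))
        roi = roi + mz @ leak

    return ROISession(
        roi=pd.DataFrame(roi, columns=labels),
        noise=pd.DataFrame(noise, columns=noise_labels),
        motion=pd.DataFrame(motion, columns=MOTION_COLUMNS),
        tr=params.tr,
        truth={"coupling": coupling, "nuisance_components": comps},
    )
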