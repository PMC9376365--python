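"""Containers and I/O for montage-labelled resting EEG blocks.

A recording is a dense channel x time sample block in microvolts with a fixed
sampling rate and 10-20 channel labels.  On disk a recording is either an EDF
file (read via :mod:`mne`, imported lazily) or a plain tab-separated numeric
matrix with a JSON sidecar holding ``{"labels": [...], "rate": ...}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: 16-channel 10-20 montage in acquisition order.
MONTAGE_1020 = [
    "O2", "O1", "P4", "P3", "C4", "C3", "F4", "F3",
    "Fp2", "Fp1", "T6", "T5", "T4", "T3", "F8", "F7",
]


@dataclass
class EEGRecording:
    """Channel x time EEG sample block.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_times)`` in microvolts.
    rate
        Sampling rate in Hz; must be positive.
    labels
        Channel names, one per row of ``samples``.
    """

    samples: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=lambda: list(MONTAGE_1020))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channel x time array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.rate

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.samples.copy(), self.rate, list(self.labels))

    # ------------------------------------------------------------------ I/O
    def save_matrix(self, path: str | Path) -> None:
        """Write the recording as ``<path>`` (TSV, channels as columns) plus
        a ``<path>.json`` sidecar with labels and rate."""
        path = Path(path)
        np.savetxt(path, self.samples.T, delimiter="\t", fmt="%.6f")
        sidecar = {"labels": list(self.labels), "rate": float(self.rate)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load_matrix(cls, path: str | Path) -> "EEGRecording":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        samples = np.loadtxt(path, delimiter="\t", ndmin=2).T
        return cls(samples, float(sidecar["rate"]), list(sidecar["labels"]))

    @classmethod
    def load_edf(cls, path: str | Path, picks: list[str] | None = None) -> "EEGRecording":
        """Read an EDF file.  Requires :mod:`mne` (optional dependency)."""
        import mne  # deferred: heavy import, optional extra

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        if picks is not None:
            raw.pick(picks)
        return cls(raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names))
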