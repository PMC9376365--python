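"""Synthetic study cohorts with APOE-genotype-dependent alpha parameters.

Each subject carries the ground truth used by the signal generators: an
individual alpha peak frequency (IAPF) that declines linearly with age —
more steeply in epsilon-4 carriers — and a dimensionless alpha amplitude.
All randomness is drawn from per-subject streams derived from
``(master seed, subject id)`` so that changing the cohort size leaves every
other subject's data untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from alphaconn.recording import MONTAGE_1020

E4PLUS = "E4plus"
E4MINUS = "E4minus"

#: age threshold splitting the younger / older subgroups
AGE_GROUP_THRESHOLD = 50.0

_STREAMS = {"cohort": 0, "eeg": 1, "bold": 2}


def subject_rng(master_seed: int, subject_id: str, stream: str) -> np.random.Generator:
    """Independent RNG for one subject and purpose.

    The stream key is ``(master_seed, crc32(subject_id), stream index)`` fed
    to :class:`numpy.random.SeedSequence`, so streams never collide across
    subjects or purposes and do not depend on generation order.
    """
    key = zlib.crc32(subject_id.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), key, _STREAMS[stream]])
    return np.random.default_rng(ss)


def age_group(age: float) -> str:
    """'younger' below 50 years, 'older' at 50 and above."""
    return "younger" if age < AGE_GROUP_THRESHOLD else "older"


@dataclass
class EEGGenParams:
    """Generative parameters for cohorts and resting EEG.

    The IAPF model is ``iapf = intercept + slope(genotype) * (age - 40) + eps``
    with ``eps ~ N(0, iapf_resid_sd^2)``; the result is clipped to [7, 14] Hz.
    ``alpha_peak_snr`` is the alpha-peak power over the 1/f background power at
    the peak bin for a unit-gain (occipital) channel; per-channel amplitude
    gains taper from occiput to frontal sites.
    """

    sample_rate: float = 256.0
    duration: float = 150.0
    channel_labels: list[str] = field(default_factory=lambda: list(MONTAGE_1020))
    iapf_intercept: float = 10.2
    iapf_age_slope_e4minus: float = -0.010
    iapf_age_slope_e4plus: float = -0.030
    iapf_resid_sd: float = 0.8
    alpha_bandwidth: float = 0.6  # FWHM of the alpha power profile, Hz
    alpha_peak_snr: float = 16.0
    one_over_f_exponent: float = 1.0
    noise_sd: float = 10.0  # background scale, a.u. (nominally microvolts)
    age_range: tuple[float, float] = (26.0, 79.0)
    male_proportion: float = 45.0 / 137.0
    alpha_power_sd: float = 0.2  # log-sd of the subject alpha amplitude factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        # all synthesized content lives below 35 Hz + alpha tail
        if self.sample_rate <= 2 * 35.0:
            raise ValueError("sample_rate must exceed twice the highest synthesized frequency")

    def slope(self, genotype: str) -> float:
        if genotype == E4PLUS:
            return self.iapf_age_slope_e4plus
        if genotype == E4MINUS:
            return self.iapf_age_slope_e4minus
        raise ValueError(f"unknown genotype {genotype!r}")


@dataclass
class SubjectSpec:
    """Ground-truth description of one synthetic subject."""

    id: str
    age: float
    sex: str  # 'M' or 'W'
    genotype: str  # E4plus / E4minus
    true_iapf: float
    true_alpha_power: float = 1.0
    edge_effects: dict | None = None

    def __post_init__(self) -> None:
        if not 7.0 <= self.true_iapf <= 14.0:
            raise ValueError(f"true_iapf {self.true_iapf} outside [7, 14] Hz")

    @property
    def age_group(self) -> str:
        return age_group(self.age)


def _make_subject(subject_id: str, genotype: str, params: EEGGenParams, seed: int) -> SubjectSpec:
    rng = subject_rng(seed, subject_id, "cohort")
    age = rng.uniform(*params.age_range)
    sex = "M" if rng.random() < params.male_proportion else "W"
    iapf = (
        params.iapf_intercept
        + params.slope(genotype) * (age - 40.0)
        + rng.normal(0.0, params.iapf_resid_sd)
    )
    iapf = float(np.clip(iapf, 7.0, 14.0))
    alpha_power = float(rng.lognormal(0.0, params.alpha_power_sd))
    return SubjectSpec(subject_id, float(age), sex, genotype, iapf, alpha_power)


def generate_cohort(
    n_e4minus: int,
    n_e4plus: int,
    params: EEGGenParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort of ``n_e4minus + n_e4plus`` subjects.

    Returns a table with one row per subject and columns ``subject``, ``age``,
    ``sex``, ``genotype``, ``age_group``, ``true_iapf``, ``true_alpha_power``.
    Deterministic given ``seed``; subject rows are invariant to the other
    group's size.
    """
    if n_e4minus < 0 or n_e4plus < 0:
        raise ValueError("group sizes must be non-negative")
    params = params or EEGGenParams()
    specs: list[SubjectSpec] = []
    for i in range(n_e4minus):
        specs.append(_make_subject(f"e4m{i + 1:03d}", E4MINUS, params, seed))
    for i in range(n_e4plus):
        specs.append(_make_subject(f"e4p{i + 1:03d}", E4PLUS, params, seed))
    return pd.DataFrame(
        {
            "subject": [s.id for s in specs],
            "age": [s.age for s in specs],
            "sex": [s.sex for s in specs],
            "genotype": [s.genotype for s in specs],
            "age_group": [s.age_group for s in specs],
            "true_iapf": [s.true_iapf for s in specs],
            "true_alpha_power": [s.true_alpha_power for s in specs],
        }
    )


def cohort_to_specs(cohort: pd.DataFrame) -> list[SubjectSpec]:
    """Rehydrate :class:`SubjectSpec` objects from a cohort table."""
    return [
        SubjectSpec(
            id=row.subject,
            age=float(row.age),
            sex=row.sex,
            genotype=row.genotype,
            true_iapf=float(row.true_iapf),
            true_alpha_power=float(row.true_alpha_power),
        )
        for row in cohort.itertuples(index=False)
    ]
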