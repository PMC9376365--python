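"""End-to-end orchestration: simulate -> EEG spectra -> rsFC -> inference.

A run is fully described by a :class:`RunConfig` (serializable, schema-checked)
plus a master seed.  Outputs are tidy TSV tables written atomically to the
output directory together with a JSON manifest recording the seed, the full
effective configuration, package versions and a SHA-256 hash per table; the
combined ``run_hash`` is identical across reruns with the same config/seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import alphaconn
from alphaconn.cohort import (
    E4MINUS,
    E4PLUS,
    EEGGenParams,
    cohort_to_specs,
    generate_cohort,
)
from alphaconn.connectivity import session_connectivity
from alphaconn.spectral import estimate_iapf, subject_subband_table
from alphaconn.stats import (
    AnovaSpec,
    compare_correlations_fisher,
    corr_test,
    duncan_posthoc,
    edge_group_compare,
    rm_anova,
)
from alphaconn.synth_bold import BOLDGenParams, synth_bold
from alphaconn.synth_eeg import synth_eeg

#: 10-20 channel -> (scalp region, hemisphere) for the IAPF topographic ANOVA
CHANNEL_TOPOGRAPHY = {
    "O2": ("occipital", "right"), "O1": ("occipital", "left"),
    "P4": ("parietal", "right"), "P3": ("parietal", "left"),
    "C4": ("central", "right"), "C3": ("central", "left"),
    "F4": ("frontal1", "right"), "F3": ("frontal1", "left"),
    "Fp2": ("frontal2", "right"), "Fp1": ("frontal2", "left"),
    "T6": ("temporal1", "right"), "T5": ("temporal1", "left"),
    "T4": ("temporal2", "right"), "T3": ("temporal2", "left"),
    "F8": ("temporal3", "right"), "F7": ("temporal3", "left"),
}

HIPP_PPC_EDGE = ("Hippocampus l", "PPC r")

VALID_MODES = ("joint", "eeg_only", "fmri_only")


class ConfigError(ValueError):
    """Invalid run configuration."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Complete, serializable description of one analysis run."""

    n_e4minus: int = 91
    n_e4plus: int = 46
    fmri_n_e4minus: int = 23
    fmri_n_e4plus: int = 14
    mode: str = "joint"
    alpha: float = 0.05
    seed: int = 0
    eeg: dict = field(default_factory=dict)  # EEGGenParams overrides
    bold: dict = field(default_factory=dict)  # BOLDGenParams overrides

    _EEG_FIELDS = {f.name for f in dataclasses.fields(EEGGenParams)}
    _BOLD_FIELDS = {f.name for f in dataclasses.fields(BOLDGenParams)}

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ConfigError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        for name in ("n_e4minus", "n_e4plus", "fmri_n_e4minus", "fmri_n_e4plus"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        unknown = set(self.eeg) - self._EEG_FIELDS
        if unknown:
            raise ConfigError(f"unknown EEG parameter(s): {sorted(unknown)}")
        unknown = set(self.bold) - self._BOLD_FIELDS
        if unknown:
            raise ConfigError(f"unknown BOLD parameter(s): {sorted(unknown)}")
        if self.fmri_n_e4minus > self.n_e4minus or self.fmri_n_e4plus > self.n_e4plus:
            raise ConfigError("fMRI subgroup cannot exceed the cohort")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def eeg_params(self) -> EEGGenParams:
        return EEGGenParams(seed=self.seed, **self.eeg)

    def bold_params(self) -> BOLDGenParams:
        return BOLDGenParams(seed=self.seed, **self.bold)

    def effective_dict(self) -> dict:
        """Fully expanded configuration with every default serialized."""
        d = dataclasses.asdict(self)
        eeg = dataclasses.asdict(self.eeg_params())
        bold = dataclasses.asdict(self.bold_params())
        bold["coupling_by_genotype"] = {
            g: m.to_dict() for g, m in bold["coupling_by_genotype"].items()
        }
        d["eeg"], d["bold"] = eeg, bold
        return d


def _atomic_write_tsv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
    os.replace(tmp, path)


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.effective_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured analysis end-to-end; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise PipelineStageError(name, exc) from exc

    eeg_params = config.eeg_params()
    cohort = stage("simulate_cohort",
                   lambda: generate_cohort(config.n_e4minus, config.n_e4plus,
                                           eeg_params, seed=config.seed))
    tables["cohort"] = cohort
    specs = cohort_to_specs(cohort)

    iapf_subject = None
    if config.mode in ("joint", "eeg_only"):
        def eeg_stage():
            sub_rows, iapf_rows = [], []
            for spec in specs:
                rec = synth_eeg(spec, eeg_params)
                tab = subject_subband_table(rec)
                tab.insert(0, "subject", spec.id)
                sub_rows.append(tab)
                imap = estimate_iapf(rec)
                imap.insert(0, "subject", spec.id)
                iapf_rows.append(imap)
            return pd.concat(sub_rows, ignore_index=True), pd.concat(iapf_rows, ignore_index=True)

        subband, iapf = stage("eeg_spectral", eeg_stage)
        tables["subband_power"] = subband
        tables["iapf"] = iapf

        def stats_stage():
            meta = cohort.set_index("subject")
            sexnum = meta["sex"].map({"M": 0.0, "W": 1.0})

            # band ANOVA on channel-mean logit power
            band_tab = (subband.groupby(["subject", "band"], as_index=False)["value"].mean())
            band_tab["genotype"] = band_tab["subject"].map(meta["genotype"])
            band_tab["age_group"] = band_tab["subject"].map(meta["age_group"])
            band_tab["sex"] = band_tab["subject"].map(sexnum)
            anova_band = rm_anova(band_tab, AnovaSpec(
                response="value", between=["genotype", "age_group"],
                within=["band"], covariates=["sex"]))

            # IAPF ANOVA over scalp region x hemisphere
            itab = iapf.copy()
            itab["region"] = itab["channel"].map(lambda c: CHANNEL_TOPOGRAPHY[c][0])
            itab["hemisphere"] = itab["channel"].map(lambda c: CHANNEL_TOPOGRAPHY[c][1])
            itab["genotype"] = itab["subject"].map(meta["genotype"])
            itab["age_group"] = itab["subject"].map(meta["age_group"])
            itab["sex"] = itab["subject"].map(sexnum)
            anova_iapf = rm_anova(itab, AnovaSpec(
                response="iapf", between=["genotype", "age_group"],
                within=["region", "hemisphere"], covariates=["sex"]))

            # Duncan post-hoc over genotype x band cells
            err = anova_band.set_index("effect")
            ms_e = float(err.loc["error(band)", "ms"])
            df_e = float(err.loc["error(band)", "df1"])
            cells = band_tab.groupby(["genotype", "band"])["value"]
            means = cells.mean()
            ns = cells.size()
            posthoc = duncan_posthoc(
                {f"{g}|{b}": v for (g, b), v in means.items()},
                {f"{g}|{b}": v for (g, b), v in ns.items()},
                ms_e, df_e, alpha=config.alpha)

            # age-IAPF correlations per genotype + Fisher comparison
            subj_iapf = iapf.groupby("subject")["iapf"].mean()
            corr_rows = []
            by_geno = {}
            for geno in (E4MINUS, E4PLUS):
                ids = meta.index[meta["genotype"] == geno]
                res = corr_test(meta.loc[ids, "age"], subj_iapf[ids])
                by_geno[geno] = res
                corr_rows.append({"group": geno, "r": res.r, "p": res.p,
                                  "n": res.n, "method": res.method})
            zstat, pz = compare_correlations_fisher(
                by_geno[E4PLUS].r, by_geno[E4PLUS].n,
                by_geno[E4MINUS].r, by_geno[E4MINUS].n, alternative="less")
            corr_rows.append({"group": "fisher_e4plus_vs_e4minus", "r": zstat,
                              "p": pz, "n": by_geno[E4PLUS].n + by_geno[E4MINUS].n,
                              "method": "fisher_r_to_z_one_sided"})
            return anova_band, anova_iapf, posthoc, pd.DataFrame(corr_rows)

        anova_band, anova_iapf, posthoc, age_corr = stage("eeg_inference", stats_stage)
        tables["anova_subband"] = anova_band
        tables["anova_iapf"] = anova_iapf
        tables["posthoc_genotype_band"] = posthoc
        tables["age_iapf_correlation"] = age_corr
        iapf_subject = iapf.groupby("subject")["iapf"].mean()

    if config.mode in ("joint", "fmri_only"):
        bold_params = config.bold_params()
        fmri_ids = (
            [s.id for s in specs if s.genotype == E4MINUS][: config.fmri_n_e4minus]
            + [s.id for s in specs if s.genotype == E4PLUS][: config.fmri_n_e4plus]
        )
        spec_by_id = {s.id: s for s in specs}

        def fmri_stage():
            z_by_subject = {}
            for sid in fmri_ids:
                session = synth_bold(spec_by_id[sid], bold_params)
                conn, _ = session_connectivity(session)
                z_by_subject[sid] = conn.z  # diagonal NaN; edges use the triangle
            groups = {sid: spec_by_id[sid].genotype for sid in fmri_ids}
            edges = edge_group_compare(z_by_subject, groups, E4PLUS, E4MINUS)
            return z_by_subject, edges

        z_by_subject, edges = stage("fmri_connectivity", fmri_stage)
        tables["edge_contrasts"] = edges

        if config.mode == "joint" and iapf_subject is not None:
            def linkage_stage():
                rows = []
                sig = edges[edges["p_fdr"] < config.alpha][["roi_i", "roi_j"]]
                pairs = {tuple(p) for p in sig.to_numpy()} | {HIPP_PPC_EDGE}
                for roi_i, roi_j in sorted(pairs):
                    zvals = np.array([z_by_subject[s].loc[roi_i, roi_j] for s in fmri_ids])
                    ivals = iapf_subject[fmri_ids].to_numpy()
                    res = corr_test(ivals, zvals)
                    rows.append({"roi_i": roi_i, "roi_j": roi_j, "r": res.r,
                                 "p": res.p, "n": res.n, "method": res.method})
                return pd.DataFrame(rows)

            tables["iapf_edge_correlation"] = stage("eeg_fmri_linkage", linkage_stage)

    def write_stage():
        manifest: dict = {
            "seed": config.seed,
            "config": config.effective_dict(),
            "config_hash": _config_hash(config),
            "versions": {
                "alphaconn": alphaconn.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "tables": {},
        }
        for name, df in tables.items():
            path = outdir / f"{name}.tsv"
            _atomic_write_tsv(df, path)
            manifest["tables"][name] = {"file": path.name, "sha256": _file_sha256(path)}
        run_hash = hashlib.sha256(
            json.dumps(
                {"config": manifest["config_hash"],
                 "tables": {k: v["sha256"] for k, v in manifest["tables"].items()}},
                sort_keys=True,
            ).encode()
        ).hexdigest()
        manifest["run_hash"] = run_hash
        tmp = outdir / "manifest.json.tmp"
        tmp.write_text(json.dumps(manifest, indent=2, default=str))
        os.replace(tmp, outdir / "manifest.json")
        return manifest

    return stage("write_outputs", write_stage)
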