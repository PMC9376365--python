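"""Group inference on the EEG features: split-plot ANOVAs of subband power
(genotype x age group between, band within, sex covariate) and of IAPF
(scalp region x hemisphere within), Duncan post-hoc over genotype x band
cells, and the age-IAPF correlations per genotype with their one-sided
Fisher r-to-z comparison.  Reads results/{cohort,subband_power,iapf}.tsv;
writes the ANOVA, post-hoc and correlation tables under results/."""

import argparse
from pathlib import Path

import pandas as pd

from alphaconn.cohort import E4MINUS, E4PLUS
from alphaconn.pipeline import CHANNEL_TOPOGRAPHY
from alphaconn.stats import (
    AnovaSpec,
    compare_correlations_fisher,
    corr_test,
    duncan_posthoc,
    rm_anova,
)

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = pd.read_csv(args.outdir / "cohort.tsv", sep="\t").set_index("subject")
subband = pd.read_csv(args.outdir / "subband_power.tsv", sep="\t")
iapf = pd.read_csv(args.outdir / "iapf.tsv", sep="\t")
sexnum = cohort["sex"].map({"M": 0.0, "W": 1.0})

band_tab = subband.groupby(["subject", "band"], as_index=False)["value"].mean()
for col, src in (("genotype", "genotype"), ("age_group", "age_group")):
    band_tab[col] = band_tab["subject"].map(cohort[src])
band_tab["sex"] = band_tab["subject"].map(sexnum)
anova_band = rm_anova(band_tab, AnovaSpec(
    response="value", between=["genotype", "age_group"], within=["band"],
    covariates=["sex"]))
anova_band.to_csv(args.outdir / "anova_subband.tsv", sep="\t", index=False)
show = anova_band.set_index("effect")
for eff in ("genotype", "band:genotype", "band:age_group"):
    row = show.loc[eff]
    print(f"subband ANOVA {eff}: F[{row.df1:.0f},{row.df2:.0f}] = {row.F:.2f}, "
          f"p = {row.p:.4g}")

itab = iapf.copy()
itab["region"] = itab["channel"].map(lambda c: CHANNEL_TOPOGRAPHY[c][0])
itab["hemisphere"] = itab["channel"].map(lambda c: CHANNEL_TOPOGRAPHY[c][1])
itab["genotype"] = itab["subject"].map(cohort["genotype"])
itab["age_group"] = itab["subject"].map(cohort["age_group"])
itab["sex"] = itab["subject"].map(sexnum)
anova_iapf = rm_anova(itab, AnovaSpec(
    response="iapf", between=["genotype", "age_group"],
    within=["region", "hemisphere"], covariates=["sex"]))
anova_iapf.to_csv(args.outdir / "anova_iapf.tsv", sep="\t", index=False)
row = anova_iapf.set_index("effect").loc["genotype"]
print(f"IAPF ANOVA genotype: F[{row.df1:.0f},{row.df2:.0f}] = {row.F:.2f}, "
      f"p = {row.p:.4g}")

err = anova_band.set_index("effect")
cells = band_tab.groupby(["genotype", "band"])["value"]
posthoc = duncan_posthoc(
    {f"{g}|{b}": v for (g, b), v in cells.mean().items()},
    {f"{g}|{b}": v for (g, b), v in cells.size().items()},
    float(err.loc["error(band)", "ms"]), float(err.loc["error(band)", "df1"]))
posthoc.to_csv(args.outdir / "posthoc_genotype_band.tsv", sep="\t", index=False)
same_band = posthoc[
    posthoc.level_a.str.split("|").str[1] == posthoc.level_b.str.split("|").str[1]]
print("Duncan genotype contrasts per band (significant at .05):")
print(same_band[["level_a", "level_b", "diff", "significant"]].to_string(index=False))

subj_iapf = iapf.groupby("subject")["iapf"].mean()
rows, by_geno = [], {}
for geno in (E4MINUS, E4PLUS):
    ids = cohort.index[cohort["genotype"] == geno]
    res = corr_test(cohort.loc[ids, "age"], subj_iapf[ids])
    by_geno[geno] = res
    rows.append({"group": geno, "r": res.r, "p": res.p, "n": res.n,
                 "method": res.method})
    print(f"{geno}: age-IAPF r = {res.r:+.3f}, p = {res.p:.4f} ({res.method}, n={res.n})")
z, p = compare_correlations_fisher(by_geno[E4PLUS].r, by_geno[E4PLUS].n,
                                   by_geno[E4MINUS].r, by_geno[E4MINUS].n,
                                   alternative="less")
rows.append({"group": "fisher_e4plus_vs_e4minus", "r": z, "p": p,
             "n": by_geno[E4PLUS].n + by_geno[E4MINUS].n,
             "method": "fisher_r_to_z_one_sided"})
print(f"Fisher r-to-z (E4+ steeper than E4-): z = {z:.2f}, one-sided p = {p:.4f}")
pd.DataFrame(rows).to_csv(args.outdir / "age_iapf_correlation.tsv", sep="\t",
                          index=False)
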