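"""Generate the synthetic study cohort (91 E4-, 46 E4+) and verify that the
genotype-specific age slopes of the true alpha peak frequency are recoverable
by regression.  Writes results/cohort.tsv."""

import argparse
from pathlib import Path

import numpy as np

from alphaconn.cohort import E4MINUS, E4PLUS, EEGGenParams, generate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

params = EEGGenParams(seed=args.seed)
cohort = generate_cohort(91, 46, params, seed=args.seed)
args.outdir.mkdir(parents=True, exist_ok=True)
cohort.to_csv(args.outdir / "cohort.tsv", sep="\t", index=False)

print(f"cohort: {len(cohort)} subjects "
      f"({(cohort.genotype == E4MINUS).sum()} E4-, {(cohort.genotype == E4PLUS).sum()} E4+)")
print(cohort.groupby(["age_group", "genotype"]).size().unstack())

for geno, true_slope in ((E4MINUS, params.iapf_age_slope_e4minus),
                         (E4PLUS, params.iapf_age_slope_e4plus)):
    sub = cohort[cohort.genotype == geno]
    slope = np.polyfit(sub["age"], sub["true_iapf"], 1)[0]
    print(f"{geno}: fitted age slope of true IAPF {slope:+.4f} Hz/yr "
          f"(generative {true_slope:+.4f})")
print(f"wrote {args.outdir / 'cohort.tsv'}")
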