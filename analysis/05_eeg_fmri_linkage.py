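"""Link the EEG and fMRI features in the same synthetic individuals:
correlate the channel-averaged IAPF with the Fisher-z connectivity of the
left hippocampus - right posterior parietal cortex edge (plus every
FDR-significant contrast edge).  Reads results/{iapf,z_edges,edge_contrasts}.tsv;
writes results/iapf_edge_correlation.tsv."""

import argparse
from pathlib import Path

import pandas as pd

from alphaconn.stats import corr_test

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

iapf = pd.read_csv(args.outdir / "iapf.tsv", sep="\t")
z_edges = pd.read_csv(args.outdir / "z_edges.tsv", sep="\t")
contrast = pd.read_csv(args.outdir / "edge_contrasts.tsv", sep="\t")

subj_iapf = iapf.groupby("subject")["iapf"].mean()
sig = contrast[contrast["p_fdr"] < 0.05][["roi_i", "roi_j"]]
pairs = {tuple(p) for p in sig.to_numpy()} | {("Hippocampus l", "PPC r")}

rows = []
for roi_i, roi_j in sorted(pairs):
    edge = z_edges[(z_edges.roi_i == roi_i) & (z_edges.roi_j == roi_j)]
    edge = edge.set_index("subject")["z"]
    common = edge.index.intersection(subj_iapf.index)
    res = corr_test(subj_iapf[common], edge[common])
    rows.append({"roi_i": roi_i, "roi_j": roi_j, "r": res.r, "p": res.p,
                 "n": res.n, "method": res.method})
    marker = " <-- hippocampal edge" if (roi_i, roi_j) == ("Hippocampus l", "PPC r") else ""
    print(f"IAPF vs z({roi_i} - {roi_j}): r = {res.r:+.3f}, "
          f"p = {res.p:.4f} ({res.method}, n={res.n}){marker}")

pd.DataFrame(rows).to_csv(args.outdir / "iapf_edge_correlation.tsv", sep="\t",
                          index=False)
print(f"wrote {args.outdir / 'iapf_edge_correlation.tsv'}")
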