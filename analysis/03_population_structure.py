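#!/usr/bin/env python
"""Population structure: clustering, memberships, migrants, F_ST.

PCA -> K-means with BIC over K=1..5 -> discriminant memberships; flags
birds whose membership to a non-natal cluster reaches 50%; Weir-Cockerham
F_ST between colonies with a 10,000-bootstrap significance test (with and
without the grounded birds, as in the study).
"""
import argparse
import pathlib

import numpy as np
import pandas as pd

from petreldemog.sfs import read_vcf
from petreldemog.structure import (
    assign_memberships,
    detect_migrants,
    fst_bootstrap_p,
    pca_scores,
    select_k,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--qc", default="results/qc")
ap.add_argument("--study", default="results/study")
ap.add_argument("--out", default="results/structure")
args = ap.parse_args()

out = pathlib.Path(args.out)
out.mkdir(parents=True, exist_ok=True)
G = read_vcf(f"{args.qc}/filtered.vcf")
meta = pd.read_csv(f"{args.study}/samples.tsv", sep="\t", index_col="id")
G.samples = meta.reindex(G.samples.index)
colony = G.samples["colony"].to_numpy()

scores = pca_scores(G)  # all PCs: K selection is most stable on the full space
km = select_k(scores, k_max=5, n_starts=20, seed=args.seed)
km.bic_table.to_csv(out / "bic.tsv", sep="\t", index=False)
print(km.bic_table.to_string(index=False))
print(f"BIC-optimal K = {km.k}")

mm = assign_memberships(scores, km.k, seed=args.seed)
members = pd.DataFrame(mm.memberships, index=G.samples.index)
members["assignment"] = mm.assignment
members["colony"] = colony
members.to_csv(out / "memberships.tsv", sep="\t")

colmap = {c: int(np.bincount(mm.assignment[colony == c]).argmax())
          for c in pd.unique(colony)}
natal = np.array([colmap[c] for c in colony])
migrants = detect_migrants(mm.memberships, natal, ids=list(G.samples.index))
print(f"migrants (non-natal membership >= 50%): {migrants}")

for label, mask in (
    ("with grounded birds", np.isin(colony, ["RDC", "GB", "RIR"])),
    ("colonies only", np.isin(colony, ["RDC", "RIR"])),
):
    sub = G.take_samples(mask)
    lab = np.where(sub.samples["colony"] == "RIR", "RIR", "RDC+GB")
    r = fst_bootstrap_p(sub, lab, n_boot=10000, seed=args.seed)
    print(f"F_ST {label}: {r.theta:.4f} (p = {r.p_value:.4g})")
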