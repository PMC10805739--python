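#!/usr/bin/env python
"""Pairwise Jacquard relatedness and pruning to an unrelated set.

Estimates the nine condensed identity coefficients for every pair by EM,
classifies relationships from kinship bands, and keeps one bird per group
of first-degree relatives (fewest-missing-first).
"""
import argparse
import pathlib



from petreldemog.relatedness import pairwise_relatedness, prune_related
from petreldemog.sfs import read_vcf

ap = argparse.ArgumentParser()
ap.add_argument("--qc", default="results/qc")
ap.add_argument("--out", default="results/relatedness")
args = ap.parse_args()

out = pathlib.Path(args.out)
out.mkdir(parents=True, exist_ok=True)
G = read_vcf(f"{args.qc}/filtered.vcf")
rel = pairwise_relatedness(G)
rel.to_csv(out / "pairs.tsv", sep="\t", index=False)
close = rel[rel["class"] != "unrelated"]
print(close.to_string(index=False) if len(close) else "no related pairs found")
missing = dict(zip(G.sample_ids, G.sample_missingness()))
kept = prune_related(rel, G.sample_ids, missing)
(out / "unrelated_ids.txt").write_text("\n".join(kept) + "\n")
print(f"unrelated set: {len(kept)} of {G.n_samples} birds")
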