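#!/usr/bin/env python
"""Folded site-frequency spectra with projection over missing data.

Builds the per-cluster 1d spectra (projection target chosen to maximize the
expected number of retained segregating sites) and the joint RIR x RDC
2d spectrum, written in fastsimcoal-obs dialect.
"""
import argparse
import pathlib

import pandas as pd

from petreldemog.sfs import genotypes_to_sfs, read_vcf, suggest_projection, write_sfs

ap = argparse.ArgumentParser()
ap.add_argument("--qc", default="results/qc")
ap.add_argument("--study", default="results/study")
ap.add_argument("--out", default="results/sfs")
args = ap.parse_args()

out = pathlib.Path(args.out)
out.mkdir(parents=True, exist_ok=True)
G = read_vcf(f"{args.qc}/filtered.vcf")
meta = pd.read_csv(f"{args.study}/samples.tsv", sep="\t", index_col="id")
G.samples = meta.reindex(G.samples.index)
colony = G.samples["colony"]

groups = {
    "RDC_GB": [s for s, c in zip(G.sample_ids, colony) if c in ("RDC", "GB")],
    "RIR": [s for s, c in zip(G.sample_ids, colony) if c == "RIR"],
}
for name, ids in groups.items():
    table, target = suggest_projection(G, ids)
    sfs = genotypes_to_sfs(G, {name: ids}, fold=True, projection={name: target})
    write_sfs(sfs, out / f"sfs_{name}.obs")
    print(f"{name}: projected to n={target} haploids, "
          f"{sfs.total():.0f} expected segregating sites")

# joint spectrum: without projection only complete-data SNPs contribute, so
# (as in the study) subsample 10 unrelated birds per colony
unrel_path = pathlib.Path("results/relatedness/unrelated_ids.txt")
unrelated = set(unrel_path.read_text().split()) if unrel_path.exists() else set(G.sample_ids)
ten = {
    d: sorted(s for s, c in zip(G.sample_ids, colony) if c == d and s in unrelated)[:10]
    for d in ("RIR", "RDC")
}
joint = genotypes_to_sfs(G, ten, fold=True, projection={"RIR": 20, "RDC": 20})
write_sfs(joint, out / "sfs_joint.obs")
print(f"joint 2d-SFS (10 unrelated birds per colony, projected to 20+20): "
      f"{joint.total():.0f} sites")
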