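"""Structured-coalescent simulation: genealogies, SNP genotypes, expected SFS.

Supports one- and two-deme histories with instantaneous size changes,
backward-time joins (forward-time splits) and piecewise-constant asymmetric
migration.  Two SNP modes:

* ``conditioned`` (default): one independent genealogy per SNP with exactly
  one mutation placed uniformly by branch length, i.e. every SNP segregates
  in the pooled sample.  SFS proportions in this mode do not depend on the
  mutation rate or sequence length.
* ``absolute``: one genealogy per tag (reduced-representation locus) with
  Poisson(mu * L_tag * total length) mutations, so tags may carry several
  linked SNPs or none.

The expected SFS is the Monte-Carlo mean of branch length subtending each
(i, j) descendant configuration, normalized over polymorphic entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .demography import (
    TIME_CEILING,
    DemographicModel,
    ModelValidationError,
    SampleConfig,
    build_model,
)
from .sfs import MISSING, FoldedSFS, GenotypeMatrix, fold_joint, fold_sfs

__all__ = [
    "build_model",
    "Genealogy",
    "simulate_genealogy",
    "simulate_genotypes",
    "ExpectedSFS",
    "expected_sfs",
]


class CoalescenceTimeoutError(RuntimeError):
    """Lineages failed to find a common ancestor before the time ceiling."""


@dataclass
class Genealogy:
    """Binary genealogy over the sampled lineages.

    Nodes 0..n-1 are leaves (ordered by deme blocks); internal nodes follow
    in coalescence order.  ``parent[root] == -1``.
    """

    node_time: np.ndarray
    parent: np.ndarray
    leaf_deme: np.ndarray
    total_length: float
    subtended: np.ndarray  # (n_nodes, n_demes) samples under each node

    @property
    def n_leaves(self) -> int:
        return (self.parent.shape[0] + 1) // 2

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])


def _compiled(model: DemographicModel):
    cm = model.compile()
    return (
        cm.start_sizes,
        cm.start_mig,
        cm.ev_time,
        cm.ev_kind,
        cm.ev_a,
        cm.ev_b,
        cm.ev_val,
    )


def _samp_array(model: DemographicModel, samples: SampleConfig) -> np.ndarray:
    arr = samples.sizes_for(model)
    if arr.sum() < 2:
        raise ModelValidationError("need >= 2 sampled lineages")
    return arr


def simulate_genealogy(
    model: DemographicModel,
    samples: SampleConfig,
    seed: int,
    ceiling: float = TIME_CEILING,
) -> Genealogy:
    """Simulate one genealogy of all samples under ``model``."""
    samp = _samp_array(model, samples)
    args = _compiled(model)
    node_time, left, right, total, root = _kernels.simulate_tree(
        np.int64(seed % (2**31)), samp, *args, ceiling
    )
    if root < 0:
        raise CoalescenceTimeoutError(
            f"no common ancestor before the {ceiling:g}-generation ceiling"
        )
    n_nodes = node_time.shape[0]
    n = (n_nodes + 1) // 2
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for v in range(n, n_nodes):
        parent[left[v]] = v
        parent[right[v]] = v
    leaf_deme = np.zeros(n, dtype=np.int64)
    ofs = 0
    for d, k in enumerate(samp):
        leaf_deme[ofs : ofs + k] = d
        ofs += k
    nd = len(model.demes)
    subtended = np.zeros((n_nodes, nd), dtype=np.int64)
    subtended[np.arange(n), leaf_deme] = 1
    for v in range(n, n_nodes):  # children always have smaller index
        subtended[v] = subtended[left[v]] + subtended[right[v]]
    return Genealogy(node_time, parent, leaf_deme, float(total), subtended)


def _haplotypes_to_matrix(
    haps: np.ndarray,
    tag_ids: np.ndarray,
    model: DemographicModel,
    samp: np.ndarray,
    rng: np.random.Generator,
    mode: str,
) -> GenotypeMatrix:
    n_snps = haps.shape[0]
    # pair haplotypes into diploids within deme, random pairing (random mating)
    cols = []
    sample_rows = []
    ofs = 0
    for d, k in enumerate(samp):
        if k % 2:
            raise ModelValidationError(
                f"haploid sample size {k} for deme {model.demes[d]!r} is odd; "
                "diploid genotypes need an even count"
            )
        perm = ofs + rng.permutation(k)
        for i in range(k // 2):
            cols.append((perm[2 * i], perm[2 * i + 1]))
            sample_rows.append(
                {"id": f"{model.demes[d]}_{i:03d}", "colony": model.demes[d]}
            )
        ofs += k
    calls = np.empty((len(cols), n_snps), dtype=np.int8)
    for i, (a, b) in enumerate(cols):
        calls[i] = haps[:, a] + haps[:, b]
    samples_df = pd.DataFrame(sample_rows).set_index("id")
    loci_df = pd.DataFrame(
        {
            "locus_id": [f"L{j + 1:06d}" for j in range(n_snps)],
            "tag_id": [f"T{int(t) + 1:06d}" for t in tag_ids],
            "chrom": "synthetic",
            "pos": np.arange(1, n_snps + 1),
            "ref": "A",
            "alt": "T",
        }
    ).set_index("locus_id")
    G = GenotypeMatrix(calls, samples_df, loci_df)
    G.loci.attrs["snp_mode"] = mode
    return G


def simulate_genotypes(
    model: DemographicModel,
    samples: SampleConfig,
    n_snps: int,
    seed: int,
    mode: str = "conditioned",
    n_tags: int | None = None,
    pool_factor: int = 8,
    ceiling: float = TIME_CEILING,
) -> GenotypeMatrix:
    """Simulate diploid SNP genotypes.

    ``conditioned`` mode yields exactly ``n_snps`` SNPs, each polymorphic in
    the pooled sample; mutations are length-bias-allocated over a pool of
    ``pool_factor * n_snps`` genealogies so SNPs are close to independent.
    ``absolute`` mode simulates ``n_tags`` tag genealogies of length
    ``samples.sequence_length / n_tags`` each and returns however many SNPs
    arise (``n_snps`` is ignored).
    """
    samp = _samp_array(model, samples)
    args = _compiled(model)
    rng = np.random.default_rng(seed)
    kseed = np.int64(seed % (2**31))
    if mode == "conditioned":
        if n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        if n_snps == 0:
            haps = np.zeros((0, samp.sum()), dtype=np.int8)
            tag_ids = np.zeros(0, dtype=np.int64)
        else:
            haps, ok = _kernels.simulate_snp_haplotypes(
                kseed, n_snps, pool_factor, samp, *args, ceiling
            )
            if not ok:
                raise CoalescenceTimeoutError("time ceiling hit during SNP simulation")
            tag_ids = np.arange(n_snps, dtype=np.int64)
    elif mode == "absolute":
        if not n_tags or n_tags < 1:
            raise ValueError("absolute mode requires n_tags >= 1")
        l_tag = samples.sequence_length / n_tags
        haps_buf, tag_buf, m, ok = _kernels.simulate_tag_haplotypes(
            kseed, n_tags, samples.mu * l_tag, samp, *args, ceiling
        )
        if not ok:
            raise CoalescenceTimeoutError("time ceiling hit during tag simulation")
        haps = haps_buf[:m]
        tag_ids = tag_buf[:m]
    else:
        raise ValueError(f"unknown SNP mode {mode!r}")
    return _haplotypes_to_matrix(haps, tag_ids, model, samp, rng, mode)


@dataclass
class ExpectedSFS:
    """Monte-Carlo expected SFS: normalized branch-length proportions.

    ``proportions`` sums to 1 over polymorphic (unmasked) entries.
    ``mean_total_length`` is the mean genealogy length in generations, which
    carries the absolute scale (expected SNP yield = mu * L * mean length).
    """

    proportions: np.ndarray
    mask: np.ndarray
    n: tuple[int, ...]
    mean_total_length: float
    folded: bool
    n_reps: int

    def as_folded_sfs(self) -> FoldedSFS:
        return FoldedSFS(self.proportions, self.n, self.mask)


def expected_sfs(
    model: DemographicModel,
    samples: SampleConfig,
    n_reps: int,
    seed: int,
    fold: bool = True,
    ceiling: float = TIME_CEILING,
) -> ExpectedSFS:
    """Expected (1d or 2d) SFS by branch-length averaging over ``n_reps``
    genealogies; deterministic given ``seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    samp = _samp_array(model, samples)
    args = _compiled(model)
    raw, total, n_failed = _kernels.accumulate_expected_sfs_fast(
        np.int64(seed % (2**31)), n_reps, samp, *args, ceiling
    )
    if n_failed:
        raise CoalescenceTimeoutError(
            f"{n_failed}/{n_reps} genealogies hit the time ceiling"
        )
    n_demes_sampled = int((samp > 0).sum())
    if len(model.demes) == 1 or samp.shape[0] == 1 or samp[1] == 0 or samp[0] == 0:
        # effectively one-dimensional
        vec = raw.sum(axis=1) if samp.shape[0] > 1 and samp[1] == 0 else raw.ravel()
        if samp.shape[0] > 1 and samp[0] == 0:
            vec = raw.sum(axis=0)
        n = int(samp.sum())
        if fold:
            f = fold_sfs(vec)
            props, mask, nn = f.data, f.mask, f.n
        else:
            mask = np.zeros(n + 1, dtype=bool)
            mask[0] = mask[n] = True
            props, nn = vec, (n,)
    else:
        if fold:
            f = fold_joint(raw, pop_names=(model.demes[0], model.demes[1]))
            props, mask, nn = f.data, f.mask, f.n
        else:
            mask = np.zeros_like(raw, dtype=bool)
            mask[0, 0] = True
            mask[samp[0], samp[1]] = True
            props, nn = raw, (int(samp[0]), int(samp[1]))
    s = props[~mask].sum()
    props = np.where(mask, 0.0, props) / s
    return ExpectedSFS(
        proportions=props,
        mask=mask,
        n=nn,
        mean_total_length=float(total / n_reps),
        folded=fold,
        n_reps=n_reps,
    )
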