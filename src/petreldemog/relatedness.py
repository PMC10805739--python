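"""Pairwise relatedness via the nine condensed Jacquard coefficients.

For two diploid individuals the nine condensed identity-by-descent states
(Delta_1..Delta_9) fully describe shared ancestry; given per-locus allele
frequencies, each state implies a probability table over the 3 x 3 observed
genotype pairs, so the Deltas can be estimated by EM over loci (the standard
mixture formulation).  Kinship is phi = D1 + (D3 + D5 + D7)/2 + D8/4;
relationship classes come from the usual kinship half-interval bands with
parent-offspring and full sibs separated by Delta_8.  A fixed genotyping
error rate is mixed into the emission table since calls are hard genotypes.

State conventions (condensed Jacquard): D1-D6 involve inbreeding
(within-individual IBD); D7 = two IBD pairs across individuals (e.g.
duplicates/MZ from outbred parents), D8 = one IBD pair (parent-offspring),
D9 = no IBD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .sfs import MISSING, GenotypeMatrix

__all__ = [
    "JacquardEstimate",
    "jacquard_emission_table",
    "pair_jacquard_em",
    "kinship_from_jacquard",
    "classify_pair",
    "pairwise_relatedness",
    "prune_related",
]

MIN_SHARED_LOCI = 50
ERROR_RATE_DEFAULT = 0.005

CLASS_DUPLICATE = "duplicate"
CLASS_PO = "parent-offspring"
CLASS_FULLSIB = "full-sib"
CLASS_SECOND = "2nd-degree"
CLASS_THIRD = "3rd-degree"
CLASS_UNRELATED = "unrelated"


@dataclass
class JacquardEstimate:
    deltas: np.ndarray  # Delta_1..Delta_9, sums to 1
    kinship: float
    relationship: str
    n_loci: int
    log_lik: float
    id1: str = ""
    id2: str = ""

    def __post_init__(self) -> None:
        if abs(self.deltas.sum() - 1.0) > 1e-6:
            raise ValueError("Jacquard coefficients must sum to 1")


def jacquard_emission_table(p: np.ndarray) -> np.ndarray:
    """P(genotype pair | state, p): array (9 states, 9 pairs, L loci).

    Pair index = 3 * g1 + g2 with genotypes coded by alt-allele count.
    ``p`` is the *reference* (allele A) frequency per locus — symmetric
    either way as long as genotype codes count the complementary allele.
    Here we take p = frequency of the allele counted by code 0 (hom ref),
    i.e. code 0 has probability p^2 under HWE.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    L = p.shape[0]
    T = np.zeros((9, 9, L))
    AA, Aa, aa = 0, 1, 2

    def idx(g1, g2):
        return 3 * g1 + g2

    # S1: both inbred, all four alleles IBD
    T[0, idx(AA, AA)] = p
    T[0, idx(aa, aa)] = q
    # S2: both inbred, no IBD across
    T[1, idx(AA, AA)] = p * p
    T[1, idx(AA, aa)] = p * q
    T[1, idx(aa, AA)] = q * p
    T[1, idx(aa, aa)] = q * q
    # S3: ind1 inbred, shares one allele IBD with ind2
    T[2, idx(AA, AA)] = p * p
    T[2, idx(AA, Aa)] = p * q
    T[2, idx(aa, Aa)] = q * p
    T[2, idx(aa, aa)] = q * q
    # S4: ind1 inbred, no IBD across (ind2 HWE)
    T[3, idx(AA, AA)] = p * p * p
    T[3, idx(AA, Aa)] = p * 2 * p * q
    T[3, idx(AA, aa)] = p * q * q
    T[3, idx(aa, AA)] = q * p * p
    T[3, idx(aa, Aa)] = q * 2 * p * q
    T[3, idx(aa, aa)] = q * q * q
    # S5: mirror of S3 (ind2 inbred, shares one with ind1)
    T[4, idx(AA, AA)] = p * p
    T[4, idx(Aa, AA)] = p * q
    T[4, idx(Aa, aa)] = q * p
    T[4, idx(aa, aa)] = q * q
    # S6: mirror of S4
    T[5, idx(AA, AA)] = p * p * p
    T[5, idx(Aa, AA)] = p * 2 * p * q
    T[5, idx(aa, AA)] = p * q * q
    T[5, idx(AA, aa)] = q * p * p
    T[5, idx(Aa, aa)] = q * 2 * p * q
    T[5, idx(aa, aa)] = q * q * q
    # S7: two IBD pairs across (outbred duplicate / MZ)
    T[6, idx(AA, AA)] = p * p
    T[6, idx(Aa, Aa)] = 2 * p * q
    T[6, idx(aa, aa)] = q * q
    # S8: one IBD pair across (outbred parent-offspring pattern)
    T[7, idx(AA, AA)] = p**3
    T[7, idx(AA, Aa)] = p * p * q
    T[7, idx(Aa, AA)] = p * p * q
    T[7, idx(Aa, Aa)] = p * q  # shared A: p q q ; shared a: q p p
    T[7, idx(Aa, aa)] = p * q * q
    T[7, idx(aa, Aa)] = p * q * q
    T[7, idx(aa, aa)] = q**3
    # S9: independent HWE genotypes
    hw = np.stack([p * p, 2 * p * q, q * q])
    for g1 in range(3):
        for g2 in range(3):
            T[8, idx(g1, g2)] = hw[g1] * hw[g2]
    return T


def _with_error(T: np.ndarray, eps: float) -> np.ndarray:
    """Mix a per-genotype uniform miscall (rate eps) into both individuals."""
    if eps <= 0:
        return T
    E = np.full((3, 3), eps / 2.0)
    np.fill_diagonal(E, 1.0 - eps)
    M = np.kron(E, E)  # (9 pairs true) -> (9 pairs observed)
    return np.einsum("ot,stl->sol", M.T, T)


def kinship_from_jacquard(deltas: np.ndarray) -> float:
    """phi = D1 + (D3 + D5 + D7) / 2 + D8 / 4."""
    d = np.asarray(deltas, dtype=float)
    return float(d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7])


def classify_pair(est: JacquardEstimate) -> str:
    """Kinship half-interval bands; PO vs full-sib split by Delta_8."""
    phi = est.kinship
    if phi > 0.354:
        return CLASS_DUPLICATE
    if phi > 0.177:
        return CLASS_PO if est.deltas[7] > 0.8 else CLASS_FULLSIB
    if phi > 0.0884:
        return CLASS_SECOND
    if phi > 0.0442:
        return CLASS_THIRD
    return CLASS_UNRELATED


def pair_jacquard_em(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    error_rate: float = ERROR_RATE_DEFAULT,
    emission_table: np.ndarray | None = None,
) -> JacquardEstimate:
    """EM estimate of Delta_1..Delta_9 for one pair.

    ``freqs`` are per-locus alternate-allele frequencies in (0, 1); loci
    where either call is missing are dropped (>= 50 shared loci required).
    The log-likelihood is monotone non-decreasing across iterations;
    initialization is the uniform Delta = 1/9.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    freqs = np.asarray(freqs, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING) & (freqs > 0) & (freqs < 1)
    g1, g2 = g1[ok], g2[ok]
    L = len(g1)
    if L < MIN_SHARED_LOCI:
        raise ValueError(f"only {L} loci with both calls; need >= {MIN_SHARED_LOCI}")
    if emission_table is None:
        # code 0 = hom ref has probability p_ref^2
        T = _with_error(jacquard_emission_table(1.0 - freqs[ok]), error_rate)
    else:
        T = emission_table[:, :, ok]
    pair_idx = 3 * g1.astype(int) + g2.astype(int)
    # E[s, l] = P(observed pair at locus l | state s)
    E = T[:, pair_idx, np.arange(L)]
    E = np.maximum(E, 1e-300)
    deltas = np.full(9, 1.0 / 9.0)
    ll_prev = -math.inf
    for _ in range(max_iter):
        mix = deltas[:, None] * E
        tot = mix.sum(axis=0)
        ll = float(np.log(tot).sum())
        w = mix / tot
        deltas = w.mean(axis=1)
        if ll - ll_prev < tol and ll >= ll_prev:
            ll_prev = ll
            break
        ll_prev = ll
    deltas = deltas / deltas.sum()
    phi = kinship_from_jacquard(deltas)
    est = JacquardEstimate(
        deltas=deltas, kinship=phi, relationship="", n_loci=L, log_lik=ll_prev
    )
    est.relationship = classify_pair(est)
    return est


def pairwise_relatedness(
    G: GenotypeMatrix,
    error_rate: float = ERROR_RATE_DEFAULT,
    min_maf: float = 0.01,
    max_iter: int = 300,
) -> pd.DataFrame:
    """All-pairs Jacquard table (id1, id2, D1..D9, phi, class, n_loci).

    Allele frequencies are computed from all samples (the estimator's
    standard assumption; pooling two diverged colonies biases phi upward
    slightly for cross-colony pairs)."""
    alt, tot = G.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    usable = (freqs > min_maf) & (freqs < 1 - min_maf)
    calls = G.calls[:, usable]
    fr = freqs[usable]
    # the emission table depends only on the frequencies: build once
    table = _with_error(jacquard_emission_table(1.0 - fr), error_rate)
    rows = []
    ids = G.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            est = pair_jacquard_em(
                calls[i], calls[j], fr, error_rate=error_rate,
                emission_table=table, max_iter=max_iter,
            )
            row = {"id1": ids[i], "id2": ids[j]}
            row.update({f"D{k + 1}": est.deltas[k] for k in range(9)})
            row.update(
                {
                    "phi": est.kinship,
                    "class": est.relationship,
                    "n_loci": est.n_loci,
                    "log_lik": est.log_lik,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def prune_related(
    pairs: pd.DataFrame,
    all_ids,
    missingness: dict | None = None,
    first_degree_classes: tuple[str, ...] = (CLASS_DUPLICATE, CLASS_PO, CLASS_FULLSIB),
) -> list[str]:
    """Greedy unrelated subset.

    Build the graph of first-degree (and duplicate) edges; within each
    connected component repeatedly retain the node with the least
    missingness (ties broken by id order) and drop its neighbors.  The
    returned set contains no first-degree edge.
    """
    missingness = missingness or {}
    g = nx.Graph()
    g.add_nodes_from(all_ids)
    for _, row in pairs.iterrows():
        if row["class"] in first_degree_classes:
            g.add_edge(row["id1"], row["id2"])
    retained: list[str] = []
    for comp in nx.connected_components(g):
        comp = set(comp)
        sub = g.subgraph(comp).copy()
        while sub.number_of_nodes():
            best = min(sub.nodes, key=lambda v: (missingness.get(v, 0.0), str(v)))
            retained.append(best)
            drop = set(sub.neighbors(best)) | {best}
            sub.remove_nodes_from(drop)
    return sorted(retained, key=str)
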