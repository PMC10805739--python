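"""Population structure: DAPC-style clustering and Weir-Cockerham F_ST.

Clustering follows the discriminant-analysis-of-principal-components recipe:
allele-frequency-scaled PCA, K-means over candidate K with the number of
clusters chosen by the lowest BIC, then linear discriminant axes fit on the
K-means groups (with the retained PC count chosen by a-score maximization)
whose class posteriors serve as membership proportions.  Migrants are
individuals whose membership to a non-natal cluster reaches the threshold.
Differentiation uses the Weir & Cockerham (1984) theta estimator with
missing-data-aware per-locus sample sizes and a bootstrap-over-loci
significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .sfs import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "FstResult",
    "pca_scores",
    "select_k",
    "assign_memberships",
    "detect_migrants",
    "wc_fst",
    "fst_bootstrap_p",
]


# ----------------------------------------------------------------------
def pca_scores(G: GenotypeMatrix, n_components: int | None = None) -> np.ndarray:
    """Principal-component scores of individuals.

    Missing calls are mean-imputed per locus; loci are centered and scaled
    by the binomial allele-frequency standard deviation sqrt(p(1-p)).
    Scores are deterministic up to sign; signs are fixed so each axis's
    largest-magnitude loading is positive.  By default all components are
    returned: K selection downstream is most stable on the full score
    space (noise spreads over many comparable axes), the standard practice
    for this clustering recipe.
    """
    calls = G.calls.astype(float)
    calls[calls == MISSING] = np.nan
    mean = np.nanmean(calls, axis=0)
    filled = np.where(np.isnan(calls), mean, calls)
    p_hat = mean / 2.0
    sd = np.sqrt(np.maximum(p_hat * (1 - p_hat), 0.0))
    keep = sd > 0
    X = (filled[:, keep] - mean[keep]) / sd[keep]
    rank = min(X.shape) - 1 if min(X.shape) > 1 else 1
    if n_components is None:
        n_components = rank
    if n_components > rank:
        log.warning("pca_scores: truncating to rank %d", rank)
        n_components = rank
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest |loading| positive on each axis
    for a in range(n_components):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    return u[:, :n_components] * s[:n_components]


# ----------------------------------------------------------------------
@dataclass
class ClusterModel:
    """K-means/BIC clustering plus discriminant memberships."""

    k: int
    assignment: np.ndarray  # hard labels, argmax of memberships
    memberships: np.ndarray  # (n, k), rows sum to 1
    bic_table: pd.DataFrame  # columns: K, BIC, WSS
    n_pcs: int | None = None

    def __post_init__(self) -> None:
        if self.memberships.ndim != 2:
            raise ValueError("memberships must be 2d")
        row = self.memberships.sum(axis=1)
        if not np.allclose(row, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")


def _kmeans_bic(scores: np.ndarray, k: int, n_starts: int, seed: int) -> tuple[float, np.ndarray]:
    n = scores.shape[0]
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(scores)
    wss = km.inertia_
    if wss <= 0:
        return -np.inf, labels
    bic = n * np.log(wss / n) + k * np.log(n)
    return bic, labels


def select_k(
    scores: np.ndarray, k_max: int = 5, n_starts: int = 20, seed: int = 0
) -> ClusterModel:
    """Choose K in 1..k_max by the lowest BIC over K-means solutions.

    BIC(K) = n ln(WSS_K / n) + K ln(n).  Degenerate inputs (duplicated
    points driving WSS to 0) cap K at the number of distinct points.
    """
    n = scores.shape[0]
    n_distinct = len(np.unique(scores.round(12), axis=0))
    rows = []
    best = None
    for k in range(1, min(k_max, n_distinct) + 1):
        bic, labels = _kmeans_bic(scores, k, n_starts, seed)
        rows.append({"K": k, "BIC": bic})
        if np.isinf(bic):
            continue
        if best is None or bic < best[0]:
            best = (bic, k, labels)
    if best is None:  # all candidate K degenerate: single cluster
        best = (np.nan, 1, np.zeros(n, dtype=int))
    _, k_star, labels = best
    memberships = np.zeros((n, k_star))
    memberships[np.arange(n), labels] = 1.0
    return ClusterModel(
        k=k_star,
        assignment=labels,
        memberships=memberships,
        bic_table=pd.DataFrame(rows),
    )


def _a_score(
    scores: np.ndarray, labels: np.ndarray, n_pcs: int, rng: np.random.Generator,
    n_perm: int = 10,
) -> float:
    """Reassignment-proportion gain of an LDA on n_pcs over label permutation."""
    lda = LinearDiscriminantAnalysis()
    X = scores[:, :n_pcs]
    obs = (lda.fit(X, labels).predict(X) == labels).mean()
    perm = 0.0
    for _ in range(n_perm):
        shuffled = rng.permutation(labels)
        perm += (lda.fit(X, shuffled).predict(X) == shuffled).mean()
    return obs - perm / n_perm


def assign_memberships(
    scores: np.ndarray,
    k: int,
    seed: int = 0,
    labels: np.ndarray | None = None,
    n_perm: int = 10,
    n_starts: int = 20,
) -> ClusterModel:
    """Discriminant memberships for K groups.

    Groups come from K-means (or are supplied); the number of leading PCs
    retained for the discriminant axes maximizes the a-score (observed LDA
    reassignment rate minus its label-permutation expectation, guarding
    against overfitting the discriminant space).  Memberships are the LDA
    class posteriors.
    """
    n = scores.shape[0]
    if k == 1:
        return ClusterModel(
            k=1,
            assignment=np.zeros(n, dtype=int),
            memberships=np.ones((n, 1)),
            bic_table=pd.DataFrame([{"K": 1, "BIC": np.nan}]),
            n_pcs=scores.shape[1],
        )
    rng = np.random.default_rng(seed)
    if labels is None:
        _, labels = _kmeans_bic(scores, k, n_starts, seed)
    candidates = [p for p in (1, 2, 3, 5, 10, 20, 40) if p <= scores.shape[1]]
    best_pcs = max(candidates)
    best_score = -np.inf
    for p in candidates:
        try:
            a = _a_score(scores, labels, p, rng, n_perm=n_perm)
        except np.linalg.LinAlgError:
            continue
        if a > best_score:
            best_score, best_pcs = a, p
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores[:, :best_pcs], labels)
    memberships = lda.predict_proba(scores[:, :best_pcs])
    return ClusterModel(
        k=k,
        assignment=np.argmax(memberships, axis=1),
        memberships=memberships,
        bic_table=pd.DataFrame([{"K": k, "BIC": np.nan}]),
        n_pcs=best_pcs,
    )


def detect_migrants(
    memberships: np.ndarray,
    natal_cluster: np.ndarray,
    ids=None,
    threshold: float = 0.5,
) -> list:
    """Individuals whose membership to any non-natal cluster is >= threshold
    (ties count as flagged)."""
    memberships = np.asarray(memberships)
    natal = np.asarray(natal_cluster, dtype=int)
    if natal.shape[0] != memberships.shape[0]:
        raise ValueError("natal labels must align with membership rows")
    ids = list(ids) if ids is not None else list(range(memberships.shape[0]))
    out = []
    for i in range(memberships.shape[0]):
        other = np.delete(memberships[i], natal[i])
        if other.size and other.max() >= threshold:
            out.append(ids[i])
    return out


# ----------------------------------------------------------------------
@dataclass
class FstResult:
    theta: float
    n_bootstrap: int
    p_value: float
    bootstrap_thetas: np.ndarray = field(default_factory=lambda: np.empty(0))


def _wc_components(G: GenotypeMatrix, pop_labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components (a, a+b+c)."""
    labels = np.asarray(pop_labels)
    pops = np.unique(labels)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    calls = G.calls
    # per-pop per-locus sample sizes (diploids with data), allele freqs, het freqs
    n_i = np.zeros((r, G.n_loci))
    p_i = np.zeros((r, G.n_loci))
    h_i = np.zeros((r, G.n_loci))
    for ii, pop in enumerate(pops):
        sub = calls[labels == pop]
        obs = sub != MISSING
        n_i[ii] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[ii] = np.where(obs, sub, 0).sum(axis=0) / (2 * np.maximum(n_i[ii], 1))
            h_i[ii] = (sub == 1).sum(axis=0) / np.maximum(n_i[ii], 1)
    ok = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    n_bar = n_i.mean(axis=0)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    poly = (p_bar > 0) & (p_bar < 1)
    n_i, p_i, h_i, n_bar, p_bar = (
        n_i[:, poly], p_i[:, poly], h_i[:, poly], n_bar[poly], p_bar[poly]
    )
    if n_bar.size == 0:
        raise ValueError("no polymorphic loci shared by the populations")
    nc = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
    a = (n_bar / nc) * (
        s2
        - 1.0
        / (n_bar - 1)
        * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, a + b + c


def wc_fst(G: GenotypeMatrix, pop_labels) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of summed components)."""
    a, denom = _wc_components(G, pop_labels)
    return float(a.sum() / denom.sum())


def fst_bootstrap_p(
    G: GenotypeMatrix, pop_labels, n_boot: int = 10000, seed: int = 0
) -> FstResult:
    """Bootstrap loci with replacement; p = fraction of bootstrap theta <= 0."""
    a, denom = _wc_components(G, pop_labels)
    theta = float(a.sum() / denom.sum())
    rng = np.random.default_rng(seed)
    L = len(a)
    idx = rng.integers(0, L, size=(n_boot, L))
    boot = a[idx].sum(axis=1) / denom[idx].sum(axis=1)
    p = float((boot <= 0).mean())
    return FstResult(theta=theta, n_bootstrap=n_boot, p_value=p, bootstrap_thetas=boot)
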