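"""SNP and individual quality-control cascade with per-step auditing.

Mirrors the in-house filtering of a DArTseq panel: tag-level pruning to one
SNP per sequenced tag, removal of low-call-rate / high-heterozygosity
individuals, per-locus call-rate / reproducibility / read-depth / MAF
filters, sex-linked-marker detection from the ZW system (females
heterozygous, males homozygous at Z-specific SNPs), a PCA-regression outlier
scan, and Hardy-Weinberg filtering stratified by genetic cluster (to avoid
Wahlund artifacts).  Every step reports loci/individuals before and after;
the counts telescope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .sfs import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "run_qc_cascade",
    "hwe_exact_test",
    "hwe_filter",
    "detect_sex_linked",
    "pca_outlier_scan",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filtering thresholds; defaults follow the study's cascade."""

    max_individual_missing: float = 0.20  # drop if missingness > 20%
    max_individual_het: float = 0.13  # drop if heterozygosity >= 13%
    min_locus_call_rate: float = 0.90  # drop if call rate < 90%
    min_rep_avg: float = 0.95  # drop if reproducibility < 95%
    min_depth: float = 10.0  # drop if mean depth < 10x
    max_depth: float = 40.0  # drop if mean depth > 40x
    min_maf: float = 0.01  # drop if MAF < 0.01
    one_snp_per_tag: bool = True
    hwe_alpha: float = 0.05
    outlier_alpha: float = 0.01
    sexlink_concordance: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "max_individual_missing",
            "max_individual_het",
            "min_locus_call_rate",
            "min_rep_avg",
            "min_maf",
            "hwe_alpha",
            "outlier_alpha",
            "sexlink_concordance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")


@dataclass
class QCReport:
    """Per-step audit: (step, loci before/after, individuals before/after)."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name, loci_before, loci_after, ind_before, ind_after, removed_ids):
        self.steps.append(
            {
                "step": name,
                "loci_before": loci_before,
                "loci_after": loci_after,
                "individuals_before": ind_before,
                "individuals_after": ind_after,
                "n_removed": (loci_before - loci_after) + (ind_before - ind_after),
                "removed_ids": list(removed_ids),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in s.items() if k != "removed_ids"} for s in self.steps]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class EmptyCohortError(RuntimeError):
    pass


# ----------------------------------------------------------------------
def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given the genotype counts, conditions on the allele counts and sums the
    probabilities of all heterozygote counts whose conditional probability
    does not exceed the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("invalid genotype counts")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    n_minor = min(n_a, n_b)
    # possible heterozygote counts share parity with the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_hom_a = (n_a - hets) // 2
    n_hom_b = (n_b - hets) // 2
    # Levene's conditional distribution of the heterozygote count
    logp = (
        hets * np.log(2.0)
        + _log_fact(n)
        - _log_fact(n_hom_a)
        - _log_fact(hets)
        - _log_fact(n_hom_b)
        - (_log_fact(2 * n) - _log_fact(n_a) - _log_fact(n_b))
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_ab]
    if len(p_obs) == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(np.minimum(p[p <= p_obs[0] * (1 + 1e-12)].sum(), 1.0))


def _log_fact(x):
    return gammaln(np.asarray(x, dtype=float) + 1.0)


# ----------------------------------------------------------------------
def detect_sex_linked(
    G: GenotypeMatrix, sex_labels=None, concordance: float = 0.95
) -> list[str]:
    """Loci consistent with Z-linkage in >= ``concordance`` of sexed birds.

    With a ZW system a Z-specific SNP makes every female (ZW) heterozygous
    and every male (ZZ) homozygous; a bird is "concordant" when its call
    matches that expectation.  The locus is flagged when the concordant
    fraction over all non-missing sexed calls reaches ``concordance`` and
    both sexes individually lean the right way (strict majority), so one
    miscall among 20 birds still clears a 0.95 threshold.  Unknown-sex
    individuals are ignored.
    """
    if sex_labels is None:
        sex_labels = G.samples.get("sex")
    if sex_labels is None:
        log.warning("detect_sex_linked: no sex labels; returning no loci")
        return []
    sex = np.asarray(sex_labels).astype(str)
    fem = sex == "F"
    mal = sex == "M"
    if fem.sum() < 3 or mal.sum() < 3:
        raise ValueError("need >= 3 labeled individuals of each sex")
    out = []
    calls = G.calls
    for j, lid in enumerate(G.locus_ids):
        cf = calls[fem, j]
        cm = calls[mal, j]
        cf = cf[cf != MISSING]
        cm = cm[cm != MISSING]
        if len(cf) == 0 or len(cm) == 0:
            continue
        n_conc = (cf == 1).sum() + (cm != 1).sum()
        frac = n_conc / (len(cf) + len(cm))
        if frac >= concordance and (cf == 1).mean() > 0.5 and (cm != 1).mean() > 0.5:
            out.append(lid)
    return out


# ----------------------------------------------------------------------
def pca_outlier_scan(
    G: GenotypeMatrix, k_components: int = 2, alpha: float = 0.01
) -> list[str]:
    """PCA-regression outlier scan (pcadapt-style).

    Each locus's (imputed, standardized) genotypes are regressed on the
    first k principal-component scores; the vector of regression z-scores is
    summarized by a Mahalanobis distance, rescaled by the genomic inflation
    factor (median distance over the chi-square median), converted to
    chi-square(k) p-values and Benjamini-Hochberg q-values; loci with
    q < alpha are flagged.  Constant loci are excluded, never flagged.
    """
    calls = G.calls.astype(float)
    calls[calls == MISSING] = np.nan
    mean = np.nanmean(calls, axis=0)
    filled = np.where(np.isnan(calls), mean, calls)
    p_hat = mean / 2.0
    sd = np.sqrt(np.maximum(p_hat * (1 - p_hat), 0.0))
    variable = sd > 0
    if variable.sum() == 0:
        return []
    X = (filled[:, variable] - mean[variable]) / sd[variable]
    n = X.shape[0]
    k = min(k_components, n - 1)
    if k < 1:
        raise ValueError("cannot compute principal components")
    # PC scores of individuals
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    # per-locus multiple regression of genotype on scores; z = t-statistics
    q, _ = np.linalg.qr(scores)
    proj = q.T @ X  # (k, L)
    resid_ss = (X**2).sum(axis=0) - (proj**2).sum(axis=0)
    df = max(n - k - 1, 1)
    sigma2 = np.maximum(resid_ss / df, 1e-12)
    z = proj / np.sqrt(sigma2)
    # Mahalanobis across the k z-scores
    zc = z - z.mean(axis=1, keepdims=True)
    cov = np.cov(zc) if k > 1 else np.array([[zc.var()]])
    cov = np.atleast_2d(cov)
    d2 = np.einsum("ij,ij->j", np.linalg.solve(cov, zc), zc)
    gif = np.median(d2) / stats.chi2.median(df=k)
    pvals = stats.chi2.sf(d2 / max(gif, 1e-12), df=k)
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    flagged = np.asarray(G.locus_ids)[variable][qvals < alpha]
    return list(flagged)


# ----------------------------------------------------------------------
def hwe_filter(
    G: GenotypeMatrix, cluster_labels, alpha: float = 0.05
) -> list[str]:
    """Loci out of Hardy-Weinberg equilibrium within *every* cluster.

    The exact test runs within each cluster (testing within clusters avoids
    flagging loci whose pooled heterozygote deficit is a Wahlund artifact of
    population structure); a locus is dropped only when significant in all
    clusters at the Bonferroni-adjusted level alpha / n_loci.
    """
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != G.n_samples:
        raise ValueError("cluster labels must align with samples")
    clusters = np.unique(labels)
    thr = alpha / max(G.n_loci, 1)
    out = []
    for j, lid in enumerate(G.locus_ids):
        sig_all = True
        for c in clusters:
            calls = G.calls[labels == c, j]
            calls = calls[calls != MISSING]
            if len(calls) == 0:
                sig_all = False
                break
            n_aa = int((calls == 0).sum())
            n_ab = int((calls == 1).sum())
            n_bb = int((calls == 2).sum())
            if hwe_exact_test(n_aa, n_ab, n_bb) >= thr:
                sig_all = False
                break
        if sig_all:
            out.append(lid)
    return out


# ----------------------------------------------------------------------
def run_qc_cascade(
    G: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    drop_trimmed: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """The full ordered cascade; deterministic given ``seed``.

    Order: trimmed-tag flag, one SNP per tag (uniform random within tag),
    individual missingness/heterozygosity, monomorphic loci, locus metadata
    bounds (call rate, reproducibility, depth), MAF, sex-linked loci,
    PCA outliers.  Cluster-stratified HWE filtering runs separately after
    clustering (see :func:`hwe_filter`).
    """
    thr = thresholds or QCThresholds()
    rng = np.random.default_rng(seed)
    report = QCReport()

    def record(name, G_before, G_after, removed):
        report.add(
            name,
            G_before.n_loci,
            G_after.n_loci,
            G_before.n_samples,
            G_after.n_samples,
            removed,
        )

    # 1. trimmed-tag flag
    if drop_trimmed and "trimmed" in G.loci:
        keep = ~G.loci["trimmed"].astype(bool).to_numpy()
        G2 = G.take_loci(keep)
        record("trimmed_tag", G, G2, list(np.asarray(G.locus_ids)[~keep]))
        G = G2
    else:
        record("trimmed_tag", G, G, [])

    # 2. one SNP per tag (random choice, logged via seed)
    if thr.one_snp_per_tag and "tag_id" in G.loci:
        keep_mask = np.zeros(G.n_loci, dtype=bool)
        tags = G.loci["tag_id"].to_numpy()
        for t in pd.unique(tags):
            idx = np.flatnonzero(tags == t)
            keep_mask[rng.choice(idx)] = True
        G2 = G.take_loci(keep_mask)
        record("one_snp_per_tag", G, G2, list(np.asarray(G.locus_ids)[~keep_mask]))
        G = G2
    else:
        record("one_snp_per_tag", G, G, [])

    # 3. individuals: missingness > 20% or heterozygosity >= 13%
    miss = G.sample_missingness()
    het = G.sample_heterozygosity()
    keep_ind = (miss <= thr.max_individual_missing) & (het < thr.max_individual_het)
    if keep_ind.sum() == 0:
        raise EmptyCohortError("all individuals removed by missingness/het filters")
    G2 = G.take_samples(keep_ind)
    record("individuals", G, G2, list(np.asarray(G.sample_ids)[~keep_ind]))
    G = G2

    # 4. monomorphic loci arising from removals
    keep = ~G.is_monomorphic()
    G2 = G.take_loci(keep)
    record("monomorphic", G, G2, list(np.asarray(G.locus_ids)[~keep]))
    G = G2

    # 5. locus metadata bounds (strict inequalities per the stated rules:
    # call rate *lower than* 90%, reproducibility *below* 95%, depth
    # *lower than* 10x or *higher than* 40x)
    keep = np.ones(G.n_loci, dtype=bool)
    if "call_rate" in G.loci:
        keep &= ~(G.loci["call_rate"].to_numpy() < thr.min_locus_call_rate)
    if "rep_avg" in G.loci:
        keep &= ~(G.loci["rep_avg"].to_numpy() < thr.min_rep_avg)
    if "avg_read_depth" in G.loci:
        depth = G.loci["avg_read_depth"].to_numpy()
        keep &= ~(depth < thr.min_depth) & ~(depth > thr.max_depth)
    G2 = G.take_loci(keep)
    record("locus_metadata", G, G2, list(np.asarray(G.locus_ids)[~keep]))
    G = G2

    # 6. MAF < 0.01
    maf = G.minor_allele_freq()
    keep = ~(maf < thr.min_maf)
    G2 = G.take_loci(keep)
    record("maf", G, G2, list(np.asarray(G.locus_ids)[~keep]))
    G = G2

    # 7. sex-linked loci
    try:
        sexlinked = detect_sex_linked(G, concordance=thr.sexlink_concordance)
    except ValueError:
        sexlinked = []
    keep = ~np.isin(G.locus_ids, sexlinked)
    G2 = G.take_loci(keep)
    record("sex_linked", G, G2, sexlinked)
    G = G2

    # 8. PCA outliers
    try:
        outliers = pca_outlier_scan(G, k_components=2, alpha=thr.outlier_alpha)
    except ValueError:
        outliers = []
    keep = ~np.isin(G.locus_ids, outliers)
    G2 = G.take_loci(keep)
    record("pca_outliers", G, G2, outliers)
    G = G2

    return G, report
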