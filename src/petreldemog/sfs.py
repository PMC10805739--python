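"""Genotype container and site-frequency-spectrum machinery.

The :class:`GenotypeMatrix` (individuals x biallelic loci, diploid calls
coded 0/1/2 with -1 for missing) is the lingua franca of the pipeline.  This
module reads/writes VCF and "DArT-lite" CSV, builds 1d/2d spectra with
hypergeometric projection over missing data, folds spectra to minor-allele
orientation, and serializes them in fastsimcoal-obs or dadi dialects.

Internally loci use 0-based coordinates; VCF I/O converts to/from 1-based.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "FoldedSFS",
    "read_vcf",
    "write_vcf",
    "read_dart_csv",
    "write_dart_csv",
    "fold_sfs",
    "fold_joint",
    "project_sfs",
    "genotypes_to_sfs",
    "suggest_projection",
    "write_sfs",
    "read_sfs",
]


# ----------------------------------------------------------------------
@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with aligned sample and locus metadata.

    ``calls[i, j]`` is the count of alternate alleles for sample ``i`` at
    locus ``j`` (0 hom ref, 1 het, 2 hom alt, -1 missing).  ``samples`` and
    ``loci`` are DataFrames indexed by id; sample metadata typically carries
    ``colony`` (RDC/RIR/GB/other), ``sex`` (F/M/unknown) and ``year``; locus
    metadata carries ``tag_id``, ``chrom``, ``pos`` (1-based), ``call_rate``,
    ``rep_avg`` and ``avg_read_depth``.
    """

    calls: np.ndarray
    samples: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2d (samples x loci)")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match metadata "
                f"({len(self.samples)} samples, {len(self.loci)} loci)"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,missing}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci.index)

    def take_samples(self, mask_or_ids) -> "GenotypeMatrix":
        idx = self._sample_indexer(mask_or_ids)
        return GenotypeMatrix(self.calls[idx], self.samples.iloc[idx].copy(), self.loci.copy())

    def take_loci(self, mask_or_ids) -> "GenotypeMatrix":
        idx = self._locus_indexer(mask_or_ids)
        return GenotypeMatrix(self.calls[:, idx], self.samples.copy(), self.loci.iloc[idx].copy())

    def _sample_indexer(self, sel) -> np.ndarray:
        return _as_indexer(sel, self.samples.index)

    def _locus_indexer(self, sel) -> np.ndarray:
        return _as_indexer(sel, self.loci.index)

    # -- summaries ------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def sample_heterozygosity(self) -> np.ndarray:
        """Observed per-individual heterozygosity over non-missing calls."""
        obs = self.calls != MISSING
        het = self.calls == 1
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / obs.sum(axis=1), 0.0)

    def allele_counts(self, sample_mask=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alt allele count, called haploid count)."""
        calls = self.calls if sample_mask is None else self.calls[sample_mask]
        obs = calls != MISSING
        alt = np.where(obs, calls, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * obs.sum(axis=0).astype(np.int64)

    def minor_allele_freq(self, sample_mask=None) -> np.ndarray:
        alt, tot = self.allele_counts(sample_mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.fmin(p, 1 - p)

    def is_monomorphic(self) -> np.ndarray:
        alt, tot = self.allele_counts()
        return (alt == 0) | (alt == tot)


def _as_indexer(sel, index: pd.Index) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        return np.flatnonzero(sel)
    if np.issubdtype(sel.dtype, np.integer):
        return sel
    return index.get_indexer(sel)


# ----------------------------------------------------------------------
@dataclass
class FoldedSFS:
    """1d or 2d minor-allele spectrum with masked monomorphic corner(s).

    1d: ``data`` has length ``n//2 + 1`` indexed by minor-allele count; entry
    0 (the monomorphic corner) is masked.  2d: ``data`` is the full
    ``(n1+1) x (n2+1)`` joint matrix in minor (pooled-frequency) orientation;
    the (0, 0) and (n1, n2) corners are masked.
    """

    data: np.ndarray
    n: tuple[int, ...]
    mask: np.ndarray
    pop_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("data/mask shape mismatch")
        if (self.data[~self.mask] < -1e-9).any():
            raise ValueError("negative SFS entries")

    @property
    def dimension(self) -> int:
        return len(self.n)

    def total(self) -> float:
        return float(self.data[~self.mask].sum())

    def proportions(self) -> np.ndarray:
        out = np.where(self.mask, 0.0, self.data)
        tot = out.sum()
        return out / tot if tot > 0 else out


# ----------------------------------------------------------------------
def fold_sfs(unfolded: np.ndarray) -> FoldedSFS:
    """Fold an unfolded 1d spectrum of length n+1 (monomorphic ends included).

    Minor-allele class i receives xi_i + xi_{n-i} for i < n/2 and xi_{n/2}
    unchanged when n is even; the masked corner collects xi_0 + xi_n.
    """
    unfolded = np.asarray(unfolded, dtype=float)
    n = len(unfolded) - 1
    if n < 1:
        raise ValueError("need length >= 2 (n >= 1)")
    half = n // 2
    folded = np.zeros(half + 1)
    folded[0] = unfolded[0] + unfolded[n]
    for i in range(1, half + 1):
        if i < n - i:
            folded[i] = unfolded[i] + unfolded[n - i]
        else:
            folded[i] = unfolded[i]
    mask = np.zeros(half + 1, dtype=bool)
    mask[0] = True
    return FoldedSFS(folded, (n,), mask)


def fold_joint(unfolded: np.ndarray, pop_names: tuple[str, str] = ("pop1", "pop2")) -> FoldedSFS:
    """Fold a joint (n1+1) x (n2+1) spectrum by pooled minor-allele frequency.

    A cell (i, j) with pooled count i + j above (n1+n2)/2 is reflected to
    (n1-i, n2-j); ties (pooled frequency exactly one half) keep the
    reference orientation.  Corners (0,0) and (n1,n2) are masked.
    """
    unfolded = np.asarray(unfolded, dtype=float)
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    n = n1 + n2
    folded = np.zeros_like(unfolded)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if i + j > n - (i + j):
                folded[n1 - i, n2 - j] += unfolded[i, j]
            else:
                folded[i, j] += unfolded[i, j]
    mask = np.zeros_like(folded, dtype=bool)
    mask[0, 0] = True
    mask[n1, n2] = True
    return FoldedSFS(folded, (n1, n2), mask, pop_names=tuple(pop_names))


def project_sfs(counts: np.ndarray, m: int) -> tuple[np.ndarray, float]:
    """Hypergeometric projection of an unfolded spectrum from size n to m.

    Returns ``(projected, lost_to_monomorphic)``: class j at size m receives
    ``sum_i S_i * C(i,j) C(n-i, m-j) / C(n,m)``; mass landing in the
    monomorphic classes j in {0, m} is reported separately (and kept in the
    returned array's end entries).
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts) - 1
    if m > n:
        raise ValueError(f"projection target {m} exceeds sample size {n}")
    if m < 2:
        raise ValueError("projection target must be >= 2")
    if m == n:
        return counts.copy(), float(counts[0] + counts[n])
    proj = np.zeros(m + 1)
    j = np.arange(m + 1)
    for i, s in enumerate(counts):
        if s == 0:
            continue
        proj += s * hypergeom.pmf(j, n, i, m)
    lost = float(proj[0] + proj[m])
    return proj, lost


def _projection_weights(n: int, i: int, m: int) -> np.ndarray:
    return hypergeom.pmf(np.arange(m + 1), n, i, m)


def genotypes_to_sfs(
    G: GenotypeMatrix,
    pop_map: Mapping[str, Sequence[str]],
    fold: bool = True,
    projection: Mapping[str, int] | None = None,
) -> FoldedSFS:
    """Build a 1d or 2d spectrum from genotypes.

    ``pop_map`` maps population name -> sample ids (1 or 2 populations).
    With ``projection`` (per-pop haploid targets) each SNP contributes its
    hypergeometric expectation at the target size; SNPs with fewer
    non-missing haploids than the target contribute nothing.  Without
    projection the target is the full haploid size of each population.
    Folding (minor-allele orientation) is applied last; the unfolded spectrum
    is returned (with monomorphic corners masked) when ``fold=False``.
    """
    pops = list(pop_map)
    if not 1 <= len(pops) <= 2:
        raise ValueError("pop_map must name one or two populations")
    sample_idx = [G._sample_indexer(list(pop_map[p])) for p in pops]
    for p, idx in zip(pops, sample_idx):
        if len(idx) == 0:
            raise ValueError(f"population {p!r} is empty")

    targets = []
    for p, idx in zip(pops, sample_idx):
        t = 2 * len(idx) if projection is None else int(projection[p])
        if t < 2:
            raise ValueError(f"projection target for {p!r} must be >= 2")
        if t > 2 * len(idx):
            raise ValueError(f"projection target {t} for {p!r} exceeds 2x diploids")
        targets.append(t)

    alt = []
    called = []
    for idx in sample_idx:
        calls = G.calls[idx]
        obs = calls != MISSING
        alt.append(np.where(obs, calls, 0).sum(axis=0))
        called.append(2 * obs.sum(axis=0))

    if len(pops) == 1:
        m = targets[0]
        out = np.zeros(m + 1)
        for a, nn in zip(alt[0], called[0]):
            if nn < m:
                continue
            out += _projection_weights(nn, a, m)
        mask = np.zeros(m + 1, dtype=bool)
        mask[0] = mask[m] = True
        if fold:
            return fold_sfs(out)
        return FoldedSFS(out, (m,), mask, pop_names=(pops[0],))

    m1, m2 = targets
    out = np.zeros((m1 + 1, m2 + 1))
    for a1, n1, a2, n2 in zip(alt[0], called[0], alt[1], called[1]):
        if n1 < m1 or n2 < m2:
            continue
        w1 = _projection_weights(n1, a1, m1)
        w2 = _projection_weights(n2, a2, m2)
        out += np.outer(w1, w2)
    if fold:
        return fold_joint(out, pop_names=(pops[0], pops[1]))
    mask = np.zeros_like(out, dtype=bool)
    mask[0, 0] = True
    mask[m1, m2] = True
    return FoldedSFS(out, (m1, m2), mask, pop_names=(pops[0], pops[1]))


def suggest_projection(G: GenotypeMatrix, pop: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Expected polymorphic-site yield per candidate (even) projection target.

    Returns a table ``(target, expected_segregating)`` and the argmax target.
    """
    idx = G._sample_indexer(list(pop))
    if len(idx) < 2:
        raise ValueError("population needs at least 2 diploids")
    calls = G.calls[idx]
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0)
    called = 2 * obs.sum(axis=0)
    rows = []
    for m in range(2, 2 * len(idx) + 1, 2):
        tot = 0.0
        for a, nn in zip(alt, called):
            if nn < m:
                continue
            tot += 1.0 - hypergeom.pmf(0, nn, a, m) - hypergeom.pmf(m, nn, a, m)
        rows.append((m, tot))
    table = pd.DataFrame(rows, columns=["target", "expected_segregating"])
    best = int(table.loc[table["expected_segregating"].idxmax(), "target"])
    return table, best


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------
def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF v4.2 (GT-only, '.' for missing alleles)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=synthetic>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        loci = G.loci
        for j, lid in enumerate(G.locus_ids):
            chrom = str(loci["chrom"].iloc[j]) if "chrom" in loci else "synthetic"
            pos = int(loci["pos"].iloc[j]) if "pos" in loci else j + 1
            ref = str(loci["ref"].iloc[j]) if "ref" in loci else "A"
            alt = str(loci["alt"].iloc[j]) if "alt" in loci else "T"
            gts = "\t".join(gt_strings[int(c)] for c in G.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t{lid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; the number of rejected multiallelic
    rows is logged.  Missing genotypes map to the missing code.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = []
    meta = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 hom ref, 1 het, 2 unknown, 3 hom alt
        gt = var.gt_types.astype(np.int8)
        row = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt))
        rows.append(row)
        meta.append(
            {
                "locus_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if n_multi:
        log.warning("read_vcf: dropped %d multiallelic site(s)", n_multi)
    loci = pd.DataFrame(meta).set_index("locus_id") if meta else pd.DataFrame(
        index=pd.Index([], name="locus_id"), columns=["chrom", "pos", "ref", "alt"]
    )
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame(index=pd.Index(sample_ids, name="id"))
    return GenotypeMatrix(calls, samples, loci)


# ----------------------------------------------------------------------
# DArT-lite CSV I/O
# ----------------------------------------------------------------------
_DART_META_COLS = ["tag_id", "chrom", "pos", "ref", "alt", "call_rate", "rep_avg", "avg_read_depth"]


def write_dart_csv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(index=G.loci.index.rename("locus_id"))
    for col in _DART_META_COLS:
        df[col] = G.loci[col] if col in G.loci else np.nan
    codes = np.where(G.calls == MISSING, "-", G.calls.astype(str))
    for i, sid in enumerate(G.sample_ids):
        df[sid] = codes[i]
    df.to_csv(path)


def read_dart_csv(path, metadata_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="locus_id")
    sample_cols = [c for c in df.columns if c not in _DART_META_COLS]
    loci = df[[c for c in _DART_META_COLS if c in df.columns]].copy()
    raw = df[sample_cols].astype(str).to_numpy().T
    calls = np.where(raw == "-", MISSING, raw)
    calls = np.vectorize(lambda x: MISSING if x in ("-", str(MISSING)) else int(x))(calls).astype(np.int8)
    samples = pd.DataFrame(index=pd.Index(sample_cols, name="id"))
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col="id")
        samples = meta.reindex(samples.index)
    return GenotypeMatrix(calls, samples, loci)


# ----------------------------------------------------------------------
# SFS file dialects
# ----------------------------------------------------------------------
def write_sfs(sfs: FoldedSFS, path, dialect: str = "fastsimcoal-obs") -> None:
    if dialect == "fastsimcoal-obs":
        _write_fsc(sfs, path)
    elif dialect == "dadi":
        _write_dadi(sfs, path)
    else:
        raise ValueError(f"unknown SFS dialect {dialect!r}")


def _write_fsc(sfs: FoldedSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        if sfs.dimension == 1:
            labels = " ".join(f"d0_{i}" for i in range(len(sfs.data)))
            fh.write(labels + "\n")
            fh.write(" ".join(_fmt(v) for v in sfs.data) + "\n")
        else:
            n1, n2 = sfs.n
            fh.write("\t" + "\t".join(f"d1_{j}" for j in range(n2 + 1)) + "\n")
            for i in range(n1 + 1):
                fh.write(f"d0_{i}\t" + "\t".join(_fmt(v) for v in sfs.data[i]) + "\n")


def _write_dadi(sfs: FoldedSFS, path) -> None:
    with open(path, "w") as fh:
        shape = " ".join(str(s) for s in sfs.data.shape)
        fh.write(f"{shape} folded\n")
        fh.write(" ".join(_fmt(v) for v in sfs.data.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def _fmt(v: float) -> str:
    return f"{v:.10g}"


def read_sfs(path, dialect: str = "fastsimcoal-obs") -> FoldedSFS:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if dialect == "dadi":
        head = lines[0].split()
        shape = tuple(int(x) for x in head[:-1]) if head[-1] == "folded" else tuple(
            int(x) for x in head
        )
        data = np.array([float(x) for x in lines[1].split()]).reshape(shape)
        mask = np.array([x == "1" for x in lines[2].split()]).reshape(shape)
        n = tuple(s - 1 if len(shape) > 1 else 2 * (s - 1) for s in shape)
        if len(shape) == 1:
            n = (2 * (shape[0] - 1),)
        return FoldedSFS(data, n, mask)
    if dialect == "fastsimcoal-obs":
        if lines[1].lstrip().startswith("d1_") or lines[1].startswith("\t"):
            cols = lines[1].split()
            n2 = len(cols) - 1
            rows = []
            for ln in lines[2:]:
                if not ln.strip():
                    continue
                parts = ln.split()
                rows.append([float(x) for x in parts[1:]])
            data = np.array(rows)
            n1 = data.shape[0] - 1
            mask = np.zeros_like(data, dtype=bool)
            mask[0, 0] = mask[n1, n2] = True
            return FoldedSFS(data, (n1, n2), mask)
        data = np.array([float(x) for x in lines[2].split()])
        mask = np.zeros(len(data), dtype=bool)
        mask[0] = True
        # folded 1d of length n//2+1: n is even 2*(len-1) by convention
        return FoldedSFS(data, (2 * (len(data) - 1),), mask)
    raise ValueError(f"unknown SFS dialect {dialect!r}")
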