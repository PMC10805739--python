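"""Synthetic study bundles emulating a two-colony DArTseq campaign.

Generates genotypes under a specified demographic history (default: the
fitted ancient-and-recent-bottlenecks history M7 at its reported point
estimates) with the study's sample design — breeders from the two colonies
plus light-grounded birds drawn from the RDC deme — then layers on the
nuisance structure the QC and relatedness stages must handle: per-locus
call-rate / reproducibility / read-depth metadata (with a configurable
fraction failing each filter), random missingness, planted related pairs
built by Mendelian transmission, sex-linked loci appended on a synthetic Z
chromosome, and multi-SNP tags.  A TruthLog records everything planted so
downstream stages can be scored by recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .demography import DemographicModel, SampleConfig
from .models import M7_TRUTH, define_models
from .sfs import MISSING, GenotypeMatrix, write_dart_csv, write_vcf
from .simulate import expected_sfs, simulate_genotypes

__all__ = ["StudyConfig", "TruthLog", "generate_study", "write_study"]


@dataclass
class StudyConfig:
    """Study design knobs; defaults reproduce the source study's design."""

    model: DemographicModel | None = None  # default: M7 at reported estimates
    n_rdc: int = 31  # RDC breeders
    n_rir: int = 37  # RIR breeders
    n_grounded: int = 19  # light-grounded birds (drawn from the RDC deme)
    n_snps: int = 10000
    missingness: float = 0.03  # extra random missing-call rate
    # planted structure
    related_pairs: tuple[tuple[str, str], ...] = ()  # (colony, class) pairs,
    # class in {"parent-offspring", "full-sib"}
    n_sex_linked: int = 0
    sex_ratio: float = 0.5  # P(female)
    # per-locus metadata distributions; defaults put ~8% of loci below each
    # QC rule so every filter is exercised
    call_rate_beta: tuple[float, float] = (40.0, 2.2)
    rep_avg_beta: tuple[float, float] = (70.0, 1.6)
    depth_lognorm: tuple[float, float] = (3.0, 0.35)  # (mean log, sd log)
    frac_multi_snp_tags: float = 0.1
    genotype_error: float = 0.0  # per-call miscall rate (sex-linked included)

    def total_samples(self) -> int:
        return self.n_rdc + self.n_rir + self.n_grounded


@dataclass
class TruthLog:
    """Ground truth for scoring downstream recovery."""

    model_label: str
    model_params: dict
    colony_of: dict  # id -> deme of origin (grounded birds: RDC)
    sex_of: dict
    related_pairs: list  # (id1, id2, class)
    sex_linked_loci: list
    sequence_length: float  # implied sites given mu (SNP-count calibration)
    mu: float
    mean_total_branch_length: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _default_model() -> DemographicModel:
    return define_models()["M7"].build(M7_TRUTH)


def _mendelian_offspring(gp1: np.ndarray, gp2: np.ndarray, rng) -> np.ndarray:
    """Child genotype from two parental genotype vectors (codes 0/1/2)."""

    def gamete(gp):
        out = np.where(gp == 1, rng.integers(0, 2, size=gp.shape), gp // 2)
        return out.astype(np.int8)

    child = gamete(gp1) + gamete(gp2)
    child[(gp1 == MISSING) | (gp2 == MISSING)] = MISSING
    return child.astype(np.int8)


def generate_study(
    cfg: StudyConfig | None = None, seed: int = 0
) -> tuple[GenotypeMatrix, TruthLog]:
    """Generate one study bundle; byte-deterministic given ``seed``."""
    cfg = cfg or StudyConfig()
    # independent child streams per phase: planting relatives or toggling
    # sex-linked loci must not perturb any other phase's draws
    ss = np.random.SeedSequence(seed)
    (rng, rng_plant, rng_sex, rng_z, rng_meta, rng_err, rng_miss) = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )
    model = cfg.model or _default_model()
    mu = 2.89e-9

    n_rdc_total = cfg.n_rdc + cfg.n_grounded
    samples = SampleConfig({"RIR": 2 * cfg.n_rir, "RDC": 2 * n_rdc_total}, mu=mu)
    G = simulate_genotypes(model, samples, cfg.n_snps, seed=int(rng.integers(2**31)))

    # implied sequence length from the conditioned SNP yield (absolute-scale
    # calibration: E[#SNPs] = mu * L * E[total branch length])
    es = expected_sfs(model, samples, n_reps=20000, seed=int(rng.integers(2**31)))
    seq_len = cfg.n_snps / (mu * es.mean_total_length)

    # relabel: RDC deme supplies breeders then grounded birds
    ids = []
    colony = []
    true_origin = {}
    i_rdc = 0
    i_gb = 0
    for sid, col in zip(G.sample_ids, G.samples["colony"]):
        if col == "RIR":
            new = f"RIR_{len([x for x in ids if x.startswith('RIR')]):03d}"
        else:
            if i_rdc < cfg.n_rdc:
                new = f"RDC_{i_rdc:03d}"
                i_rdc += 1
            else:
                new = f"GB_{i_gb:03d}"
                i_gb += 1
        ids.append(new)
        colony.append(new.split("_")[0])
        true_origin[new] = col
    order = np.argsort(ids)
    calls = G.calls[order]
    ids = [ids[i] for i in order]
    colony = [colony[i] for i in order]

    # sexes
    sex = np.where(rng_sex.random(len(ids)) < cfg.sex_ratio, "F", "M")
    sex_of = dict(zip(ids, sex))

    # plant related pairs by Mendelian construction: the second member of
    # the pair is REPLACED by a constructed relative (n stays fixed)
    planted = []
    used = set()
    id_arr = np.array(ids)
    for colony_name, rel_class in cfg.related_pairs:
        cand = [
            i
            for i, c in enumerate(colony)
            if c == colony_name and ids[i] not in used
        ]
        need = 3 if rel_class == "parent-offspring" else 4
        if len(cand) < need:
            raise ValueError(
                f"cannot plant {rel_class} pair in colony {colony_name!r}: "
                f"fewer than {need} unused samples"
            )
        picks = rng_plant.choice(cand, size=need, replace=False)
        if rel_class == "parent-offspring":
            a, b, c = picks  # parents a, c; child replaces b
            calls[b] = _mendelian_offspring(calls[a], calls[c], rng_plant)
            planted.append((ids[a], ids[b], "parent-offspring"))
        elif rel_class == "full-sib":
            a, b, c, d = picks  # parents b, c; sibs replace a and d
            calls[a] = _mendelian_offspring(calls[b], calls[c], rng_plant)
            calls[d] = _mendelian_offspring(calls[b], calls[c], rng_plant)
            planted.append((ids[a], ids[d], "full-sib"))
        else:
            raise ValueError(f"unknown relationship class {rel_class!r}")
        used.update(ids[i] for i in picks)

    # sex-linked loci on a synthetic Z chromosome: females (ZW) het, males
    # (ZZ) homozygous for one of the alleles
    n_z = cfg.n_sex_linked
    if n_z:
        zcalls = np.empty((len(ids), n_z), dtype=np.int8)
        hom = rng_z.integers(0, 2, size=n_z) * 2
        for i in range(len(ids)):
            zcalls[i] = 1 if sex[i] == "F" else hom
        calls = np.concatenate([calls, zcalls], axis=1)

    # locus metadata
    n_loci = calls.shape[1]
    tag_id = np.array([f"T{j + 1:06d}" for j in range(n_loci)], dtype=object)
    n_multi = int(cfg.frac_multi_snp_tags * (n_loci - n_z))
    if n_multi:
        # pair up some autosomal loci onto shared tags
        donors = rng_meta.choice(n_loci - n_z, size=n_multi, replace=False)
        for j in donors:
            tag_id[j] = tag_id[(j + 1) % (n_loci - n_z)]
    call_rate = rng_meta.beta(*cfg.call_rate_beta, size=n_loci)
    rep_avg = rng_meta.beta(*cfg.rep_avg_beta, size=n_loci)
    depth = rng_meta.lognormal(*cfg.depth_lognorm, size=n_loci)
    chrom = np.array(
        ["synthetic"] * (n_loci - n_z) + ["Z_synthetic"] * n_z, dtype=object
    )

    # genotyping error then missingness (driven by per-locus call rate and
    # the global extra missingness)
    if cfg.genotype_error > 0:
        err = rng_err.random(calls.shape) < cfg.genotype_error
        bump = rng_err.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(
            err & (calls != MISSING), (calls + bump) % 3, calls
        ).astype(np.int8)
    miss_p = np.clip((1.0 - call_rate)[None, :] * 0.5 + cfg.missingness, 0, 1)
    calls = np.where(rng_miss.random(calls.shape) < miss_p, MISSING, calls).astype(np.int8)

    samples_df = pd.DataFrame(
        {
            "colony": colony,
            "sex": sex,
            "year": rng_meta.integers(2016, 2019, size=len(ids)),
        },
        index=pd.Index(ids, name="id"),
    )
    loci_df = pd.DataFrame(
        {
            "tag_id": tag_id,
            "chrom": chrom,
            "pos": np.arange(1, n_loci + 1),
            "ref": "A",
            "alt": "T",
            "call_rate": 1.0 - (calls == MISSING).mean(axis=0),
            "rep_avg": rep_avg,
            "avg_read_depth": depth,
        },
        index=pd.Index([f"L{j + 1:06d}" for j in range(n_loci)], name="locus_id"),
    )
    # recorded call_rate is the realized one; the beta draw shapes it
    out = GenotypeMatrix(calls, samples_df, loci_df)
    truth = TruthLog(
        model_label=model.label,
        model_params=dict(M7_TRUTH) if cfg.model is None else {},
        colony_of=true_origin,
        sex_of=sex_of,
        related_pairs=planted,
        sex_linked_loci=[f"L{j + 1:06d}" for j in range(n_loci - n_z, n_loci)],
        sequence_length=seq_len,
        mu=mu,
        mean_total_branch_length=es.mean_total_length,
        seed=seed,
    )
    return out, truth


def write_study(G: GenotypeMatrix, truth: TruthLog, outdir) -> None:
    """Emit VCF, DArT-lite CSV, sample metadata TSV and the truth log."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(G, outdir / "genotypes.vcf")
    write_dart_csv(G, outdir / "genotypes_dart.csv")
    G.samples.to_csv(outdir / "samples.tsv", sep="\t")
    truth.to_json(outdir / "truth.json")
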