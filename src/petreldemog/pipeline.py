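"""End-to-end pipeline: QC -> structure -> relatedness -> SFS -> Ne history.

``run_pipeline`` chains the stages in study order, persisting every
intermediate under the output directory and appending a timestamped run log.
Input is either a synthetic study configuration or paths to VCF/DArT-lite
genotypes plus a sample-metadata table.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import FitOptions, GT_DEFAULT, MU_DEFAULT, define_models, fit_model, rank_models
from .qc import QCThresholds, hwe_filter, run_qc_cascade
from .relatedness import pairwise_relatedness, prune_related
from .sfs import genotypes_to_sfs, read_dart_csv, read_vcf, suggest_projection, write_sfs, write_vcf
from .stairway import bootstrap_trajectories
from .structure import assign_memberships, detect_migrants, fst_bootstrap_p, pca_scores, select_k
from .synthdata import StudyConfig, generate_study, write_study

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Exactly one input source (synthetic config or genotype paths)."""

    seed: int
    out_dir: str
    synthetic: StudyConfig | None = None
    vcf_path: str | None = None
    dart_path: str | None = None
    metadata_path: str | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    k_max: int = 5
    n_fst_boot: int = 1000
    n_stairway_boot: int = 19
    models_to_fit: tuple[str, ...] = ()
    fit_options: FitOptions = field(default_factory=FitOptions)
    mu: float = MU_DEFAULT
    gt: float = GT_DEFAULT

    def validate(self) -> None:
        sources = [
            self.synthetic is not None,
            self.vcf_path is not None,
            self.dart_path is not None,
        ]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be configured")


def _log_line(path: Path, msg: str) -> None:
    with open(path, "a") as fh:
        fh.write(f"{_dt.datetime.now().isoformat()}\t{msg}\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the consolidated report dictionary.

    Stage order: load/generate -> QC cascade -> clustering/F_ST/migrants ->
    cluster-stratified HWE filter -> relatedness and pruning -> per-cluster
    folded SFS -> stairway trajectory -> optional model fitting/ranking.
    Any stage error aborts with the stage name; completed intermediates
    stay on disk.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = out / "run.log"
    _log_line(run_log, f"pipeline start version={__version__} seed={cfg.seed}")
    report: dict = {"seed": cfg.seed, "version": __version__}
    stage = "load"
    try:
        truth = None
        if cfg.synthetic is not None:
            G, truth = generate_study(cfg.synthetic, seed=cfg.seed)
            write_study(G, truth, out / "synthetic")
            report["sequence_length"] = truth.sequence_length
        elif cfg.vcf_path is not None:
            G = read_vcf(cfg.vcf_path)
            if cfg.metadata_path:
                meta = pd.read_csv(cfg.metadata_path, sep="\t", index_col="id")
                G.samples = meta.reindex(G.samples.index)
        else:
            G = read_dart_csv(cfg.dart_path, cfg.metadata_path)
        _log_line(run_log, f"loaded {G.n_samples} samples x {G.n_loci} loci")

        stage = "qc"
        Gq, qc_report = run_qc_cascade(G, cfg.thresholds, seed=cfg.seed)
        qc_report.write_tsv(out / "qc_report.tsv")
        write_vcf(Gq, out / "filtered.vcf")
        report["qc"] = qc_report.to_frame().to_dict("records")
        _log_line(run_log, f"qc kept {Gq.n_samples} x {Gq.n_loci}")

        stage = "structure"
        scores = pca_scores(Gq)
        km = select_k(scores, k_max=cfg.k_max, seed=cfg.seed)
        mm = assign_memberships(scores, km.k, seed=cfg.seed)
        km.bic_table.to_csv(out / "bic.tsv", sep="\t", index=False)
        colony = Gq.samples.get("colony")
        members = pd.DataFrame(
            mm.memberships,
            index=Gq.samples.index,
            columns=[f"cluster_{i}" for i in range(mm.memberships.shape[1])],
        )
        members["assignment"] = mm.assignment
        members.to_csv(out / "memberships.tsv", sep="\t")
        report["K"] = int(km.k)
        migrants = []
        if colony is not None and km.k > 1:
            # natal cluster = modal cluster of each colony label
            colmap = {}
            for c in pd.unique(colony):
                mask = (colony == c).to_numpy()
                colmap[c] = int(np.bincount(mm.assignment[mask]).argmax())
            natal = np.array([colmap[c] for c in colony])
            migrants = detect_migrants(
                mm.memberships, natal, ids=list(Gq.samples.index)
            )
            fst = fst_bootstrap_p(
                Gq, colony.to_numpy(), n_boot=cfg.n_fst_boot, seed=cfg.seed
            )
            report["fst"] = {"theta": fst.theta, "p": fst.p_value}
        report["migrants"] = migrants
        _log_line(run_log, f"K={km.k} migrants={migrants}")

        stage = "hwe"
        labels = mm.assignment
        dropped = hwe_filter(Gq, labels, alpha=cfg.thresholds.hwe_alpha)
        Gq = Gq.take_loci(~np.isin(Gq.locus_ids, dropped))
        report["hwe_dropped"] = len(dropped)
        _log_line(run_log, f"hwe dropped {len(dropped)} loci")

        stage = "relatedness"
        rel = pairwise_relatedness(Gq)
        rel.to_csv(out / "relatedness.tsv", sep="\t", index=False)
        missing = dict(zip(Gq.sample_ids, Gq.sample_missingness()))
        retained = prune_related(rel, Gq.sample_ids, missing)
        (out / "unrelated_ids.txt").write_text("\n".join(retained) + "\n")
        report["n_unrelated"] = len(retained)
        Gu = Gq.take_samples(np.isin(Gq.sample_ids, retained))
        _log_line(run_log, f"unrelated set n={len(retained)}")

        stage = "sfs"
        seq_len = report.get("sequence_length", 1.0)
        sfs_all = None
        for c in np.unique(labels):
            ids = [s for s, l in zip(Gq.sample_ids, labels) if l == c and s in retained]
            if len(ids) < 3:
                continue
            _, target = suggest_projection(Gu, ids)
            sfs_c = genotypes_to_sfs(Gu, {f"cluster{c}": ids}, fold=True,
                                     projection={f"cluster{c}": target})
            write_sfs(sfs_c, out / f"sfs_cluster{c}.obs")
            if sfs_all is None or sfs_c.total() > sfs_all.total():
                sfs_all = sfs_c
        _log_line(run_log, "sfs written")

        stage = "stairway"
        if sfs_all is not None and sfs_all.total() >= 200:
            summ = bootstrap_trajectories(
                sfs_all,
                n_boot=cfg.n_stairway_boot,
                mu=cfg.mu,
                sequence_length=seq_len,
                gt=cfg.gt,
                seed=cfg.seed,
            )
            summ.to_frame().to_csv(out / "stairway.tsv", sep="\t", index=False)
            report["stairway_plateau_ne"] = float(summ.median[-1])
        _log_line(run_log, "stairway done")

        stage = "models"
        if cfg.models_to_fit:
            defs = define_models()
            colony_arr = Gu.samples["colony"].to_numpy()
            pop_map = {
                "RIR": [s for s, c in zip(Gu.sample_ids, colony_arr) if c == "RIR"],
                "RDC": [s for s, c in zip(Gu.sample_ids, colony_arr) if c != "RIR"],
            }
            obs2d = genotypes_to_sfs(Gu, pop_map, fold=True)
            fits = [
                fit_model(defs[mid], obs2d, cfg.fit_options, seed=cfg.seed)
                for mid in cfg.models_to_fit
            ]
            if len(fits) > 1:
                table = rank_models(fits, obs2d)
                table.to_csv(out / "model_ranking.tsv", sep="\t", index=False)
                report["model_ranking"] = table.to_dict("records")
            report["fits"] = {
                f.model_id: {"params": f.params, "log10_cl": f.max_log10_cl}
                for f in fits
            }
        _log_line(run_log, "pipeline done")
    except Exception as exc:
        _log_line(run_log, f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
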