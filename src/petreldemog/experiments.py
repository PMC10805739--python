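"""Canonical recovery experiments: simulation truth set to the fitted
two-colony history, inference run end to end, results in natural units.

These drive both the numbered analysis scripts and the acceptance checks, so
the experiment definitions live in the library:

* ``m7_recovery``  — simulate a folded 2d-SFS (20,000 conditioned SNPs,
  10+10 diploids) under the ancient-and-recent-bottlenecks history at its
  reported point estimates and refit it by composite likelihood.
* ``stairway_decline_recovery`` — simulate a 200-fold instantaneous decline
  (plateau 8e5 diploids) and locate the onset from the fitted multi-epoch
  trajectory.
* ``k_selection_recovery`` — generate the full study design (31 + 37 + 19
  birds) and select the number of genetic clusters by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel, Resize, SampleConfig
from .models import (
    DEMES,
    FitOptions,
    FitResult,
    GT_DEFAULT,
    M7_TRUTH,
    MU_DEFAULT,
    define_models,
)
from .models import fit_model
from .sfs import genotypes_to_sfs
from .simulate import expected_sfs, simulate_genotypes
from .stairway import bootstrap_trajectories, decline_onset_time
from .structure import pca_scores, select_k
from .synthdata import StudyConfig, generate_study

__all__ = [
    "m7_recovery",
    "stairway_decline_recovery",
    "k_selection_recovery",
    "STAIRWAY_TRUTH",
]

# two-epoch single-deme truth for the decline-onset experiment: a 200-fold
# instantaneous crash from an 8e5-diploid plateau at 125 kyr before present
STAIRWAY_TRUTH = {
    "plateau_ne": 8.0e5,
    "recent_ne": 4.0e3,
    "decline_onset_years": 125000.0,
}


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class M7Recovery:
    fit: FitResult
    truth: dict
    t_split_years: float
    tb_anc1_kyr: float
    n_anc2: float
    sequence_length: float


def m7_recovery(
    seed: int,
    n_snps: int = 20000,
    n_diploids_per_colony: int = 10,
    opts: FitOptions | None = None,
) -> M7Recovery:
    """Simulate under the fitted history and refit it (parameter recovery)."""
    s_cal, s_data, s_fit = _child_seeds(seed, 3)
    m7 = define_models()["M7"]
    model = m7.build(M7_TRUTH)
    n_hap = 2 * n_diploids_per_colony
    sc = SampleConfig({DEMES[0]: n_hap, DEMES[1]: n_hap}, mu=MU_DEFAULT)
    # SNP-count calibration: the effective assayed length implied by the
    # panel's SNP yield under the generating history
    es = expected_sfs(model, sc, n_reps=100000, seed=s_cal, fold=True)
    seq_len = n_snps / (MU_DEFAULT * es.mean_total_length)
    G = simulate_genotypes(model, sc, n_snps, seed=s_data)
    cols = G.samples["colony"]
    pop_map = {
        d: [s for s, c in zip(G.sample_ids, cols) if c == d] for d in DEMES
    }
    obs = genotypes_to_sfs(G, pop_map, fold=True)
    opts = opts or FitOptions(
        n_sims=20000, n_cycles=40, n_runs=20, sequence_length=seq_len
    )
    if opts.sequence_length is None:
        opts.sequence_length = seq_len
    fit = fit_model(m7, obs, opts, seed=s_fit)
    return M7Recovery(
        fit=fit,
        truth=dict(M7_TRUTH),
        t_split_years=fit.params["T_split"] * GT_DEFAULT,
        tb_anc1_kyr=fit.params["Tb_ANC1"] * GT_DEFAULT / 1e3,
        n_anc2=fit.params["N_ANC2"],
        sequence_length=seq_len,
    )


@dataclass
class StairwayRecovery:
    onset_kyr: float
    summary: object
    sequence_length: float


def stairway_decline_recovery(
    seed: int,
    n_snps: int = 15000,
    n_project: int = 33,
    n_boot: int = 19,
) -> StairwayRecovery:
    """Two-epoch decline-onset recovery with the study's projection size."""
    s_cal, s_data, s_fit = _child_seeds(seed, 3)
    onset_gen = STAIRWAY_TRUTH["decline_onset_years"] / GT_DEFAULT
    model = DemographicModel(
        demes=["A"],
        sizes=[STAIRWAY_TRUTH["recent_ne"]],
        events=[Resize(onset_gen, "A", STAIRWAY_TRUTH["plateau_ne"])],
        label="two-epoch decline",
    )
    n_hap = n_project + (n_project % 2)  # simulate whole diploids
    sc = SampleConfig({"A": n_hap}, mu=MU_DEFAULT)
    es = expected_sfs(model, sc, n_reps=50000, seed=s_cal, fold=False)
    seq_len = n_snps / (MU_DEFAULT * es.mean_total_length)
    G = simulate_genotypes(model, sc, n_snps, seed=s_data)
    obs = genotypes_to_sfs(
        G, {"A": G.sample_ids}, fold=True, projection={"A": n_project}
    )
    summary = bootstrap_trajectories(
        obs, n_boot=n_boot, mu=MU_DEFAULT, sequence_length=seq_len,
        gt=GT_DEFAULT, seed=s_fit,
    )
    onset = decline_onset_time(summary)
    return StairwayRecovery(
        onset_kyr=onset * GT_DEFAULT / 1e3, summary=summary, sequence_length=seq_len
    )


@dataclass
class KSelectionRecovery:
    k: int
    bic_table: object


def k_selection_recovery(
    seed: int, n_snps: int = 10000, n_starts: int = 20, k_max: int = 5
) -> KSelectionRecovery:
    """Study-design cluster-count recovery: 31 RDC + 37 RIR + 19 grounded."""
    s_data, s_k = _child_seeds(seed, 2)
    cfg = StudyConfig(n_snps=n_snps)
    G, _truth = generate_study(cfg, seed=s_data)
    scores = pca_scores(G)
    cm = select_k(scores, k_max=k_max, n_starts=n_starts, seed=s_k)
    return KSelectionRecovery(k=cm.k, bic_table=cm.bic_table)
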