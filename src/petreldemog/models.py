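"""Two-colony demographic model set and SFS composite-likelihood fitting.

Seven nested histories (M1-M7) for the RIR/RDC colony pair are fit to a
folded joint SFS by maximizing a multinomial composite likelihood over SFS
classes, with expected spectra obtained by Monte-Carlo branch-length
averaging (common random numbers within each refinement cycle).  Models are
ranked by AIC; parameter uncertainty comes from a block bootstrap over SNPs.

Fixed constants shared by the migration models (M3, M4, M7): forward-time
gene flow runs from RDC into RIR only, at 2Nm = 0.5 before the recent colony
declines and 2Nm = 0.01 after them; the recent declines themselves are
pinned at 4 generations before present (the colonies are known to have
collapsed within the last century, about four generations).  These constants
are not counted as free parameters, and the pinned recent epoch is what
gives the spectrum an absolute time scale.

Because every SNP is ascertained as segregating, SFS *proportions* are
invariant to jointly rescaling all sizes and times; absolute scale is
restored by a Poisson term for the observed SNP count with mean
``mu * L * E[total branch length]`` (equivalent to supplying the
monomorphic class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demography import DemographicModel, Join, Resize, SetMigration
from .demography import SampleConfig
from .sfs import FoldedSFS, GenotypeMatrix, genotypes_to_sfs
from .simulate import expected_sfs, simulate_genotypes

__all__ = [
    "ModelDefinition",
    "FitResult",
    "FitOptions",
    "define_models",
    "composite_log10_lik",
    "saturated_log10_lik",
    "fit_model",
    "rank_models",
    "likelihood_distribution",
    "block_bootstrap_ci",
    "scale_to_natural_units",
]

MU_DEFAULT = 2.89e-9  # substitutions / site / generation
GT_DEFAULT = 18.9  # years / generation
TB_RECENT = 4.0  # generations; recent colony declines ("past 100 years")
MIG_RECENT = 0.01  # 2Nm0, forward RDC -> RIR, after the declines
MIG_ANCIENT = 0.5  # 2Nm1, forward RDC -> RIR, before the declines
P_FLOOR = 1e-8  # floor for zero expected SFS entries

SIZE_RANGE = (10.0, 1e7)  # diploids, log-uniform search
# Present-day colony sizes are census-constrained (the colonies are known
# today to number on the order of a hundred breeding pairs), so their search
# range is informative; all other sizes are essentially unconstrained.
PRESENT_SIZE_RANGE = (10.0, 1e3)
TIME_RANGE = (1.0, 2e4)  # generations, log-uniform search

DEMES = ("RIR", "RDC")


@dataclass(frozen=True)
class ModelDefinition:
    """One candidate history: free parameters plus a builder."""

    id: str
    description: str
    free_params: tuple[str, ...]
    ranges: Mapping[str, tuple[float, float]]
    builder: Callable[[Mapping[str, float]], DemographicModel]
    constraint: Callable[[Mapping[str, float]], bool]

    @property
    def k(self) -> int:
        return len(self.free_params)

    def build(self, params: Mapping[str, float]) -> DemographicModel:
        if not self.constraint(params):
            raise ValueError(f"{self.id}: parameter ordering constraint violated: {dict(params)}")
        return self.builder(params)


def _mig_events(tb: float) -> tuple[dict, list]:
    """Recent/ancient asymmetric gene-flow scheme (forward RDC -> RIR)."""
    start = {("RDC", "RIR"): MIG_RECENT}
    ev = [SetMigration(tb, "RDC", "RIR", MIG_ANCIENT)]
    return start, ev


def _m1(p) -> DemographicModel:
    return DemographicModel(
        demes=list(DEMES),
        sizes=[p["N_RIR"], p["N_RDC"]],
        events=[
            Join(p["T_split"], "RIR", "RDC"),
            Resize(p["T_split"], "RDC", p["N_ANC1"]),
        ],
        label="M1",
    )


def _m2(p, migration: bool = False) -> DemographicModel:
    mig, mig_ev = _mig_events(TB_RECENT) if migration else ({}, [])
    events = [
        Resize(TB_RECENT, "RIR", p["N1_RIR"]),
        Resize(TB_RECENT, "RDC", p["N1_RDC"]),
        *mig_ev,
        Join(p["T_split"], "RIR", "RDC"),
        Resize(p["T_split"], "RDC", p["N_ANC1"]),
    ]
    return DemographicModel(
        demes=list(DEMES),
        sizes=[p["N_RIR"], p["N_RDC"]],
        events=events,
        migration=mig,
        label="M3" if migration else "M2",
    )


def _m4(p) -> DemographicModel:
    mig, mig_ev = _mig_events(TB_RECENT)
    events = [
        Resize(TB_RECENT, "RIR", p["N1_RIR"]),
        *mig_ev,
        Join(p["T_split"], "RIR", "RDC"),
        Resize(p["T_split"], "RDC", p["N_ANC1"]),
    ]
    return DemographicModel(
        demes=list(DEMES),
        sizes=[p["N_RIR"], p["N_RDC"]],
        events=events,
        migration=mig,
        label="M4",
    )


def _m5(p) -> DemographicModel:
    return DemographicModel(
        demes=list(DEMES),
        sizes=[p["N_RIR"], p["N_RDC"]],
        events=[
            Join(p["T_split"], "RIR", "RDC"),
            Resize(p["T_split"], "RDC", p["N_ANC1"]),
            Resize(p["Tb_ANC1"], "RDC", p["N_ANC2"]),
        ],
        label="M5",
    )


def _m6(p) -> DemographicModel:
    return DemographicModel(
        demes=list(DEMES),
        sizes=[p["N_RIR"], p["N_RDC"]],
        events=[
            Join(p["T_split"], "RIR", "RDC"),
            Resize(p["T_split"], "RDC", p["N_ANC1"]),
            Resize(p["Tb_ANC1"], "RDC", p["N_ANC2"]),
            Resize(p["Tb_ANC2"], "RDC", p["N_ANC3"]),
        ],
        label="M6",
    )


def _m7(p) -> DemographicModel:
    mig, mig_ev = _mig_events(TB_RECENT)
    events = [
        Resize(TB_RECENT, "RIR", p["N1_RIR"]),
        Resize(TB_RECENT, "RDC", p["N1_RDC"]),
        *mig_ev,
        Join(p["T_split"], "RIR", "RDC"),
        Resize(p["T_split"], "RDC", p["N_ANC1"]),
        Resize(p["Tb_ANC1"], "RDC", p["N_ANC2"]),
    ]
    return DemographicModel(
        demes=list(DEMES),
        sizes=[p["N_RIR"], p["N_RDC"]],
        events=events,
        migration=mig,
        label="M7",
    )


def define_models() -> dict[str, ModelDefinition]:
    """Registry of the seven candidate histories M1-M7."""
    S, T = SIZE_RANGE, TIME_RANGE

    def rng(names):
        out = {}
        for n in names:
            if n in ("N_RIR", "N_RDC"):
                out[n] = PRESENT_SIZE_RANGE
            elif n.startswith("N"):
                out[n] = S
            else:
                out[n] = T
        return out

    def after_recent(p):
        return p["T_split"] > TB_RECENT

    def anc_order(p):
        return p["Tb_ANC1"] > p["T_split"]

    defs = {
        "M1": ModelDefinition(
            "M1",
            "null model: split with resize only",
            ("N_RIR", "N_RDC", "N_ANC1", "T_split"),
            rng(("N_RIR", "N_RDC", "N_ANC1", "T_split")),
            _m1,
            lambda p: True,
        ),
        "M2": ModelDefinition(
            "M2",
            "bottlenecks without gene flow",
            ("N_RIR", "N_RDC", "N1_RIR", "N1_RDC", "N_ANC1", "T_split"),
            rng(("N_RIR", "N_RDC", "N1_RIR", "N1_RDC", "N_ANC1", "T_split")),
            lambda p: _m2(p, migration=False),
            after_recent,
        ),
        "M3": ModelDefinition(
            "M3",
            "bottlenecks with gene flow (2Nm1=0.5 -> 2Nm0=0.01, RDC->RIR)",
            ("N_RIR", "N_RDC", "N1_RIR", "N1_RDC", "N_ANC1", "T_split"),
            rng(("N_RIR", "N_RDC", "N1_RIR", "N1_RDC", "N_ANC1", "T_split")),
            lambda p: _m2(p, migration=True),
            after_recent,
        ),
        "M4": ModelDefinition(
            "M4",
            "asymmetric bottleneck: decline in RIR only, same gene-flow change",
            ("N_RIR", "N_RDC", "N1_RIR", "N_ANC1", "T_split"),
            rng(("N_RIR", "N_RDC", "N1_RIR", "N_ANC1", "T_split")),
            _m4,
            after_recent,
        ),
        "M5": ModelDefinition(
            "M5",
            "ancient bottleneck: one pre-split decline",
            ("N_RIR", "N_RDC", "N_ANC1", "N_ANC2", "T_split", "Tb_ANC1"),
            rng(("N_RIR", "N_RDC", "N_ANC1", "N_ANC2", "T_split", "Tb_ANC1")),
            _m5,
            anc_order,
        ),
        "M6": ModelDefinition(
            "M6",
            "two ancient bottlenecks",
            ("N_RIR", "N_RDC", "N_ANC1", "N_ANC2", "N_ANC3", "T_split", "Tb_ANC1", "Tb_ANC2"),
            rng(
                (
                    "N_RIR",
                    "N_RDC",
                    "N_ANC1",
                    "N_ANC2",
                    "N_ANC3",
                    "T_split",
                    "Tb_ANC1",
                    "Tb_ANC2",
                )
            ),
            _m6,
            lambda p: p["Tb_ANC1"] > p["T_split"] and p["Tb_ANC2"] > p["Tb_ANC1"],
        ),
        "M7": ModelDefinition(
            "M7",
            "ancient & recent bottlenecks with gene flow",
            ("N_RIR", "N_RDC", "N1_RIR", "N1_RDC", "N_ANC1", "N_ANC2", "T_split", "Tb_ANC1"),
            rng(
                (
                    "N_RIR",
                    "N_RDC",
                    "N1_RIR",
                    "N1_RDC",
                    "N_ANC1",
                    "N_ANC2",
                    "T_split",
                    "Tb_ANC1",
                )
            ),
            _m7,
            lambda p: p["T_split"] > TB_RECENT and p["Tb_ANC1"] > p["T_split"],
        ),
    }
    return defs


# M7 point estimates used as simulation truth: sizes/times the source study
# reports, field-realistic choices where it prints none (see docs/methods.md).
M7_TRUTH: dict[str, float] = {
    "N_RIR": 100.0,
    "N_RDC": 160.0,
    "N1_RIR": 400.0,
    "N1_RDC": 800.0,
    "N_ANC1": 500.0,
    "N_ANC2": 4.0e5,
    "T_split": 1500.0 / GT_DEFAULT,
    "Tb_ANC1": 37000.0 / GT_DEFAULT,
}


# ----------------------------------------------------------------------
def composite_log10_lik(
    obs: np.ndarray, expected: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Multinomial composite log10-likelihood: sum m_i log10(max(p_i, floor)).

    ``obs`` are class counts, ``expected`` class proportions (summing to 1
    over unmasked entries); masked entries are excluded.
    """
    obs = np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if obs.shape != expected.shape:
        raise ValueError("observed and expected SFS shapes differ")
    if mask is None:
        mask = np.zeros(obs.shape, dtype=bool)
    m = obs[~mask]
    if m.sum() <= 0:
        raise ValueError("observed SFS has zero total count")
    p = np.maximum(expected[~mask], P_FLOOR)
    return float(np.sum(m * np.log10(p)))


def saturated_log10_lik(obs: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Gibbs bound: the composite likelihood at the observed proportions."""
    obs = np.asarray(obs, dtype=float)
    if mask is None:
        mask = np.zeros(obs.shape, dtype=bool)
    m = obs[~mask]
    tot = m.sum()
    p = np.where(m > 0, m / tot, 1.0)
    return float(np.sum(m * np.log10(p)))


def _poisson_log10(n_obs: float, lam: float) -> float:
    return float(stats.poisson.logpmf(round(n_obs), max(lam, 1e-300)) / math.log(10))


@dataclass
class FitOptions:
    """Knobs for the composite-likelihood search."""

    n_sims: int = 20000  # genealogies per expected-SFS evaluation
    n_cycles: int = 40  # refinement cycles (fresh common random numbers each)
    n_runs: int = 20  # independent random restarts
    step0: float = 0.4  # initial log10 step per parameter (decades)
    step_final: float = 0.02
    max_march: int = 3  # max consecutive steps per parameter per cycle
    final_factor: int = 10  # precision multiplier for the endpoint re-scoring
    polish_top: int = 3  # endpoints refined at higher precision
    polish_cycles: int = 6
    polish_factor: int = 5  # n_sims multiplier during polishing
    polish_step0: float = 0.08
    # SNP-count anchor: effective sequence length in sites; None disables
    sequence_length: float | None = None
    mu: float = MU_DEFAULT


@dataclass
class FitResult:
    """Best fit of one model to one observed spectrum."""

    model_id: str
    params: dict[str, float]
    k: int
    max_log10_cl: float
    aic: float
    delta_aic: float = math.nan
    delta_lhood: float = math.nan
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    runs_log10_cl: list[float] = field(default_factory=list)
    obs_fingerprint: tuple = ()

    def scaled(self, mu: float = MU_DEFAULT, gt: float = GT_DEFAULT) -> pd.DataFrame:
        return scale_to_natural_units(self.params, mu=mu, gt=gt)


def _obs_fingerprint(obs: FoldedSFS) -> tuple:
    return (obs.data.shape, round(obs.total(), 6))


def _sample_config_for(obs: FoldedSFS, opts: FitOptions) -> SampleConfig:
    n1, n2 = obs.n
    return SampleConfig(
        {DEMES[0]: n1, DEMES[1]: n2},
        sequence_length=opts.sequence_length or 1.0,
        mu=opts.mu,
    )


def _evaluate(
    definition: ModelDefinition,
    params: Mapping[str, float],
    obs: FoldedSFS,
    samples: SampleConfig,
    opts: FitOptions,
    crn_seed: int,
) -> float:
    model = definition.builder(params)
    es = expected_sfs(model, samples, n_reps=opts.n_sims, seed=crn_seed, fold=True)
    cl = composite_log10_lik(obs.data, es.proportions, obs.mask)
    if opts.sequence_length is not None:
        lam = opts.mu * opts.sequence_length * es.mean_total_length
        cl += _poisson_log10(obs.total(), lam)
    return cl


def _random_start(definition: ModelDefinition, rng: np.random.Generator) -> dict[str, float]:
    for _ in range(1000):
        p = {
            name: 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            for name, (lo, hi) in definition.ranges.items()
        }
        if definition.constraint(p):
            return p
    raise RuntimeError(f"{definition.id}: could not draw a feasible start")


def _cyclic_search(
    definition: ModelDefinition,
    params: dict[str, float],
    obs: FoldedSFS,
    samples: SampleConfig,
    opts: FitOptions,
    rng: np.random.Generator,
    n_cycles: int,
    step0: float,
    step_final: float,
    n_sims: int,
) -> dict[str, float]:
    """One search phase: cyclic per-parameter marching refinement.

    Each cycle draws fresh common random numbers (one seed shared by every
    expected-SFS evaluation, so parameter comparisons are de-noised),
    re-scores the incumbent, then for each free parameter tries a geometric
    step up or down and marches while it improves.  Step sizes shrink
    geometrically from ``step0`` to ``step_final`` decades.
    """
    phase_opts = replace(opts, n_sims=n_sims)
    decay = (
        (step_final / step0) ** (1.0 / max(n_cycles - 1, 1)) if n_cycles > 1 else 1.0
    )
    step = step0
    for _cycle in range(n_cycles):
        crn_seed = int(rng.integers(0, 2**31 - 1))
        cl_cur = _evaluate(definition, params, obs, samples, phase_opts, crn_seed)
        for name in definition.free_params:
            lo, hi = definition.ranges[name]

            def _try(value: float) -> float | None:
                cand = dict(params)
                cand[name] = value
                if cand[name] == params[name] or not definition.constraint(cand):
                    return None
                return _evaluate(definition, cand, obs, samples, phase_opts, crn_seed)

            # pick an improving direction, then march while it pays off
            for direction in (1.0, -1.0):
                value = float(np.clip(params[name] * 10 ** (direction * step), lo, hi))
                cl_cand = _try(value)
                if cl_cand is not None and cl_cand > cl_cur:
                    params = {**params, name: value}
                    cl_cur = cl_cand
                    for _ in range(opts.max_march - 1):
                        value = float(
                            np.clip(params[name] * 10 ** (direction * step), lo, hi)
                        )
                        cl_cand = _try(value)
                        if cl_cand is None or cl_cand <= cl_cur:
                            break
                        params = {**params, name: value}
                        cl_cur = cl_cand
                    break
        step *= decay
    return params


def fit_model(
    definition: ModelDefinition,
    obs: FoldedSFS,
    opts: FitOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one model to a folded joint SFS by noisy composite-likelihood
    refinement.

    ``n_runs`` independent searches start from random points in the
    log-uniform ranges and refine cyclically (see :func:`_cyclic_search`).
    Because in-search scores are Monte-Carlo noisy, every endpoint is then
    re-scored at ``final_factor`` x simulation effort under common random
    numbers; the leading ``polish_top`` endpoints get a short
    higher-precision polish phase before the overall winner is returned.
    """
    opts = opts or FitOptions()
    if obs.dimension != 2:
        raise ValueError("fit_model expects a 2d folded SFS")
    samples = _sample_config_for(obs, opts)
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(opts.n_runs + 2)

    endpoints: list[dict[str, float]] = []
    for run_ss in run_seeds[: opts.n_runs]:
        rng = np.random.default_rng(run_ss)
        params = _random_start(definition, rng)
        params = _cyclic_search(
            definition, params, obs, samples, opts, rng,
            opts.n_cycles, opts.step0, opts.step_final, opts.n_sims,
        )
        endpoints.append(params)

    final_opts = replace(opts, n_sims=opts.n_sims * opts.final_factor)
    final_seed = int(np.random.default_rng(run_seeds[-2]).integers(0, 2**31 - 1))
    scored = sorted(
        (
            (_evaluate(definition, p, obs, samples, final_opts, final_seed), i)
            for i, p in enumerate(endpoints)
        ),
        reverse=True,
    )
    runs_cl = [cl for cl, _ in scored]

    polish_rng = np.random.default_rng(run_seeds[-1])
    best_params: dict[str, float] | None = None
    best_cl = -math.inf
    for cl0, i in scored[: max(opts.polish_top, 1)]:
        params = _cyclic_search(
            definition, endpoints[i], obs, samples, opts, polish_rng,
            opts.polish_cycles, opts.polish_step0, opts.step_final,
            opts.n_sims * opts.polish_factor,
        )
        cl = _evaluate(definition, params, obs, samples, final_opts, final_seed)
        if cl > best_cl:
            best_cl, best_params = cl, params
    for cl0, i in scored[max(opts.polish_top, 1):]:
        if cl0 > best_cl:  # an unpolished endpoint may still win
            best_cl, best_params = cl0, endpoints[i]

    assert best_params is not None
    aic = 2 * definition.k - 2 * math.log(10) * best_cl
    return FitResult(
        model_id=definition.id,
        params=best_params,
        k=definition.k,
        max_log10_cl=best_cl,
        aic=aic,
        runs_log10_cl=runs_cl,
        obs_fingerprint=_obs_fingerprint(obs),
    )

def rank_models(fits: Sequence[FitResult], obs: FoldedSFS) -> pd.DataFrame:
    """AIC ranking table with delta-AIC and delta-Lhood vs the saturated bound."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    fps = {f.obs_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were computed on different observed spectra")
    sat = saturated_log10_lik(obs.data, obs.mask)
    best_aic = min(f.aic for f in fits)
    rows = []
    for f in fits:
        f.delta_aic = f.aic - best_aic
        f.delta_lhood = sat - f.max_log10_cl
        rows.append(
            {
                "model": f.model_id,
                "k": f.k,
                "max_log10_CL": f.max_log10_cl,
                "AIC": f.aic,
                "delta_AIC": f.delta_aic,
                "delta_Lhood": f.delta_lhood,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    )


def likelihood_distribution(
    definition: ModelDefinition,
    params: Mapping[str, float],
    n_snps: int,
    n_reps: int = 100,
    seed: int = 0,
    n_sims_expected: int = 100000,
) -> np.ndarray:
    """Distribution of log10 composite likelihoods of datasets simulated at
    ``params`` and scored against the model's own expected spectrum."""
    model = definition.build(params)
    n_per = {d: 20 for d in DEMES}
    samples = SampleConfig(n_per)
    es = expected_sfs(model, samples, n_reps=n_sims_expected, seed=seed, fold=True)
    out = np.empty(n_reps)
    for r in range(n_reps):
        G = simulate_genotypes(model, samples, n_snps, seed=seed + 7919 * (r + 1))
        obs = genotypes_to_sfs(
            G,
            {DEMES[0]: [s for s, c in zip(G.sample_ids, G.samples["colony"]) if c == DEMES[0]],
             DEMES[1]: [s for s, c in zip(G.sample_ids, G.samples["colony"]) if c == DEMES[1]]},
            fold=True,
        )
        out[r] = composite_log10_lik(obs.data, es.proportions, obs.mask)
    return out


def block_bootstrap_ci(
    G: GenotypeMatrix,
    pop_map: Mapping[str, Sequence[str]],
    definition: ModelDefinition,
    opts: FitOptions | None = None,
    n_blocks: int = 100,
    n_reps: int = 40,
    n_runs_per_rep: int = 2,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Per-parameter CIs from a block bootstrap over SNPs.

    SNPs are cut into ``n_blocks`` contiguous equal-size blocks; each
    replicate resamples blocks with replacement, rebuilds the folded 2d-SFS,
    and refits the model with ``n_runs_per_rep`` restarts.  The CI is the
    normal-approximation mean +/- t_{(1+level)/2, df} * SE across replicates.
    """
    opts = replace(opts or FitOptions(), n_runs=n_runs_per_rep)
    n_loci = G.n_loci
    if n_loci < n_blocks:
        raise ValueError(f"need at least {n_blocks} SNPs, got {n_loci}")
    bounds = np.linspace(0, n_loci, n_blocks + 1).astype(int)
    blocks = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_blocks)]
    rng = np.random.default_rng(seed)
    estimates: dict[str, list[float]] = {p: [] for p in definition.free_params}
    for rep in range(n_reps):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([blocks[b] for b in chosen])
        Gb = G.take_loci(idx)
        obs = genotypes_to_sfs(Gb, pop_map, fold=True)
        fit = fit_model(definition, obs, opts, seed=int(rng.integers(0, 2**31 - 1)))
        for p in definition.free_params:
            estimates[p].append(fit.params[p])
    df = n_reps - 1
    tcrit = stats.t.ppf(0.5 + level / 2, df) if df > 0 else math.nan
    ci = {}
    for p, vals in estimates.items():
        arr = np.asarray(vals)
        se = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        ci[p] = (float(arr.mean() - tcrit * se), float(arr.mean() + tcrit * se))
    return ci


def scale_to_natural_units(
    params: Mapping[str, float], mu: float = MU_DEFAULT, gt: float = GT_DEFAULT
) -> pd.DataFrame:
    """Report times in years (generations x GT) and sizes in diploids
    (with breeding pairs = diploids / 2 as a secondary column)."""
    rows = []
    for name, value in params.items():
        if name.startswith("T"):
            rows.append(
                {"parameter": name, "value": value, "unit": "generations",
                 "scaled": value * gt, "scaled_unit": "years", "pairs": math.nan}
            )
        else:
            rows.append(
                {"parameter": name, "value": value, "unit": "diploids",
                 "scaled": value, "scaled_unit": "diploids", "pairs": value / 2}
            )
    return pd.DataFrame(rows)
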