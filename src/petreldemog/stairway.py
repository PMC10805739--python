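"""Model-free multi-epoch Ne estimation from a folded 1d-SFS.

The estimator follows the stairway idea: parameterize history by one scaled
population mutation rate per coalescent level (the period during which
exactly k ancestral lineages survive, k = n..2), so the expected unfolded
spectrum is *linear* in the per-level parameters:

    E[xi_i] = sum_k  theta*_k / (k - 1) * C(n-i-1, k-2) / C(n-1, k-1)

where ``theta*_k = 4 N_k mu L`` is the per-level population mutation rate
summed over the ``L`` assayed sites.  (The combinatorial factor is the
probability that a randomly chosen branch while k lineages survive subtends
exactly i of the n samples; it depends only on the exchangeable topology, so
the identity holds for any time-varying Ne.)  Spectra are folded before
fitting; classes are modeled as independent Poisson counts, which is the
multinomial composite likelihood plus an anchor on the total SNP count.

Levels are grouped into ``b + 1`` contiguous blocks sharing one theta
(b = number of breakpoints); b is chosen by a 2/3 training / 1/3 validation
random split of sites.  Times come from E[T_k] = 4 N_k / (k (k-1))
generations; years multiply by the generation time at reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .sfs import FoldedSFS, fold_sfs

__all__ = [
    "NeTrajectory",
    "TrajectorySummary",
    "level_projection_matrix",
    "expected_folded_sfs_stepwise",
    "expected_t_k",
    "expected_t_k_montecarlo",
    "fit_stairway",
    "bootstrap_trajectories",
    "decline_onset_time",
]

MU_DEFAULT = 2.89e-9
GT_DEFAULT = 18.9


# ----------------------------------------------------------------------
@dataclass
class NeTrajectory:
    """Per-level stairway solution.

    ``thetas[j]`` is theta*_k = 4 N_k mu L for level k = n - j (so index 0
    is the most recent level, k = n); breakpoints in time follow from
    E[T_k] = 4 N_k / (k (k-1)).
    """

    thetas: np.ndarray  # length n-1, ordered k = n .. 2
    n: int
    mu: float = MU_DEFAULT
    sequence_length: float = 1.0
    gt: float = GT_DEFAULT
    log_lik: float = math.nan
    n_breakpoints: int | None = None

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n, 1, -1)

    def ne(self) -> np.ndarray:
        """Diploid Ne per level: theta* / (4 mu L)."""
        return self.thetas / (4.0 * self.mu * self.sequence_length)

    def theta_per_site(self) -> np.ndarray:
        return self.thetas / self.sequence_length

    def level_durations(self) -> np.ndarray:
        """E[T_k] per level in generations."""
        k = self.levels.astype(float)
        return 4.0 * self.ne() / (k * (k - 1.0))

    def step_function(self) -> tuple[np.ndarray, np.ndarray]:
        """(start_times, Ne) of the piecewise-constant trajectory, from the
        present (t=0) backward; the last segment extends to infinity."""
        dur = self.level_durations()
        starts = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return starts, self.ne()

    def ne_at(self, times: np.ndarray) -> np.ndarray:
        starts, ne = self.step_function()
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(ne) - 1)
        return ne[idx]


# ----------------------------------------------------------------------
def level_projection_matrix(n: int) -> np.ndarray:
    """A[i-1, j] maps theta*_{k=n-j} to E[xi_i] (unfolded classes i=1..n-1)."""
    A = np.zeros((n - 1, n - 1))
    for j, k in enumerate(range(n, 1, -1)):
        for i in range(1, n):
            # P(a branch alive during level k subtends i of the n samples):
            # C(n-i-1, k-2) / C(n-1, k-1) — exchangeable-topology identity.
            if n - i - (k - 2) < 0:
                continue
            logw = _log_comb(n - i - 1, k - 2) - _log_comb(n - 1, k - 1)
            if math.isinf(logw):
                continue
            A[i - 1, j] = math.exp(logw) / (k - 1)
    return A


def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -math.inf
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _fold_matrix(n: int) -> np.ndarray:
    """F[c, i-1] folds unfolded classes 1..n-1 to minor classes 1..n//2."""
    half = n // 2
    F = np.zeros((half, n - 1))
    for i in range(1, n):
        c = min(i, n - i)
        F[c - 1, i - 1] += 1.0
    return F


def expected_t_k(n: int, starts: np.ndarray, sizes: np.ndarray, n_reps: int = 200000,
                 seed: int = 0, method: str = "auto") -> np.ndarray:
    """E[T_k] (k = n..2, generations) under a piecewise-constant Ne(t).

    ``starts``/``sizes`` give epoch start times (from 0) and diploid sizes.
    Exact for a single constant epoch; Monte-Carlo (vectorized pure-death
    process) otherwise, or when ``method='mc'`` is forced.
    """
    starts = np.asarray(starts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if method == "exact" or (method == "auto" and len(sizes) == 1):
        if len(sizes) != 1:
            raise ValueError("exact method implemented for constant Ne only")
        k = np.arange(n, 1, -1).astype(float)
        return 4.0 * sizes[0] / (k * (k - 1.0))
    return expected_t_k_montecarlo(n, starts, sizes, n_reps, seed)


def expected_t_k_montecarlo(
    n: int, starts: np.ndarray, sizes: np.ndarray, n_reps: int = 200000, seed: int = 0
) -> np.ndarray:
    """Vectorized pure-death simulation of the ancestral lineage count."""
    rng = np.random.default_rng(seed)
    starts = np.asarray(starts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    n_ep = len(sizes)
    t = np.zeros(n_reps)
    out = np.zeros(n - 1)
    for j, k in enumerate(range(n, 1, -1)):
        rate_scale = k * (k - 1) / 4.0  # divided by N(t) gives the rate
        e = rng.exponential(size=n_reps)  # unit-rate exponential to consume
        t_new = np.empty(n_reps)
        remaining = e.copy()
        cur = t.copy()
        done = np.zeros(n_reps, dtype=bool)
        for ep in range(n_ep):
            hi = starts[ep + 1] if ep + 1 < n_ep else np.inf
            rate = rate_scale / sizes[ep]
            active = ~done & (cur < hi)
            if not active.any():
                continue
            span = np.where(np.isinf(hi), np.inf, hi - cur)
            need = remaining / rate
            fits = active & (need <= span)
            t_new[fits] = cur[fits] + need[fits]
            done |= fits
            spill = active & ~fits
            remaining[spill] -= rate * span[spill]
            cur[spill] = hi
        # lineages that never coalesce within finite epochs: last epoch open
        out[j] = (t_new - t).mean()
        t = t_new
    return out


def expected_folded_sfs_stepwise(
    traj: NeTrajectory, n: int | None = None, sequence_length: float | None = None
) -> FoldedSFS:
    """Expected folded SFS under a per-level trajectory (exact)."""
    n = n or traj.n
    if n < 4:
        raise ValueError("need n >= 4")
    A = level_projection_matrix(n)
    unfolded = A @ traj.thetas
    if sequence_length is not None:
        unfolded = unfolded * (sequence_length / traj.sequence_length)
    full = np.concatenate([[0.0], unfolded, [0.0]])
    return fold_sfs(full)


# ----------------------------------------------------------------------
def _poisson_loglik(counts: np.ndarray, expected: np.ndarray) -> float:
    expected = np.maximum(expected, 1e-12)
    return float(np.sum(counts * np.log(expected) - expected - gammaln(counts + 1)))


def _fit_partition(
    counts: np.ndarray,
    M: np.ndarray,
    bounds: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 3000,
) -> tuple[np.ndarray, float]:
    """Maximize the Poisson likelihood over per-group thetas for a given
    contiguous partition of levels (``bounds`` = group edges).

    The objective is concave in theta, so monotone multiplicative
    (Richardson-Lucy / EM) updates converge to the global optimum from any
    positive start.
    """
    n_groups = len(bounds) - 1
    Mg = np.stack(
        [M[:, bounds[g] : bounds[g + 1]].sum(axis=1) for g in range(n_groups)], axis=1
    )
    col = np.maximum(Mg.sum(axis=0), 1e-300)
    total = max(counts.sum(), 1.0)
    th = init.copy() if init is not None else np.full(n_groups, total / col.sum())
    th = np.maximum(th, 1e-12)
    ll = _poisson_loglik(counts, Mg @ th)
    for _ in range(max_iter):
        mu_hat = np.maximum(Mg @ th, 1e-300)
        th = th * (Mg.T @ (counts / mu_hat)) / col
        new_ll = _poisson_loglik(counts, Mg @ th)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return th, ll


def _greedy_split_path(
    counts: np.ndarray, M: np.ndarray, max_breaks: int, checkpoints: set[int]
) -> dict[int, tuple[np.ndarray, np.ndarray, float]]:
    """Greedy recursive partitioning of levels.

    Starting from one group, repeatedly insert the breakpoint that most
    improves the Poisson likelihood.  Returns, for each checkpoint b,
    (bounds, per-group thetas, log-lik).
    """
    n_levels = M.shape[1]
    bounds = [0, n_levels]
    th, ll = _fit_partition(counts, M, np.array(bounds))
    out: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    if 0 in checkpoints:
        out[0] = (np.array(bounds), th.copy(), ll)
    for b in range(1, max_breaks + 1):
        best = None
        for pos in range(1, n_levels):
            if pos in bounds:
                continue
            cand = np.array(sorted(bounds + [pos]))
            g = int(np.searchsorted(cand, pos)) - 1
            init = np.insert(th, g, th[g])
            th_c, ll_c = _fit_partition(counts, M, cand, init=init, max_iter=400)
            if best is None or ll_c > best[2]:
                best = (cand, th_c, ll_c)
        if best is None:
            break
        bounds = list(best[0])
        th, ll = best[1], best[2]
        if b in checkpoints:
            th_ref, ll_ref = _fit_partition(counts, M, best[0], init=th)
            out[b] = (best[0], th_ref, ll_ref)
    return out


def fit_stairway(
    obs: FoldedSFS,
    mu: float = MU_DEFAULT,
    sequence_length: float = 1.0,
    gt: float = GT_DEFAULT,
    seed: int = 0,
    candidate_breakpoints: tuple[int, ...] | None = None,
    n_starts: int = 5,
) -> NeTrajectory:
    """Fit per-level thetas to a folded 1d-SFS.

    Breakpoints are placed greedily (each insertion maximizes the Poisson
    likelihood); the breakpoint count b is chosen among the candidates by
    composite-likelihood validation on a random 2/3 / 1/3 split of sites,
    then the winner is refit on the full spectrum.  Deterministic given
    ``seed``.
    """
    if obs.dimension != 1:
        raise ValueError("fit_stairway expects a folded 1d SFS")
    n = obs.n[0]
    counts = obs.data[1:].copy()  # polymorphic minor classes 1..n//2
    if counts.sum() < 200:
        raise ValueError("need at least 200 segregating sites")
    if (counts > 0).sum() < 2:
        raise ValueError("degenerate SFS: fewer than two informative classes")
    M = _fold_matrix(n) @ level_projection_matrix(n)
    n_levels = n - 1
    if candidate_breakpoints is None:
        candidate_breakpoints = tuple(sorted({1, 2, max((n - 2) // 2, 1), n - 2}))
    candidate_breakpoints = tuple(
        min(b, n_levels - 1) for b in candidate_breakpoints
    )
    rng = np.random.default_rng(seed)

    # 2/3-1/3 site split for b selection
    train = np.array([rng.binomial(int(c), 2.0 / 3.0) for c in counts], dtype=float)
    valid = counts - train
    path = _greedy_split_path(train, M, max(candidate_breakpoints), set(candidate_breakpoints))
    best_b, best_val = None, -math.inf
    for b in candidate_breakpoints:
        if b not in path:
            continue
        bounds, th, _ = path[b]
        expec = _expand(M, bounds, th)
        p = np.maximum(expec / expec.sum(), 1e-12)
        val_cl = float(np.sum(valid * np.log(p)))
        if val_cl > best_val:
            best_val, best_b = val_cl, b
    final = _greedy_split_path(counts, M, best_b, {best_b})
    bounds, th, ll = final[best_b]
    thetas = np.empty(n_levels)
    for g in range(len(bounds) - 1):
        thetas[bounds[g] : bounds[g + 1]] = th[g]
    return NeTrajectory(
        thetas=thetas,
        n=n,
        mu=mu,
        sequence_length=sequence_length,
        gt=gt,
        log_lik=ll,
        n_breakpoints=best_b,
    )


def _expand(M: np.ndarray, bounds: np.ndarray, th: np.ndarray) -> np.ndarray:
    full = np.empty(M.shape[1])
    for g in range(len(bounds) - 1):
        full[bounds[g] : bounds[g + 1]] = th[g]
    return M @ full


# ----------------------------------------------------------------------
@dataclass
class TrajectorySummary:
    """Pointwise median and percentile band over bootstrap trajectories."""

    times: np.ndarray  # generations, log grid
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    gt: float
    fits: list[NeTrajectory] = field(default_factory=list)

    def times_years(self) -> np.ndarray:
        return self.times * self.gt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_generations": self.times,
                "time_years": self.times_years(),
                "Ne_median": self.median,
                "Ne_lo": self.lo,
                "Ne_hi": self.hi,
            }
        )


def bootstrap_trajectories(
    obs: FoldedSFS,
    n_boot: int = 199,
    mu: float = MU_DEFAULT,
    sequence_length: float = 1.0,
    gt: float = GT_DEFAULT,
    seed: int = 0,
    n_grid: int = 64,
    level: float = 0.95,
    n_starts: int = 5,
) -> TrajectorySummary:
    """Point fit plus ``n_boot`` multinomial site resamples; pointwise
    median and (1-level)/2 percentile band on a log-time grid."""
    point = fit_stairway(
        obs, mu=mu, sequence_length=sequence_length, gt=gt, seed=seed, n_starts=n_starts
    )
    fits = [point]
    rng = np.random.default_rng(seed + 1)
    counts = obs.data.copy()
    poly = counts[1:]
    total = int(round(poly.sum()))
    p = poly / poly.sum()
    for b in range(n_boot):
        resampled = rng.multinomial(total, p).astype(float)
        boot_obs = FoldedSFS(
            np.concatenate([[0.0], resampled]), obs.n, obs.mask.copy()
        )
        fits.append(
            fit_stairway(
                boot_obs,
                mu=mu,
                sequence_length=sequence_length,
                gt=gt,
                seed=seed + 100 + b,
                n_starts=n_starts,
            )
        )
    tmin = max(min(f.level_durations()[0] for f in fits), 1e-2)
    tmax = max(f.step_function()[0][-1] + f.level_durations()[-1] for f in fits)
    grid = np.geomspace(max(tmin, 1.0), tmax * 1.5, n_grid)
    vals = np.stack([f.ne_at(grid) for f in fits])
    alpha = (1.0 - level) / 2.0
    return TrajectorySummary(
        times=grid,
        median=np.median(vals, axis=0),
        lo=np.quantile(vals, alpha, axis=0),
        hi=np.quantile(vals, 1 - alpha, axis=0),
        gt=gt,
        fits=fits,
    )


def decline_onset_time(summary: TrajectorySummary) -> float:
    """First time (scanning ancient -> recent) the median trajectory falls
    below half its ancestral plateau; generations.  The plateau is the
    median Ne at the most ancient grid time."""
    plateau = summary.median[-1]
    below = summary.median < 0.5 * plateau
    for i in range(len(summary.times) - 1, -1, -1):
        if below[i]:
            return float(summary.times[i])
    raise ValueError("median trajectory never falls below half its plateau")
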