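"""Piecewise profile model and its differential-evolution fitter.

A single gene's normalized expression trajectory is modeled as a
plateau-ramp-plateau-ramp-plateau curve with seven free parameters:
four durations ``t1..t4`` (hours) and three amplitudes ``A1..A3``
(dimensionless).  The curve starts at the first sampling time ``t0``:

* flat at ``A1`` on ``[t0, t0+t1]``,
* linear ramp from ``A1`` to ``A2`` over the next ``t2`` hours,
* flat at ``A2`` for ``t3`` hours,
* linear ramp from ``A2`` to ``A3`` over ``t4`` hours,
* flat at ``A3`` afterwards.

``t1`` is the time to first inflection and ``t2+t3+t4`` the time from the
first inflection until the profile levels off.  The fit cost is the
squared deviation from the replicate-averaged data scaled by the
replicate standard deviation, so noisier time points weigh less.

Fitting uses a classic DE/rand/1/bin differential-evolution population
(greedy selection) and pools the final populations of several
independent restarts into a :class:`FitEnsemble`; the spread of the
ensemble members that fit the data well is the confidence information
used downstream for behavioral classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PiecewiseParams",
    "DEConfig",
    "FitEnsemble",
    "evaluate_piecewise",
    "cost",
    "fit_profile_de",
    "fit_profiles",
    "good_fit_mask",
    "summarize_timescales",
]

#: order of the free parameters in flat array form
PARAM_NAMES = ("t1", "t2", "t3", "t4", "A1", "A2", "A3")


@dataclass(frozen=True)
class PiecewiseParams:
    """The 7 free parameters of the piecewise profile plus the fixed origin t0."""

    t0: float
    t1: float
    t2: float
    t3: float
    t4: float
    A1: float
    A2: float
    A3: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float], t0: float) -> "PiecewiseParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (7,):
            raise ValueError("parameter vector must have length 7")
        return cls(t0, *theta.tolist())

    @property
    def knots(self) -> np.ndarray:
        """Absolute times of the four segment boundaries."""
        return self.t0 + np.cumsum([self.t1, self.t2, self.t3, self.t4])

    @property
    def t_change(self) -> float:
        """Duration from first inflection until the profile levels off."""
        return self.t2 + self.t3 + self.t4


def _evaluate_population(theta: np.ndarray, t: np.ndarray, t0: float) -> np.ndarray:
    """Evaluate the piecewise curve for a population of parameter vectors.

    Parameters are a ``(P, 7)`` array in :data:`PARAM_NAMES` order; returns
    ``(P, len(t))``.  Zero-length ramps degenerate to jumps; the boundary
    point of a zero-length ramp takes the value of the preceding plateau.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    t1, t2, t3, t4 = (theta[:, j : j + 1] for j in range(4))
    A1, A2, A3 = (theta[:, j : j + 1] for j in range(4, 7))
    k1 = t0 + t1
    k2 = k1 + t2
    k3 = k2 + t3
    k4 = k3 + t4
    tt = np.asarray(t, dtype=float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ramp1 = A1 + (A2 - A1) * (tt - k1) / t2
        ramp2 = A2 + (A3 - A2) * (tt - k3) / t4
    # first matching branch wins, so degenerate (t2=0 / t4=0) ramps never
    # contribute their NaNs, and plateau values are bit-exact amplitudes
    out = np.where(
        tt <= k1,
        A1,
        np.where(tt < k2, ramp1, np.where(tt <= k3, A2, np.where(tt < k4, ramp2, A3))),
    )
    return out


def evaluate_piecewise(params: PiecewiseParams, t) -> np.ndarray | float:
    """Evaluate the piecewise curve at time(s) ``t`` (hours, >= t0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < params.t0 - 1e-12):
        raise ValueError(f"cannot evaluate profile before t0={params.t0}")
    out = _evaluate_population(params.as_array()[None, :], np.atleast_1d(t_arr), params.t0)[0]
    return float(out[0]) if t_arr.ndim == 0 else out


def cost(params: PiecewiseParams, d, sigma, times) -> float:
    """Error-scaled squared deviation F = sum_j (d_j - s_j)^2 / sigma_j^2.

    ``d`` is the replicate-averaged level at each time, ``sigma`` the
    replicate standard deviation (must be strictly positive; floor it
    upstream).  Scaling by sigma down-weights noisy time points.
    """
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (d.shape == sigma.shape == times.shape):
        raise ValueError("d, sigma and times must have matching shapes")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive (apply a floor upstream)")
    s = evaluate_piecewise(params, times)
    return float(np.sum((d - s) ** 2 / sigma**2))


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings.

    ``agents``, ``crossover`` (CR) and ``mixing`` (the scale factor F)
    follow the standard DE/rand/1/bin parameterization.  ``restarts``
    independent runs are pooled into the final ensemble.  Iteration stops
    at ``max_iter`` or when the best cost improves by less than ``tol``
    (relative) over ``tol_window`` iterations.
    """

    agents: int = 15
    crossover: float = 0.75
    mixing: float = 0.6
    restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-6
    tol_window: int = 100
    amp_factor: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.agents < 4:
            raise ValueError("DE needs at least 4 agents")
        if not 0 <= self.crossover <= 1:
            raise ValueError("crossover must be in [0, 1]")
        if self.mixing <= 0:
            raise ValueError("mixing must be positive")


@dataclass
class FitEnsemble:
    """Pooled final DE populations for one profile, sorted by cost."""

    params: np.ndarray  # (M, 7), PARAM_NAMES order, best first
    costs: np.ndarray  # (M,)
    t0: float
    times: np.ndarray
    config: DEConfig
    best_cost_trace: np.ndarray  # per-iteration best cost, non-increasing
    n_iter: int

    def __post_init__(self) -> None:
        order = np.argsort(self.costs, kind="stable")
        self.params = self.params[order]
        self.costs = self.costs[order]

    def __len__(self) -> int:
        return len(self.costs)

    @property
    def best(self) -> PiecewiseParams:
        return PiecewiseParams.from_array(self.params[0], self.t0)

    @property
    def best_cost(self) -> float:
        return float(self.costs[0])

    def member(self, i: int) -> PiecewiseParams:
        return PiecewiseParams.from_array(self.params[i], self.t0)

    def curves(self, t=None) -> np.ndarray:
        """Member curves evaluated on ``t`` (default: the fit grid)."""
        t = self.times if t is None else np.asarray(t, dtype=float)
        return _evaluate_population(self.params, t, self.t0)

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the ensemble (members, costs,
        trace and the DE settings that produced them)."""
        from dataclasses import asdict

        return {
            "t0": self.t0,
            "times": self.times.tolist(),
            "param_names": list(PARAM_NAMES),
            "members": self.params.tolist(),
            "costs": self.costs.tolist(),
            "best_cost_trace": self.best_cost_trace.tolist(),
            "n_iter": self.n_iter,
            "de_config": asdict(self.config),
        }

    def fit_mean_sd(self, t=None, mask=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-time mean and SD across (optionally masked) members."""
        c = self.curves(t)
        if mask is not None:
            c = c[np.asarray(mask, dtype=bool)]
        return c.mean(axis=0), c.std(axis=0, ddof=0)


def _rescale_durations(theta: np.ndarray, span: float) -> None:
    """Clamp duration parameters in place so all knots stay inside the window."""
    dur = theta[:, :4]
    total = dur.sum(axis=1)
    over = total > span
    if np.any(over):
        dur[over] *= (span / total[over])[:, None]


def _distinct_triples(rng: np.random.Generator, n_rows: int, n_agents: int,
                      self_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three distinct within-block partner indices per row, none equal to self."""
    r = rng.integers(0, n_agents, size=(n_rows, 3))
    while True:
        bad = (
            (r[:, 0] == r[:, 1])
            | (r[:, 0] == r[:, 2])
            | (r[:, 1] == r[:, 2])
            | (r == self_idx[:, None]).any(axis=1)
        )
        if not bad.any():
            break
        r[bad] = rng.integers(0, n_agents, size=(int(bad.sum()), 3))
    return r[:, 0], r[:, 1], r[:, 2]


def fit_profiles(
    d: np.ndarray,
    sigma: np.ndarray,
    times: np.ndarray,
    config: DEConfig | None = None,
) -> list[FitEnsemble]:
    """Fit many profiles at once (vectorized over genes, restarts and agents).

    ``d`` and ``sigma`` are ``(n_genes, n_times)``; returns one
    :class:`FitEnsemble` per gene.  All restarts of all genes advance in a
    single vectorized DE loop; genes whose best cost has converged drop out
    of the active set individually.
    """
    config = config or DEConfig()
    d = np.atleast_2d(np.asarray(d, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    times = np.asarray(times, dtype=float)
    if d.shape != sigma.shape or d.shape[1] != times.size:
        raise ValueError("d, sigma and times have inconsistent shapes")
    if not np.all(np.isfinite(d)) or not np.all(np.isfinite(sigma)):
        raise ValueError("profiles must be finite")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")

    n_genes, n_t = d.shape
    t0 = float(times[0])
    span = float(times[-1] - t0)
    na, nr = config.agents, config.restarts
    rows_per_gene = na * nr
    n_rows = n_genes * rows_per_gene

    rng = np.random.default_rng(config.seed)
    gene_of_row = np.repeat(np.arange(n_genes), rows_per_gene)
    agent_idx = np.tile(np.arange(na), n_genes * nr)
    block_start = (np.arange(n_rows) // na) * na

    upper = np.empty((n_rows, 7))
    upper[:, :4] = span
    upper[:, 4:] = (config.amp_factor * d.max(axis=1))[gene_of_row][:, None]
    # degenerate all-zero profiles still need a nonzero amplitude box
    upper[:, 4:] = np.maximum(upper[:, 4:], 1e-12)

    # durations come from sorted uniform knot positions, so initial knots are
    # uniform over the observation window and the sum constraint holds by
    # construction; amplitudes are uniform in their box
    X = np.empty((n_rows, 7))
    knots0 = np.sort(rng.uniform(0.0, span, size=(n_rows, 4)), axis=1)
    X[:, 0] = knots0[:, 0]
    X[:, 1:4] = np.diff(knots0, axis=1)
    X[:, 4:] = rng.uniform(0.0, 1.0, size=(n_rows, 3)) * upper[:, 4:]
    # data-anchored initialization: half of each population takes its knots
    # from the sampling times and its amplitudes from the observed levels at
    # those times, giving DE refinable candidates near every plausible
    # plateau/ramp layout of the measured profile
    if n_t >= 5:
        anchored = rng.random(n_rows) < 0.5
        n_anc = int(anchored.sum())
        j = np.sort(rng.integers(1, n_t, size=(n_anc, 4)), axis=1)
        ok = (j[:, 0] < j[:, 1]) & (j[:, 2] < j[:, 3])
        while not ok.all():
            j[~ok] = np.sort(rng.integers(1, n_t, size=((~ok).sum(), 4)), axis=1)
            ok = (j[:, 0] < j[:, 1]) & (j[:, 2] < j[:, 3])
        rows_anc = np.flatnonzero(anchored)
        g_anc = gene_of_row[rows_anc]
        knots_t = times[j]
        X[rows_anc, 0] = knots_t[:, 0] - t0
        X[rows_anc, 1:4] = np.diff(knots_t, axis=1)
        X[rows_anc, 4] = d[g_anc, j[:, 0]]
        X[rows_anc, 5] = d[g_anc, j[:, 1]]
        X[rows_anc, 6] = d[g_anc, j[:, 3]]
        np.clip(X[rows_anc, 4:], 0.0, upper[rows_anc, 4:], out=X[rows_anc, 4:])
    inv_var = 1.0 / sigma**2

    def eval_cost(theta: np.ndarray, rows: np.ndarray) -> np.ndarray:
        s = _evaluate_population(theta, times, t0)
        g = gene_of_row[rows]
        return ((d[g] - s) ** 2 * inv_var[g]).sum(axis=1)

    all_rows = np.arange(n_rows)
    F = eval_cost(X, all_rows)

    max_iter = config.max_iter
    trace = np.full((n_genes, max_iter + 1), np.nan)
    gene_best = np.minimum.reduceat(F, np.arange(0, n_rows, rows_per_gene))
    trace[:, 0] = gene_best
    stop_iter = np.full(n_genes, max_iter, dtype=int)
    active_genes = np.ones(n_genes, dtype=bool)
    active_rows = all_rows

    it = 0
    while it < max_iter and active_rows.size:
        it += 1
        nact = active_rows.size
        xi = X[active_rows]
        r1, r2, r3 = _distinct_triples(rng, nact, na, agent_idx[active_rows])
        base = block_start[active_rows]
        v = X[base + r1] + config.mixing * (X[base + r2] - X[base + r3])
        # reflect out-of-box mutants back inside (clipping would pile the
        # population onto the bounds and starve the search of diversity)
        ub = upper[active_rows]
        v = np.abs(v)
        over = v > ub
        v[over] = (2 * ub - v)[over]
        np.clip(v, 0.0, ub, out=v)
        _rescale_durations(v, span)
        cross = rng.random((nact, 7)) < config.crossover
        cross[np.arange(nact), rng.integers(0, 7, size=nact)] = True
        trial = np.where(cross, v, xi)
        f_trial = eval_cost(trial, active_rows)
        better = f_trial < F[active_rows]
        upd = active_rows[better]
        X[upd] = trial[better]
        F[upd] = f_trial[better]

        gene_best = np.minimum.reduceat(F, np.arange(0, n_rows, rows_per_gene))
        trace[active_genes, it] = gene_best[active_genes]

        if it % config.tol_window == 0:
            prev = trace[:, it - config.tol_window]
            cur = trace[:, it]
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = (prev - cur) / np.maximum(prev, 1e-300)
            converged = active_genes & ((rel < config.tol) | (cur == 0.0))
            if converged.any():
                stop_iter[converged] = it
                active_genes &= ~converged
                active_rows = all_rows[active_genes[gene_of_row]]

    stop_iter[active_genes] = it

    ensembles = []
    for g in range(n_genes):
        sl = slice(g * rows_per_gene, (g + 1) * rows_per_gene)
        ensembles.append(
            FitEnsemble(
                params=X[sl].copy(),
                costs=F[sl].copy(),
                t0=t0,
                times=times,
                config=config,
                best_cost_trace=trace[g, : stop_iter[g] + 1].copy(),
                n_iter=int(stop_iter[g]),
            )
        )
    return ensembles


def fit_profile_de(d, sigma, times, config: DEConfig | None = None) -> FitEnsemble:
    """Fit a single averaged profile; see :func:`fit_profiles`."""
    return fit_profiles(np.atleast_2d(d), np.atleast_2d(sigma), times, config)[0]


def good_fit_mask(ensemble: FitEnsemble, d, sigma) -> np.ndarray:
    """Members that are, on average across the time course, within one
    replicate standard deviation of the replicate average (boundary
    inclusive)."""
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    curves = ensemble.curves()
    mean_dev = (np.abs(d[None, :] - curves) / sigma[None, :]).mean(axis=1)
    return mean_dev <= 1.0 + 1e-12


def summarize_timescales(
    ensembles: Sequence[FitEnsemble],
    d: np.ndarray,
    sigma: np.ndarray,
    exclude: np.ndarray | None = None,
) -> dict:
    """Good-fit-averaged t1 and t2+t3+t4 per gene.

    ``exclude`` marks genes without an inflection (flat profiles); they
    carry no timescale and are dropped.  Genes without any good fit are
    dropped as well and counted.
    """
    d = np.atleast_2d(d)
    sigma = np.atleast_2d(sigma)
    t1, t_change, idx = [], [], []
    n_no_good = 0
    for g, ens in enumerate(ensembles):
        if exclude is not None and exclude[g]:
            continue
        mask = good_fit_mask(ens, d[g], sigma[g])
        if not mask.any():
            n_no_good += 1
            continue
        members = ens.params[mask]
        t1.append(float(members[:, 0].mean()))
        t_change.append(float(members[:, 1:4].sum(axis=1).mean()))
        idx.append(g)
    return {
        "gene_index": np.array(idx, dtype=int),
        "t1": np.array(t1),
        "t_change": np.array(t_change),
        "n_without_good_fit": n_no_good,
    }
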