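"""Maximum-likelihood fitting of the retention curve and the trace model.

Both fits treat per-condition choice counts as independent binomials whose
success probability is the model prediction:

* retention fit — ``k_d ~ Binomial(n_d, c + (1 - c) a exp(-lambda_r d))``
  over the delay conditions of a delayed-MTS summary;
* trace probe fit — ``k_first ~ Binomial(n_row, P(first | g, lambda, beta))``
  over the six probe duration conditions, where ``P(first)`` is the
  conditional first-sample choice probability of the trace model.

With only six probe conditions the trace parameters are jointly weakly
identified, so the gain is pinned to 1 by default and (decay, temperature)
are fitted; confidence intervals are profile-likelihood (not Wald), which
behaves better at these small counts.  Optimization is bounded L-BFGS-B
from a fixed grid of starts.  A flat-likelihood diagnostic is raised when
the fit does not improve on the equal-probability null — the graceful
report for data that carry no order information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .trace_model import TraceParams
from .experiment_sim import PROBE_CONDITIONS, SEQUENCE_ISI
from .stats_analysis import ContingencyTable, TestResult

__all__ = [
    "FitResult",
    "OptimizationError",
    "fit_retention",
    "fit_trace_probes",
    "recovery_study",
    "lr_test",
]

_OBJ_TOL = 1e-8
_CHI2_95_DF1 = float(sps.chi2.ppf(0.95, 1))


class OptimizationError(RuntimeError):
    """A nested fit ended with an impossible (negative) deviance."""


@dataclass(frozen=True)
class FitResult:
    """Point estimates, log-likelihood and diagnostics of one ML fit."""

    estimates: Mapping[str, float]
    log_likelihood: float
    converged: bool
    n_obs: int
    ci: Mapping[str, tuple[float, float]] | None = None
    diagnostics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and not math.isfinite(self.log_likelihood):
            raise ValueError("converged fit must have finite log-likelihood")


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial log-likelihood up to the constant binomial coefficients."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float((k * np.log(p) + (n - k) * np.log1p(-p)).sum())


# ---------------------------------------------------------------------------
# Retention curve
# ---------------------------------------------------------------------------

def fit_retention(
    delays: Sequence[float],
    k: Sequence[int],
    n: Sequence[int],
    chance: float = 0.5,
) -> FitResult:
    """ML fit of the exponential retention curve to per-delay counts.

    Estimates (asymptote ``a``, decay rate ``lambda_r``) under independent
    binomial likelihoods, with ``a`` in [0, 1] and ``lambda_r >= 0``.  When
    the data sit at chance everywhere, ``a`` collapses to 0, the decay rate
    is unidentified, and the ``flat_likelihood`` diagnostic is set.
    """
    delays = np.asarray(delays, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(set(delays.tolist())) < 2:
        raise ValueError("retention fit needs >= 2 distinct delays")
    if np.any(k > n) or np.any(k < 0) or np.any(n <= 0):
        raise ValueError("need 0 <= k <= n with n > 0 for every delay")
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must be in (0, 1)")

    def nll(theta: np.ndarray) -> float:
        a, lam = theta
        p = chance + (1.0 - chance) * a * np.exp(-lam * delays)
        return -_binom_ll(k, n, p)

    starts = [(a0, l0) for a0 in (0.05, 0.3, 0.6, 0.9) for l0 in (0.05, 0.5)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0=np.array(x0), method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, 50.0)],
            options={"ftol": _OBJ_TOL},
        )
        if best is None or res.fun < best.fun:
            best = res
    a_hat, lam_hat = best.x
    ll = -float(best.fun)
    ll_null = _binom_ll(k, n, np.full_like(delays, chance))
    diagnostics = []
    if ll - ll_null < 1e-6:
        diagnostics.append("flat_likelihood")
    if a_hat < 1e-6:
        diagnostics.append("decay_rate_unidentified")
    return FitResult(
        estimates={"asymptote": float(a_hat), "decay_rate": float(lam_hat),
                   "chance": chance},
        log_likelihood=ll,
        converged=bool(best.success),
        n_obs=int(n.sum()),
        diagnostics=tuple(diagnostics),
    )


# ---------------------------------------------------------------------------
# Trace model on probe counts
# ---------------------------------------------------------------------------

_TRACE_BOUNDS = {"gain": (1e-6, 20.0), "decay": (0.0, 10.0),
                 "temperature": (0.0, 100.0)}
_TRACE_STARTS = {"gain": (0.5, 2.0), "decay": (0.1, 0.5, 1.5, 4.0),
                 "temperature": (1.0, 8.0)}


def _probe_probs_vec(
    conditions: np.ndarray,
    isi: float,
    retention_gap: float,
    gain: float,
    decay: float,
    temperature: float,
    lapse: float,
) -> np.ndarray:
    """Vectorized conditional P(first) across probe conditions.

    Same quantity as :func:`tracemem.trace_model.probe_prediction` (four
    options, two zero-intensity foils, lapse-mixed softmax, conditioned on a
    sample choice), evaluated in closed form for speed.
    """
    d1, d2 = conditions[:, 0], conditions[:, 1]
    i1 = -np.expm1(-gain * d1) * np.exp(-decay * (retention_gap + isi + d2))
    i2 = -np.expm1(-gain * d2) * np.exp(-decay * retention_gap)
    z1 = temperature * i1
    z2 = temperature * i2
    zmax = np.maximum(z1, z2)  # foils have intensity 0, i.e. z = 0
    w1, w2, w0 = np.exp(z1 - zmax), np.exp(z2 - zmax), np.exp(-zmax)
    denom = w1 + w2 + 2.0 * w0
    p1 = (1.0 - lapse) * w1 / denom + lapse / 4.0
    p2 = (1.0 - lapse) * w2 / denom + lapse / 4.0
    return p1 / (p1 + p2)


def fit_trace_probes(
    table: ContingencyTable,
    conditions: Sequence[tuple[float, float]] = PROBE_CONDITIONS,
    isi: float = SEQUENCE_ISI,
    retention_gap: float = 0.0,
    fixed: Mapping[str, float] | None = None,
    ci: bool = True,
) -> FitResult:
    """ML fit of the trace model to a conditions x (first, second) table.

    ``fixed`` pins parameters by name; by default the gain is pinned to 1
    and the lapse to 0, leaving (decay, temperature) free.  Reports profile
    95% CIs for the free parameters and sets ``flat_likelihood`` when the
    deviance against the equal-probability null is below 1e-6.
    """
    conds = np.asarray(conditions, dtype=float)
    counts = np.asarray(table.counts, dtype=float)
    if counts.shape != (len(conds), 2):
        raise ValueError(
            f"table has {counts.shape[0]} rows for {len(conds)} conditions"
        )
    pins = {"gain": 1.0, "lapse": 0.0}
    if fixed:
        pins.update(fixed)
    free = [p for p in ("gain", "decay", "temperature") if p not in pins]
    k_first = counts[:, 0]
    n_row = counts.sum(axis=1)

    def unpack(theta: np.ndarray) -> dict[str, float]:
        params = dict(pins)
        params.update(zip(free, theta))
        return params

    def nll(theta: np.ndarray) -> float:
        q = unpack(theta)
        p = _probe_probs_vec(conds, isi, retention_gap, q["gain"], q["decay"],
                             q["temperature"], q["lapse"])
        return -_binom_ll(k_first, n_row, p)

    if not free:
        # fully pinned model: just evaluate the likelihood
        ll = -nll(np.empty(0))
        ll_null = _binom_ll(k_first, n_row, np.full(len(conds), 0.5))
        diagnostics = ["flat_likelihood"] if 2.0 * (ll - ll_null) < 1e-6 else []
        return FitResult(
            estimates={p: float(v) for p, v in pins.items()},
            log_likelihood=ll, converged=True, n_obs=int(n_row.sum()),
            diagnostics=tuple(diagnostics),
        )
    bounds = [_TRACE_BOUNDS[p] for p in free]
    start_axes = [_TRACE_STARTS[p] for p in free]
    starts = [np.array(s, dtype=float)
              for s in _grid(start_axes, limit=8)]
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0=x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": _OBJ_TOL})
        if best is None or res.fun < best.fun:
            best = res
    ll = -float(best.fun)
    ll_null = _binom_ll(k_first, n_row, np.full(len(conds), 0.5))
    deviance_vs_null = 2.0 * (ll - ll_null)
    diagnostics = []
    if deviance_vs_null < 1e-6:
        diagnostics.append("flat_likelihood")
    estimates = unpack(best.x)
    cis = None
    if ci:
        cis = {
            name: _profile_ci(nll, best.x.copy(), i, bounds, float(best.fun))
            for i, name in enumerate(free)
        }
    return FitResult(
        estimates={p: float(v) for p, v in estimates.items()},
        log_likelihood=ll,
        converged=bool(best.success),
        n_obs=int(n_row.sum()),
        ci=cis,
        diagnostics=tuple(diagnostics),
    )


def _grid(axes: list[tuple[float, ...]], limit: int) -> list[tuple[float, ...]]:
    pts: list[tuple[float, ...]] = [()]
    for ax in axes:
        pts = [p + (v,) for p in pts for v in ax]
    return pts[:limit]


def _profile_ci(
    nll,
    mle: np.ndarray,
    index: int,
    bounds: list[tuple[float, float]],
    nll_min: float,
    level_drop: float = _CHI2_95_DF1 / 2.0,
) -> tuple[float, float]:
    """Profile-likelihood CI for one free parameter.

    At each fixed value of the parameter the other free parameters are
    re-optimized; the interval is where the profiled negative log-likelihood
    stays within chi2(0.95, 1)/2 of the minimum.  Bounds of the parameter
    space truncate the interval.
    """
    lo_b, hi_b = bounds[index]
    others = [i for i in range(len(mle)) if i != index]

    def pnll(v: float) -> float:
        if not others:
            x = mle.copy()
            x[index] = v
            return nll(x)
        x0 = mle[others]
        ob = [bounds[i] for i in others]

        def inner(y: np.ndarray) -> float:
            x = mle.copy()
            x[index] = v
            x[others] = y
            return nll(x)

        res = optimize.minimize(inner, x0=x0, method="L-BFGS-B", bounds=ob,
                                options={"ftol": _OBJ_TOL})
        return float(res.fun)

    target = nll_min + level_drop
    center = float(mle[index])
    scale = 0.25 * (1.0 + abs(center))

    def edge(direction: int) -> float:
        limit = hi_b if direction > 0 else lo_b
        v, step = center, scale
        for _ in range(60):
            nxt = v + direction * step
            if (direction > 0 and nxt >= limit) or (direction < 0 and nxt <= limit):
                if pnll(limit) <= target:
                    return limit
                nxt = limit
            if pnll(nxt) > target:
                # bisect between v (inside) and nxt (outside)
                inside, outside = v, nxt
                for _ in range(40):
                    mid = 0.5 * (inside + outside)
                    if pnll(mid) <= target:
                        inside = mid
                    else:
                        outside = mid
                    if abs(outside - inside) < 1e-4 * (1.0 + abs(center)):
                        break
                return inside
            v = nxt
            step *= 1.6
        return limit

    return (edge(-1), edge(+1))


# ---------------------------------------------------------------------------
# Parameter recovery and nested-model comparison
# ---------------------------------------------------------------------------

def recovery_study(
    true_params: TraceParams,
    design: Mapping | None = None,
    reps: int = 50,
    seed: int = 0,
) -> dict:
    """Simulate-and-refit validation of the trace probe fit.

    Draws ``reps`` datasets of binomial first-choice counts at the true
    parameters under ``design`` (conditions, isi, retention gap, trials per
    condition), refits each, and reports per-parameter bias, RMSE and
    profile-CI coverage.  Deterministic given ``seed``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    design = dict(design or {})
    conditions = np.asarray(design.get("conditions", PROBE_CONDITIONS), float)
    isi = float(design.get("isi", SEQUENCE_ISI))
    gap = float(design.get("retention_gap", 0.0))
    n_per = int(design.get("n_per_condition", 20))
    fixed = dict(design.get("fixed", {"gain": true_params.gain}))
    rng = np.random.default_rng(seed)
    p_true = _probe_probs_vec(conditions, isi, gap, true_params.gain,
                              true_params.decay, true_params.temperature,
                              true_params.lapse)
    truth = {"gain": true_params.gain, "decay": true_params.decay,
             "temperature": true_params.temperature}
    estimates: dict[str, list[float]] = {}
    covered: dict[str, int] = {}
    for _ in range(reps):
        k = rng.binomial(n_per, p_true)
        table = ContingencyTable(
            row_labels=tuple(f"c{i}" for i in range(len(conditions))),
            col_labels=("chose_first", "chose_second"),
            counts=np.column_stack([k, n_per - k]),
        )
        fit = fit_trace_probes(table, conditions=conditions, isi=isi,
                               retention_gap=gap, fixed=fixed, ci=True)
        for name, (lo, hi) in (fit.ci or {}).items():
            estimates.setdefault(name, []).append(fit.estimates[name])
            if lo <= truth[name] <= hi:
                covered[name] = covered.get(name, 0) + 1
    report: dict = {"reps": reps, "seed": seed, "n_per_condition": n_per,
                    "parameters": {}}
    for name, vals in estimates.items():
        arr = np.asarray(vals)
        report["parameters"][name] = {
            "true": truth[name],
            "bias": float(arr.mean() - truth[name]),
            "rmse": float(np.sqrt(((arr - truth[name]) ** 2).mean())),
            "ci_coverage": covered.get(name, 0) / reps,
        }
    return report


def lr_test(fit_full: FitResult, fit_null: FitResult, df: int) -> TestResult:
    """Likelihood-ratio test of nested fits: 2*delta-log-likelihood vs chi2(df)."""
    if df <= 0:
        raise ValueError("df must be > 0")
    deviance = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    if deviance < -1e-8:
        raise OptimizationError(
            f"full model fits worse than null (deviance {deviance:.3g}); "
            "optimization failed"
        )
    deviance = max(deviance, 0.0)
    p = float(sps.chi2.sf(deviance, df))
    return TestResult(statistic=float(deviance), df=df, p_value=p,
                      method="likelihood_ratio",
                      n=fit_full.n_obs)
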