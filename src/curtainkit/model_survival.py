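"""Photobleaching-corrected dwell-time analysis for multi-binding-site arrays.

Fluorescent spots on a DNA curtain disappear either because the protein
dissociates (lifetime ``tau``) or because its dye photobleaches (lifetime
``tau_nu`` at 100% illumination, diluted by the laser duty cycle ``r``,
the off-time/on-time ratio of the framed illumination).  A single
fluorophore therefore vanishes after an exponential waiting time with
effective mean

    lambda = (1/tau + 1/(r * tau_nu))**-1

On an array of ``N`` binding sites where each site carries a labeled
protein with probability ``l`` (the labeling ratio), the spot disappears
when the *last* of the ``i`` labeled molecules is gone.  With
``C_i(t) = (1 - exp(-t/lambda))**i`` (the CDF of the maximum of ``i``
i.i.d. exponentials) and binomial weights ``B(i, l, N)`` conditioned on
at least one label, the survival of a spot observed from cut-off time
``c`` onward is

    S(t) = 1 - sum_{i=1..N} [(C_i(t) - C_i(c)) / (1 - C_i(c))]
                 * B(i, l, N) / (1 - B(0, l, N))

This module provides that model, Kaplan-Meier estimation with Greenwood
variance, single-exponential fits, a z-test for lifetime comparison, and
a global fit that shares parameters across measurements: one ``tau_nu``
for all datasets, one ``r`` per frame delay, (``N``, ``l``) fixed per
DNA substrate, one ``tau`` per protein construct and a fixed cut-off
``c`` per measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FrameSchedule",
    "KineticParams",
    "SpotDataset",
    "SurvivalCurve",
    "GlobalFitSpec",
    "GlobalFitResult",
    "effective_lambda",
    "binomial_weight",
    "survival_model",
    "kaplan_meier",
    "fit_global",
    "fit_single_exponential",
    "fit_exponential_curve",
    "compare_lifetimes_ztest",
    "UnderIdentifiedWarning",
]


class UnderIdentifiedWarning(UserWarning):
    """The sharing spec leaves a structurally unidentified direction."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Framed illumination timing: ``illumination_time`` seconds of laser-on
    per frame followed by ``frame_delay`` seconds of laser-off."""

    illumination_time: float
    frame_delay: float

    def __post_init__(self) -> None:
        if not self.illumination_time > 0:
            raise ValueError(f"illumination_time must be > 0, got {self.illumination_time}")
        if self.frame_delay < 0:
            raise ValueError(f"frame_delay must be >= 0, got {self.frame_delay}")

    @property
    def r_init(self) -> float:
        """Duty-cycle ratio used to initialise (or fix) the fit parameter r."""
        return self.frame_delay / self.illumination_time

    @property
    def frame_interval(self) -> float:
        return self.illumination_time + self.frame_delay


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameter set of the multi-site disappearance model.

    ``tau`` and ``tau_nu`` accept ``math.inf`` as an explicit sentinel for
    "no dissociation" / "no photobleaching"; these limits are handled
    analytically throughout.
    """

    tau: float
    tau_nu: float
    r: float
    N: int = 1
    l: float = 1.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0 (or inf), got {self.tau}")
        if not (self.tau_nu > 0):
            raise ValueError(f"tau_nu must be > 0 (or inf), got {self.tau_nu}")
        if not (self.r > 0):
            raise ValueError(f"r must be > 0, got {self.r}")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        if not (0 <= self.l <= 1):
            raise ValueError(f"l must lie in [0, 1], got {self.l}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")

    @property
    def lam(self) -> float:
        """Effective single-fluorophore disappearance time (s)."""
        return effective_lambda(self.tau, self.tau_nu, self.r)


@dataclass
class SpotDataset:
    """Disappearance times (s, from observation start) of the spots of one
    measurement, with right-censoring flags (True = still present at the
    end of the recording)."""

    disappearance_times: np.ndarray
    censored: np.ndarray
    schedule: FrameSchedule
    construct_id: str = "construct"
    dna_id: str = "dna"
    measurement_id: str = "measurement"
    c: float = 0.0

    def __post_init__(self) -> None:
        self.disappearance_times = np.asarray(self.disappearance_times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.disappearance_times.shape != self.censored.shape:
            raise ValueError("disappearance_times and censored must have equal length")
        if self.disappearance_times.size == 0:
            raise ValueError(f"measurement {self.measurement_id!r} is empty")
        if np.any(self.disappearance_times < self.c):
            raise ValueError(
                f"measurement {self.measurement_id!r} has times below the cut-off c={self.c}"
            )

    @property
    def n_events(self) -> int:
        return int(np.sum(~self.censored))


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct uncensored event
    times, with Greenwood variance."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray


@dataclass
class GlobalFitSpec:
    """Parameter-sharing layout for :func:`fit_global`.

    dna_params
        ``dna_id -> (N, l)``; fixed unless ``free_l``.
    free_r
        If True, r is a free bounded parameter per distinct frame delay
        (bounds ``r_init/r_bound_factor .. r_init*r_bound_factor``).  The
        default keeps r fixed at the duty-cycle ratio: with a single
        construct the per-delay effective lifetimes are the only
        observables, and freeing every r makes tau structurally
        unidentifiable.
    fixed
        Optional hard assignments, e.g. ``{"tau_nu": math.inf}`` or
        ``{"tau:myconstruct": math.inf}``; infinities switch the
        corresponding channel off analytically.
    """

    dna_params: Mapping[str, tuple[int, float]]
    tau_init: Mapping[str, float] | float | None = None
    tau_nu_init: float = 100.0
    free_r: bool = False
    free_l: bool = False
    r_bound_factor: float = 10.0
    tau_bounds: tuple[float, float] = (1e-2, 1e8)
    tau_nu_bounds: tuple[float, float] = (1e-2, 1e8)
    l_bounds: tuple[float, float] = (1e-3, 1.0)
    fixed: Mapping[str, float] = field(default_factory=dict)
    objective: str = "wls"  # "wls" (default) or "mle"
    n_starts: int = 5
    start_seed: int = 0
    variance_floor: float = 1e-4


@dataclass
class GlobalFitResult:
    estimates: dict[str, float]
    stderr: dict[str, float]
    converged: bool
    objective_value: float
    n_datasets: int
    n_points: int
    per_dataset_rms: dict[str, float]
    warnings: list[str]
    start_seeds: list[int]

    def tau(self, construct_id: str) -> float:
        return self.estimates[f"tau:{construct_id}"]

    def tau_se(self, construct_id: str) -> float:
        return self.stderr[f"tau:{construct_id}"]


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------


def effective_lambda(tau: float, tau_nu: float, r: float) -> float:
    """Effective single-fluorophore disappearance time (s).

    ``lambda = (1/tau + 1/(r*tau_nu))**-1``.  ``math.inf`` is accepted for
    ``tau`` (no dissociation, bleaching only) or ``tau_nu`` (no bleaching),
    but not both.
    """
    if not (tau > 0):
        raise ValueError(f"tau must be > 0 (or inf), got {tau}")
    if not (tau_nu > 0):
        raise ValueError(f"tau_nu must be > 0 (or inf), got {tau_nu}")
    if not (r > 0) or math.isinf(r):
        raise ValueError(f"r must be a positive finite ratio, got {r}")
    rate = (0.0 if math.isinf(tau) else 1.0 / tau) + (
        0.0 if math.isinf(tau_nu) else 1.0 / (r * tau_nu)
    )
    if rate == 0.0:
        raise ValueError("tau and tau_nu cannot both be infinite")
    return 1.0 / rate


def binomial_weight(i: int, l: float, N: int) -> float:
    """Probability that exactly ``i`` of ``N`` sites carry a labeled
    molecule: ``C(N, i) * l**i * (1-l)**(N-i)``."""
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValueError(f"N must be an integer >= 1, got {N}")
    if not (isinstance(i, (int, np.integer)) and 0 <= i <= N):
        raise ValueError(f"i must be an integer in [0, {N}], got {i}")
    if not (0 <= l <= 1):
        raise ValueError(f"l must lie in [0, 1], got {l}")
    return math.comb(N, i) * l**i * (1.0 - l) ** (N - i)


def _component_cdf(t: np.ndarray, i: int, lam: float) -> np.ndarray:
    # C_i(t) = (1 - exp(-t/lam))**i, the CDF of the max of i exponentials
    return np.power(-np.expm1(-t / lam), i)


def survival_model(
    t: float | np.ndarray, params: KineticParams
) -> float | np.ndarray:
    """Model survival probability of a fluorescent spot at time ``t`` (s),
    conditioned on presence at the cut-off ``params.c``."""
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if params.l == 0:
        raise ValueError("l = 0 leaves no labeled molecules; survival undefined")
    if np.any(t_arr < params.c - 1e-12):
        raise ValueError(f"t must be >= the cut-off c = {params.c}")
    lam = params.lam
    N, l, c = params.N, params.l, params.c
    # normalize by the explicit sum over i >= 1 (equal to 1 - B(0,l,N)
    # analytically, but exact in floating point, so the N = 1 case
    # collapses to a clean exponential)
    weights = np.array([binomial_weight(i, l, N) for i in range(1, N + 1)])
    weights /= weights.sum()
    s = np.ones_like(t_arr)
    for i in range(1, N + 1):
        ci_t = _component_cdf(t_arr, i, lam)
        ci_c = _component_cdf(np.asarray([c]), i, lam)[0]
        s = s - weights[i - 1] * (ci_t - ci_c) / (1.0 - ci_c)
    s = np.clip(s, 0.0, 1.0)
    return float(s[0]) if scalar else s


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def kaplan_meier(data: SpotDataset) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood variance.

    Evaluated at the distinct uncensored event times; censored spots leave
    the risk set at their censoring time (ties: events before censorings,
    the standard convention).
    """
    if data.n_events == 0:
        raise ValueError(
            f"measurement {data.measurement_id!r} has no uncensored events"
        )
    times = data.disappearance_times
    events = ~data.censored
    order = np.lexsort((~events, times))  # by time, events first on ties
    times, events = times[order], events[order]

    event_times = np.unique(times[events])
    surv = np.empty_like(event_times)
    var = np.empty_like(event_times)
    at_risk = np.empty(event_times.size, dtype=int)

    s = 1.0
    greenwood = 0.0
    n = times.size
    for j, tj in enumerate(event_times):
        nj = int(np.sum(times >= tj))
        dj = int(np.sum(times[events] == tj))
        s *= 1.0 - dj / nj
        if nj > dj:
            greenwood += dj / (nj * (nj - dj))
        else:
            greenwood = math.inf  # S hits 0; variance of log undefined
        at_risk[j] = nj
        surv[j] = s
        var[j] = s * s * greenwood if math.isfinite(greenwood) else 0.0
    return SurvivalCurve(times=event_times, survival=surv, at_risk=at_risk, variance=var)


# ---------------------------------------------------------------------------
# single-exponential fits and z-test
# ---------------------------------------------------------------------------


def fit_exponential_curve(
    times: np.ndarray,
    survival: np.ndarray,
    weights: np.ndarray | None = None,
    c: float = 0.0,
) -> tuple[float, float]:
    """Weighted least-squares fit of ``S(t) = exp(-(t - c)/tau)`` to a
    survival curve; returns ``(tau, se)``."""
    times = np.asarray(times, dtype=float)
    survival = np.asarray(survival, dtype=float)
    if weights is None:
        weights = np.ones_like(times)
    w = np.sqrt(np.asarray(weights, dtype=float))
    tau0 = max(np.mean(times - c), 1e-6)

    def resid(log_tau: np.ndarray) -> np.ndarray:
        return w * (survival - np.exp(-(times - c) / np.exp(log_tau[0])))

    res = optimize.least_squares(resid, x0=[math.log(tau0)], method="lm")
    tau_hat = float(np.exp(res.x[0]))
    m = times.size
    dof = max(m - 1, 1)
    jtj = float(res.jac[:, 0] @ res.jac[:, 0])
    var_log = (2.0 * res.cost / dof) / jtj if jtj > 0 else math.inf
    return tau_hat, tau_hat * math.sqrt(var_log)


def fit_single_exponential(data: SpotDataset) -> tuple[float, float]:
    """Exponential lifetime fitted to the Kaplan-Meier curve of one
    measurement; returns ``(tau, se)``."""
    if data.n_events < 5:
        raise ValueError(
            f"need >= 5 uncensored events, measurement {data.measurement_id!r} "
            f"has {data.n_events}"
        )
    events = data.disappearance_times[~data.censored]
    if np.ptp(events) == 0:
        raise ValueError(
            f"degenerate input: all event times equal in {data.measurement_id!r}"
        )
    curve = kaplan_meier(data)
    weights = 1.0 / np.maximum(curve.variance, 1e-4)
    return fit_exponential_curve(curve.times, curve.survival, weights, c=data.c)


def compare_lifetimes_ztest(
    tau1: float, se1: float, tau2: float, se2: float
) -> tuple[float, float]:
    """Two-tailed z-test for a lifetime difference; returns ``(z, p)``."""
    if not (se1 > 0 and se2 > 0):
        raise ValueError("standard errors must be positive")
    z = (tau1 - tau2) / math.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------


class _ParamLayout:
    """Maps the shared-parameter structure onto a flat log-space vector."""

    def __init__(self, datasets: Sequence[SpotDataset], spec: GlobalFitSpec):
        self.constructs = sorted({d.construct_id for d in datasets})
        self.delays = sorted({d.schedule.frame_delay for d in datasets})
        self.dnas = sorted({d.dna_id for d in datasets})
        for d in datasets:
            if d.dna_id not in spec.dna_params:
                raise ValueError(f"dna_id {d.dna_id!r} missing from spec.dna_params")
        self.names: list[str] = []       # free parameters, log-space
        self.bounds: list[tuple[float, float]] = []
        self.inits: list[float] = []
        self.fixed: dict[str, float] = dict(spec.fixed)
        self.spec = spec

        r_init_by_delay: dict[float, float] = {}
        for d in datasets:
            r_init_by_delay.setdefault(d.schedule.frame_delay, d.schedule.r_init)
        self.r_init_by_delay = r_init_by_delay

        def add(name: str, init: float, bounds: tuple[float, float]) -> None:
            if name in self.fixed:
                return
            self.names.append(name)
            self.inits.append(math.log(init))
            self.bounds.append((math.log(bounds[0]), math.log(bounds[1])))

        for cid in self.constructs:
            if isinstance(spec.tau_init, Mapping):
                t0 = spec.tau_init.get(cid)
            else:
                t0 = spec.tau_init
            if t0 is None:
                # crude moment start: mean uncensored time across the construct
                ts = np.concatenate(
                    [
                        d.disappearance_times[~d.censored]
                        for d in datasets
                        if d.construct_id == cid
                    ]
                )
                t0 = float(np.clip(np.mean(ts), *spec.tau_bounds))
            add(f"tau:{cid}", t0, spec.tau_bounds)
        add("tau_nu", spec.tau_nu_init, spec.tau_nu_bounds)
        for delay in self.delays:
            r0 = max(r_init_by_delay[delay], 1e-6)
            if spec.free_r:
                add(
                    f"r:{delay:g}",
                    r0,
                    (r0 / spec.r_bound_factor, r0 * spec.r_bound_factor),
                )
            else:
                self.fixed.setdefault(f"r:{delay:g}", r0)
        if spec.free_l:
            for dna in self.dnas:
                add(f"l:{dna}", spec.dna_params[dna][1], spec.l_bounds)

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        vals = {n: float(np.exp(v)) for n, v in zip(self.names, x)}
        vals.update(self.fixed)
        return vals

    def params_for(self, d: SpotDataset, vals: Mapping[str, float]) -> KineticParams:
        N, l_fixed = self.spec.dna_params[d.dna_id]
        l = vals.get(f"l:{d.dna_id}", l_fixed)
        return KineticParams(
            tau=vals[f"tau:{d.construct_id}"],
            tau_nu=vals["tau_nu"],
            r=vals[f"r:{d.schedule.frame_delay:g}"],
            N=int(N),
            l=float(l),
            c=d.c,
        )


def _curve_residuals(
    datasets: Sequence[SpotDataset],
    curves: Sequence[SurvivalCurve],
    layout: _ParamLayout,
    floor: float,
) -> tuple:
    sw = [np.sqrt(1.0 / np.maximum(cv.variance, floor)) for cv in curves]

    def resid(x: np.ndarray) -> np.ndarray:
        vals = layout.unpack(x)
        parts = []
        for d, cv, w in zip(datasets, curves, sw):
            model = survival_model(cv.times, layout.params_for(d, vals))
            parts.append(w * (cv.survival - model))
        return np.concatenate(parts)

    return resid, sw


def _nll(
    datasets: Sequence[SpotDataset], layout: _ParamLayout
) -> "callable":
    def nll(x: np.ndarray) -> float:
        vals = layout.unpack(x)
        total = 0.0
        for d in datasets:
            p = layout.params_for(d, vals)
            t = d.disappearance_times
            ev = ~d.censored
            s = np.asarray(survival_model(t, p))
            # density by centred finite difference of S (robust to the inf
            # sentinels; h scaled to lambda)
            h = max(p.lam * 1e-5, 1e-9)
            s_hi = np.asarray(survival_model(np.maximum(t[ev] + h, p.c), p))
            s_lo = np.asarray(survival_model(np.maximum(t[ev] - h, p.c), p))
            dens = np.maximum((s_lo - s_hi) / (2 * h), 1e-300)
            total -= float(np.sum(np.log(dens)))
            total -= float(np.sum(np.log(np.maximum(s[~ev], 1e-300))))
        return total

    return nll


def fit_global(
    datasets: Sequence[SpotDataset],
    spec: GlobalFitSpec,
    curves: Sequence[SurvivalCurve] | None = None,
) -> GlobalFitResult:
    """Global weighted least-squares fit of the multi-site survival model.

    The Kaplan-Meier curve of each measurement (computed here unless
    ``curves`` is supplied, e.g. for noiseless self-consistency checks) is
    fitted jointly against :func:`survival_model` under the sharing layout
    of ``spec``, with inverse-Greenwood weights floored at
    ``spec.variance_floor``.  Multi-start bounded trust-region least
    squares; among equal-objective solutions the one whose r values sit
    closest to the duty-cycle ratios wins (the flat rescaling direction
    between tau_nu and the r's is broken by that tie-break, not by data).
    """
    if len(datasets) == 0:
        raise ValueError("no datasets supplied")
    layout = _ParamLayout(datasets, spec)
    warn_msgs: list[str] = []
    if len(layout.delays) < 2 and "tau_nu" in layout.names:
        msg = (
            "single frame delay with free tau and tau_nu: the fit is "
            "under-identified (only the effective lambda is constrained)"
        )
        warnings.warn(msg, UnderIdentifiedWarning)
        warn_msgs.append(msg)
    if spec.free_r and "tau_nu" in layout.names:
        msg = (
            "free r per delay together with free tau_nu leaves a flat "
            "rescaling direction; estimates rely on bounds and tie-breaks"
        )
        warnings.warn(msg, UnderIdentifiedWarning)
        warn_msgs.append(msg)

    if curves is None:
        curves = [kaplan_meier(d) for d in datasets]
    elif len(curves) != len(datasets):
        raise ValueError("curves must parallel datasets")

    x0 = np.array(layout.inits)
    lo = np.array([b[0] for b in layout.bounds])
    hi = np.array([b[1] for b in layout.bounds])
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(spec.start_seed)
    starts = [x0]
    start_seeds = [int(spec.start_seed)]
    for k in range(1, max(spec.n_starts, 1)):
        starts.append(np.clip(x0 + rng.uniform(-0.35, 0.35, size=x0.size), lo, hi))
        start_seeds.append(int(spec.start_seed))

    if spec.objective == "mle":
        fun = _nll(datasets, layout)
        best = None
        for s0 in starts:
            res = optimize.minimize(
                fun, s0, method="L-BFGS-B", bounds=list(zip(lo, hi))
            )
            if best is None or res.fun < best.fun:
                best = res
        vals = layout.unpack(best.x)
        # curvature-based SEs via numerical Hessian of the NLL in log-space
        hess = _numeric_hessian(fun, best.x)
        cov = np.linalg.pinv(hess)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {
            n: vals[n] * se_log[i] for i, n in enumerate(layout.names)
        }
        stderr.update({n: 0.0 for n in layout.fixed})
        per_rms = {d.measurement_id: float("nan") for d in datasets}
        return GlobalFitResult(
            estimates=vals,
            stderr=stderr,
            converged=bool(best.success),
            objective_value=float(best.fun),
            n_datasets=len(datasets),
            n_points=int(sum(d.disappearance_times.size for d in datasets)),
            per_dataset_rms=per_rms,
            warnings=warn_msgs,
            start_seeds=start_seeds,
        )
    if spec.objective != "wls":
        raise ValueError(f"unknown objective {spec.objective!r}")

    resid, _ = _curve_residuals(datasets, curves, layout, spec.variance_floor)
    solutions = []
    for s0 in starts:
        res = optimize.least_squares(
            resid, s0, bounds=(lo, hi), method="trf", x_scale="jac"
        )
        r_dev = 0.0
        vals = layout.unpack(res.x)
        for delay in layout.delays:
            r_dev += abs(math.log(vals[f"r:{delay:g}"] / layout.r_init_by_delay[delay]))
        solutions.append((res.cost, r_dev, res))
    solutions.sort(key=lambda t: (round(t[0], 10), t[1]))
    best = solutions[0][2]
    if not best.success:
        msg = f"optimizer did not converge (status {best.status}): {best.message}"
        warnings.warn(msg, RuntimeWarning)
        warn_msgs.append(msg)

    vals = layout.unpack(best.x)
    m = best.fun.size
    p = best.x.size
    scale = 2.0 * best.cost / max(m - p, 1)
    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * scale
    se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    stderr = {n: vals[n] * se_log[i] for i, n in enumerate(layout.names)}
    stderr.update({n: 0.0 for n in layout.fixed})

    per_rms = {}
    offset = 0
    r_all = best.fun
    for d, cv in zip(datasets, curves):
        k = cv.times.size
        per_rms[d.measurement_id] = float(
            np.sqrt(np.mean(r_all[offset : offset + k] ** 2))
        )
        offset += k
    return GlobalFitResult(
        estimates=vals,
        stderr=stderr,
        converged=bool(best.success),
        objective_value=float(best.cost),
        n_datasets=len(datasets),
        n_points=m,
        per_dataset_rms=per_rms,
        warnings=warn_msgs,
        start_seeds=start_seeds,
    )


def _numeric_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    hess = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return hess
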