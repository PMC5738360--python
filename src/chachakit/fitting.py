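"""Nonlinear least-squares estimation of the reporter models.

Three fits are provided: the steady-state reporter surface
G = G_max * L/(L+K_L) * A^n/(K_A+A^n) on adaptor-by-dose grids (the
stoichiometry fit), the 4PL Hill dose-response curve (EC50), and the
dox-induction Hill curve (cooperativity check). All fits share one engine:

* positive parameters are optimized in log10 space, which makes positivity
  structural and the multi-start grid a plain lattice;
* a deterministic multi-start over a 3-point-per-parameter log grid spanning
  +/-2 decades around moment-based initial guesses; the start with the best
  final loss wins, so fits are reproducible without a seed;
* standard errors come from the regression curvature (lmfit's covariance),
  mapped back to the natural scale by the delta method;
* goodness of fit is reported as the Pearson correlation r between observed
  and fitted responses.

Fitting is unweighted on linear response values. An optional additive basal
parameter ``G0`` is available for leaky real data (default off, so the core
surface is fit exactly as derived).
"""

from __future__ import annotations

import itertools
import json
import warnings
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .model_core import chacha_steady_state_gfp
from .params import SteadyStateParams

__all__ = [
    "FitResult",
    "IdentifiabilityError",
    "FitConvergenceError",
    "fit_steady_state_model",
    "fit_hill_dose_response",
    "fit_dox_hill",
    "pearson_r",
]

LN10 = math.log(10.0)


class IdentifiabilityError(ValueError):
    """The design cannot identify the requested free parameters."""


class FitConvergenceError(RuntimeError):
    """No multi-start converged to a usable optimum."""


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``estimates``/``standard_errors`` are on the natural parameter scale;
    ``r`` is the Pearson correlation between observed and fitted responses;
    ``seed_or_starts`` records every multi-start initial point with its final
    loss; ``loss_trace`` is the best-so-far loss across accepted starts
    (nonincreasing by construction).
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float | None]
    r: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    seed_or_starts: list[dict] = field(default_factory=list)
    loss_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "r": self.r,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(indent=2) + "\n")


def pearson_r(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Pearson correlation between observed and fitted responses."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 3:
        raise ValueError("need >=3 paired values")
    if np.ptp(obs) == 0 or np.ptp(fit) == 0:
        raise ValueError("zero variance in observed or fitted values")
    return float(stats.pearsonr(obs, fit).statistic)


@dataclass(frozen=True)
class _ParamSpec:
    name: str
    init: float
    log: bool = True
    lo: float | None = None  # natural-scale bounds
    hi: float | None = None
    vary: bool = True


def _build_params(specs: Sequence[_ParamSpec], start: dict[str, float]) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for s in specs:
        value = start.get(s.name, s.init)
        if s.log:
            lo = -np.inf if s.lo is None else math.log10(s.lo)
            hi = np.inf if s.hi is None else math.log10(s.hi)
            params.add(
                f"log10_{s.name}",
                value=float(np.clip(math.log10(value), lo, hi)),
                min=lo,
                max=hi,
                vary=s.vary,
            )
        else:
            params.add(
                s.name,
                value=value,
                min=-np.inf if s.lo is None else s.lo,
                max=np.inf if s.hi is None else s.hi,
                vary=s.vary,
            )
    return params


def _natural_values(specs: Sequence[_ParamSpec], params: lmfit.Parameters) -> dict[str, float]:
    out = {}
    for s in specs:
        if s.log:
            out[s.name] = 10.0 ** params[f"log10_{s.name}"].value
        else:
            out[s.name] = params[s.name].value
    return out


def _natural_stderr(specs: Sequence[_ParamSpec], params: lmfit.Parameters) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for s in specs:
        if not s.vary:
            out[s.name] = None
            continue
        if s.log:
            p = params[f"log10_{s.name}"]
            out[s.name] = (
                None if p.stderr is None else LN10 * (10.0**p.value) * p.stderr
            )
        else:
            p = params[s.name]
            out[s.name] = p.stderr
    return out


def _start_grid(
    specs: Sequence[_ParamSpec], n_points: int = 3, decades: float = 2.0
) -> list[dict[str, float]]:
    """Deterministic log lattice around the moment-based initial guesses."""
    axes: list[list[tuple[str, float]]] = []
    for s in specs:
        if not s.vary or not s.log:
            continue
        factors = np.logspace(-decades, decades, n_points)
        values = s.init * factors
        if s.lo is not None or s.hi is not None:
            values = np.clip(values, s.lo, s.hi)
        values = sorted(set(float(v) for v in values))
        axes.append([(s.name, v) for v in values])
    if not axes:
        return [{}]
    return [dict(combo) for combo in itertools.product(*axes)]


def _multistart_fit(
    specs: Sequence[_ParamSpec],
    residual,
    starts: list[dict[str, float]],
    max_nfev: int | None = None,
) -> tuple[lmfit.minimizer.MinimizerResult, list[dict], list[float]]:
    best = None
    start_log: list[dict] = []
    trace: list[float] = []
    for start in starts:
        params = _build_params(specs, start)
        try:
            with warnings.catch_warnings():
                # flat directions at poor starts make lmfit's covariance
                # momentarily invalid; only the winning start's errors matter
                warnings.simplefilter("ignore", RuntimeWarning)
                result = lmfit.minimize(
                    residual,
                    params,
                    method="least_squares",
                    nan_policy="raise",
                    max_nfev=max_nfev,
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                )
        except Exception as exc:  # a single bad start must not kill the fit
            start_log.append({"start": dict(start), "loss": None, "error": str(exc)})
            continue
        loss = float(result.chisqr)
        start_log.append({"start": dict(start), "loss": loss})
        if best is None or loss < best[0]:
            best = (loss, result)
            trace.append(loss)
    if best is None:
        raise FitConvergenceError("every multi-start failed")
    return best[1], start_log, trace


def _finish(
    specs: Sequence[_ParamSpec],
    result: lmfit.minimizer.MinimizerResult,
    observed: np.ndarray,
    model_fn,
    start_log: list[dict],
    trace: list[float],
) -> FitResult:
    estimates = _natural_values(specs, result.params)
    fitted = model_fn(estimates)
    return FitResult(
        estimates=estimates,
        standard_errors=_natural_stderr(specs, result.params),
        r=pearson_r(observed, fitted),
        residuals=observed - fitted,
        converged=bool(result.success),
        n_iter=int(result.nfev),
        seed_or_starts=start_log,
        loss_trace=trace,
    )


def _geomedian(values: np.ndarray) -> float:
    values = values[values > 0]
    return float(np.exp(np.median(np.log(values))))


STEADY_STATE_NAMES = ("G_max", "K_L", "K_A", "n_stoich")


def fit_steady_state_model(
    data: pd.DataFrame,
    free: Sequence[str] = STEADY_STATE_NAMES,
    fixed: dict[str, float] | None = None,
    use_true_adaptor: bool = False,
    basal: bool = False,
    n_starts_per_param: int = 3,
) -> FitResult:
    """Fit the steady-state reporter surface to a grid dataset.

    ``data`` must carry columns adaptor_level, ligand_dose, replicate, gfp,
    adaptor_readout. The adaptor covariate is the noisy ``adaptor_readout``
    (a fluorescent proxy of adaptor expression) unless ``use_true_adaptor``;
    errors-in-variables correction is deliberately not attempted. Parameters
    not in ``free`` must be supplied through ``fixed``. ``basal`` adds an
    additive baseline G0 for leaky data (off by default so the fitted surface
    is exactly the derived closed form).
    """
    free = tuple(free)
    fixed = dict(fixed or {})
    unknown = set(free) - set(STEADY_STATE_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    for name in STEADY_STATE_NAMES:
        if name not in free and name not in fixed:
            raise ValueError(f"parameter {name} is neither free nor fixed")

    doses = data["ligand_dose"].to_numpy(float)
    design_levels = data["adaptor_level"].to_numpy(float)
    adaptor = (
        design_levels if use_true_adaptor else data["adaptor_readout"].to_numpy(float)
    )
    gfp = data["gfp"].to_numpy(float)

    n_levels = len(np.unique(design_levels))
    n_doses = len(np.unique(doses))
    if "n_stoich" in free and (n_levels < 2 or n_doses < 2):
        raise IdentifiabilityError(
            "fitting n_stoich requires >=2 distinct adaptor levels and >=2 doses "
            f"(got {n_levels} levels, {n_doses} doses)"
        )
    if ("K_L" in free and n_doses < 2) or ("K_A" in free and n_levels < 2):
        raise IdentifiabilityError(
            f"design too thin: {n_levels} adaptor levels, {n_doses} doses"
        )

    n0 = 1.0
    inits = {
        "G_max": float(np.max(gfp)) if np.max(gfp) > 0 else 1.0,
        "K_L": _geomedian(doses),
        "K_A": _geomedian(adaptor) ** n0,
        "n_stoich": n0,
    }
    specs = [
        _ParamSpec("G_max", inits["G_max"], vary="G_max" in free),
        _ParamSpec("K_L", inits["K_L"], vary="K_L" in free),
        _ParamSpec("K_A", inits["K_A"], vary="K_A" in free),
        _ParamSpec("n_stoich", inits["n_stoich"], lo=0.1, hi=10.0, vary="n_stoich" in free),
    ]
    for s in specs:
        if not s.vary:
            object.__setattr__(s, "init", fixed[s.name])
    if basal:
        specs.append(_ParamSpec("G0", float(np.min(gfp)), log=False, lo=0.0))

    def surface(values: dict[str, float]) -> np.ndarray:
        p = SteadyStateParams(
            G_max=values["G_max"],
            K_L=values["K_L"],
            K_A=values["K_A"],
            n_stoich=values["n_stoich"],
        )
        out = chacha_steady_state_gfp(doses, adaptor, p)
        return out + values.get("G0", 0.0)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        return surface(_natural_values(specs, params)) - gfp

    starts = _start_grid(specs, n_points=n_starts_per_param)
    result, start_log, trace = _multistart_fit(specs, residual, starts)
    return _finish(specs, result, gfp, surface, start_log, trace)


def fit_hill_dose_response(
    data: pd.DataFrame, fix_bottom: float | None = None, n_starts_per_param: int = 3
) -> FitResult:
    """Fit the 4PL Hill curve to a dose-response series.

    ``data`` needs columns ligand_dose and gfp (replicate optional). The
    estimates populate :class:`~chachakit.params.DoseResponseParams` fields
    (bottom, top, EC50, hill_slope); EC50 is reported with its standard error.
    """
    doses = data["ligand_dose"].to_numpy(float)
    gfp = data["gfp"].to_numpy(float)
    unique_doses = np.unique(doses)
    if unique_doses.size < 4:
        raise IdentifiabilityError(
            f"need >=4 distinct doses, got {unique_doses.size}"
        )

    means = pd.Series(gfp).groupby(doses).mean()
    b0 = max(float(means.min()), 0.0)
    t0 = float(means.max())
    half = 0.5 * (b0 + t0)
    ec50_0 = float(means.index[np.argmin(np.abs(means.to_numpy() - half))])
    if ec50_0 <= 0:
        ec50_0 = _geomedian(unique_doses)
    specs = [
        _ParamSpec("bottom", b0, log=False, lo=0.0, vary=fix_bottom is None),
        _ParamSpec("top", t0),
        _ParamSpec("EC50", ec50_0),
        _ParamSpec("hill_slope", 1.0, lo=0.1, hi=10.0),
    ]
    if fix_bottom is not None:
        object.__setattr__(specs[0], "init", fix_bottom)

    def curve(values: dict[str, float]) -> np.ndarray:
        # evaluate the 4PL directly: the optimizer may transiently propose
        # top < bottom, which the validated parameter type would reject
        dh = np.power(doses, values["hill_slope"])
        frac = dh / (values["EC50"] ** values["hill_slope"] + dh)
        return values["bottom"] + (values["top"] - values["bottom"]) * frac

    def residual(params: lmfit.Parameters) -> np.ndarray:
        return curve(_natural_values(specs, params)) - gfp

    starts = _start_grid(specs, n_points=n_starts_per_param)
    result, start_log, trace = _multistart_fit(specs, residual, starts)
    return _finish(specs, result, gfp, curve, start_log, trace)


def fit_dox_hill(data: pd.DataFrame, n_starts_per_param: int = 3) -> FitResult:
    """Fit the dox-induction Hill curve G = G_max_dox * D^n/(K_D + D^n).

    ``data`` needs columns dox_level and gfp. ``n_hill`` is the cooperativity
    of interest and is reported with its standard error; K_D carries units of
    dose**n_hill (the denominator is K_D + D^n as written, not K_D^n).
    """
    dox = data["dox_level"].to_numpy(float)
    gfp = data["gfp"].to_numpy(float)
    unique = np.unique(dox)
    if unique.size < 4:
        raise IdentifiabilityError(f"need >=4 distinct dox levels, got {unique.size}")

    g0 = float(np.max(gfp)) if np.max(gfp) > 0 else 1.0
    kd0 = _geomedian(unique)
    specs = [
        _ParamSpec("G_max_dox", g0),
        _ParamSpec("K_D", kd0),
        _ParamSpec("n_hill", 1.0, lo=0.1, hi=10.0),
    ]

    def curve(values: dict[str, float]) -> np.ndarray:
        dn = np.power(dox, values["n_hill"])
        return values["G_max_dox"] * dn / (values["K_D"] + dn)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        return curve(_natural_values(specs, params)) - gfp

    starts = _start_grid(specs, n_points=n_starts_per_param)
    result, start_log, trace = _multistart_fit(specs, residual, starts)
    return _finish(specs, result, gfp, curve, start_log, trace)
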