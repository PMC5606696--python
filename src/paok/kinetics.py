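"""Substrate-inhibition (Haldane) kinetics for competing Accumulibacter types.

The central rate law is the substrate-inhibited Michaelis–Menten form

    nu(S) = Vmax * S / ((Km + S) * (1 + S / Ki))

where ``S`` is the aerobic phosphate concentration (mg P L^-1), ``Vmax`` the
maximum specific substrate-utilization rate (per unit time), ``Km`` the
half-saturation constant and ``Ki`` the inhibition constant (both mg P L^-1).
The curve rises from zero, peaks at S = sqrt(Km*Ki) and decays at high
substrate, so two populations with different (Vmax, Km, Ki) can swap rank as
phosphate increases.  The concentration where their curves intersect — the
crossover — predicts a switch in competitive dominance between
polyphosphate-accumulating (PAO) populations enriched at different phosphate
levels.

This module provides the rate law, its analytic peak, dominance
classification on a rate grid, crossover solving (bracketed bisection with a
closed-form quadratic cross-check), least-squares parameter recovery from
noisy rate observations, and an exhaustive grid search for parameter pairs
consistent with a set of observed dominance outcomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "KineticParams",
    "RateCurve",
    "DominanceObservation",
    "FitResult",
    "DegenerateCurvesError",
    "REFERENCE_PARAMS",
    "specific_rate",
    "peak_concentration",
    "rate_curve",
    "dominant_label",
    "crossover_concentrations",
    "crossover_quadratic",
    "fit_params",
    "search_explaining_params",
]


class DegenerateCurvesError(ValueError):
    """Two rate curves are identical: every concentration is a crossover."""


@dataclass(frozen=True)
class KineticParams:
    """Haldane parameters for one population.

    Parameters
    ----------
    label : population identifier, e.g. ``"Type I"``.
    vmax : maximum specific substrate-utilization rate, per unit time.
    km : half-saturation constant, mg P L^-1.
    ki : inhibition constant, mg P L^-1.
    """

    label: str
    vmax: float
    km: float
    ki: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be non-empty")
        for name in ("vmax", "km", "ki"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


#: Assumed kinetic parameters for Accumulibacter Types I and II that explain
#: Type II dominance at low phosphate and Type I dominance at high phosphate:
#: similar affinities (Km ~ 0.5), slightly higher Vmax for Type II, and a much
#: stronger high-phosphate inhibition of Type II (Ki 300 vs 2000).
REFERENCE_PARAMS: tuple[KineticParams, KineticParams] = (
    KineticParams("Type I", vmax=0.95, km=0.48, ki=2000.0),
    KineticParams("Type II", vmax=1.0, km=0.5, ki=300.0),
)


@dataclass(frozen=True)
class RateCurve:
    """Specific rates of several populations evaluated on a concentration grid."""

    concentrations: np.ndarray
    rates: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        grid = np.asarray(self.concentrations, dtype=float)
        if grid.size == 0:
            raise ValueError("concentration grid must be non-empty")
        if np.any(grid < 0):
            raise ValueError("concentrations must be >= 0")
        if grid.size > 1 and np.any(np.diff(grid) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        for label, values in self.rates.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(f"rate array for {label!r} does not match grid")
            if np.any(arr < 0):
                raise ValueError(f"negative rate for {label!r}")
        object.__setattr__(self, "concentrations", grid)

    def to_frame(self):
        import pandas as pd

        data = {"s": self.concentrations}
        data.update({label: np.asarray(v, float) for label, v in self.rates.items()})
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DominanceObservation:
    """An observed dominant population at one aerobic phosphate concentration."""

    concentration: float
    dominant_label: str

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def specific_rate(params: KineticParams, s):
    """Haldane specific substrate-utilization rate at concentration ``s``.

    ``s`` may be a scalar or array (mg P L^-1).  Raises ``ValueError`` for
    negative concentrations.  The rate is zero only at ``s = 0`` and is
    strictly below ``vmax`` for every positive ``s``.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be >= 0")
    nu = params.vmax * arr / ((params.km + arr) * (1.0 + arr / params.ki))
    return float(nu) if np.isscalar(s) or arr.ndim == 0 else nu


def peak_concentration(params: KineticParams) -> float:
    """Concentration maximizing the Haldane rate: ``sqrt(km * ki)``.

    Setting d(nu)/dS = 0 for the rate law gives Km*Ki - S^2 = 0, so the unique
    interior maximum sits at the geometric mean of the two constants.
    """
    return math.sqrt(params.km * params.ki)


def _check_params_set(params_set: Sequence[KineticParams]) -> None:
    if not params_set:
        raise ValueError("params_set must be non-empty")
    labels = [p.label for p in params_set]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate population labels: {labels}")


def rate_curve(params_set: Sequence[KineticParams], grid) -> RateCurve:
    """Evaluate every population's rate on a shared concentration grid."""
    _check_params_set(params_set)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    rates = {p.label: specific_rate(p, grid) for p in params_set}
    return RateCurve(concentrations=grid, rates=rates)


def dominant_label(
    params_set: Sequence[KineticParams],
    s: float,
    tie_tol: float = 1e-3,
) -> str:
    """Label of the fastest population at concentration ``s``, or ``"tie"``.

    The population with the highest specific rate is expected to dominate an
    enrichment held at that concentration.  When the top two rates differ by
    less than ``tie_tol`` relative to the larger one the outcome is reported
    as ``"tie"`` — at very low phosphate the types have similar affinities and
    the model cannot resolve a winner.
    """
    _check_params_set(params_set)
    if len(params_set) < 2:
        raise ValueError("dominance needs at least two populations")
    if s < 0:
        raise ValueError("concentration must be >= 0")
    rates = np.array([specific_rate(p, s) for p in params_set])
    order = np.argsort(rates)[::-1]
    top, second = rates[order[0]], rates[order[1]]
    if top <= 0 or (top - second) / top < tie_tol:
        return "tie"
    return params_set[order[0]].label


def crossover_quadratic(a: KineticParams, b: KineticParams) -> list[float]:
    """Positive roots of the closed-form crossover quadratic.

    Cross-multiplying nu_a(S) = nu_b(S) and cancelling the trivial S = 0 root
    leaves  A*S^2 + B*S + C = 0  with
    A = Va/Kib - Vb/Kia,  B = Va(1+Kmb/Kib) - Vb(1+Kma/Kia),  C = Va*Kmb - Vb*Kma.
    Used as an independent cross-check of the numerical root-finder.
    """
    A = a.vmax / b.ki - b.vmax / a.ki
    B = a.vmax * (1.0 + b.km / b.ki) - b.vmax * (1.0 + a.km / a.ki)
    C = a.vmax * b.km - b.vmax * a.km
    if A == 0.0 and B == 0.0 and C == 0.0:
        raise DegenerateCurvesError("identical rate curves")
    if A == 0.0:
        if B == 0.0:
            return []
        root = -C / B
        return [root] if root > 0 else []
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    roots = sorted(r for r in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)) if r > 0)
    return roots


def crossover_concentrations(
    a: KineticParams,
    b: KineticParams,
    s_range: tuple[float, float] = (0.0, 1000.0),
    n_scan: int = 1000,
    rel_tol: float = 1e-9,
) -> list[float]:
    """Concentrations in ``s_range`` where the two rate curves intersect.

    Brackets sign changes of ``nu_a - nu_b`` on a log-spaced scan of
    ``n_scan`` points, then refines each bracket by bisection (brentq) to
    ``rel_tol`` relative precision.  The trivial root at S = 0 is excluded.
    An empty list means the curves do not cross in the range; identical
    parameter sets raise :class:`DegenerateCurvesError` because every
    concentration would qualify.
    """
    if (a.vmax, a.km, a.ki) == (b.vmax, b.km, b.ki):
        raise DegenerateCurvesError("identical rate curves have no isolated crossover")
    lo, hi = s_range
    if lo < 0 or hi <= lo:
        raise ValueError("s_range must satisfy 0 <= lo < hi")
    lo = max(lo, 1e-6 * hi)  # exclude the shared root at S=0

    def diff(s: float) -> float:
        return specific_rate(a, s) - specific_rate(b, s)

    grid = np.geomspace(lo, hi, n_scan)
    values = specific_rate(a, grid) - specific_rate(b, grid)
    roots: list[float] = []
    for i in np.flatnonzero(np.sign(values[:-1]) * np.sign(values[1:]) < 0):
        root = brentq(diff, grid[i], grid[i + 1], rtol=rel_tol)
        roots.append(float(root))
    # exact zeros on the scan grid count as roots too
    for i in np.flatnonzero(values == 0.0):
        roots.append(float(grid[i]))
    return sorted(set(roots))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares Haldane fit."""

    params: KineticParams
    residual_norm: float
    converged: bool
    n_obs: int
    message: str = ""


def fit_params(
    observations: Sequence[tuple[float, float]],
    init: KineticParams,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    loss: str = "absolute",
) -> FitResult:
    """Recover (Vmax, Km, Ki) from rate-vs-concentration observations.

    Parameters
    ----------
    observations : sequence of ``(s, measured_rate)`` pairs; at least four,
        and not all at the same concentration (the three-parameter model is
        unidentifiable from a single design point).
    init : starting parameter set; its label is carried to the estimate.
    bounds : optional ``(lower, upper)`` triples for (vmax, km, ki);
        defaults to strictly positive, unbounded above.
    loss : ``"absolute"`` residuals (default) or ``"log"`` residuals
        (multiplicative errors; rates span decades across the S range, so the
        log loss weights low-concentration points fairly).

    Non-convergence is reported via ``converged=False``, never raised.
    """
    obs = [(float(s), float(r)) for s, r in observations]
    if len(obs) < 4:
        raise ValueError("need at least 4 observations to fit 3 parameters")
    s_vals = np.array([s for s, _ in obs])
    y_vals = np.array([r for _, r in obs])
    if np.all(s_vals == s_vals[0]):
        raise ValueError("degenerate design: all observations at one concentration")
    if loss not in ("absolute", "log"):
        raise ValueError(f"unknown loss {loss!r}")
    if loss == "log" and np.any(y_vals <= 0):
        raise ValueError("log loss requires strictly positive observed rates")
    if bounds is None:
        bounds = ([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf])

    def model(theta: np.ndarray) -> np.ndarray:
        vmax, km, ki = theta
        return vmax * s_vals / ((km + s_vals) * (1.0 + s_vals / ki))

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu = model(theta)
        if loss == "log":
            return np.log(np.maximum(mu, 1e-300)) - np.log(y_vals)
        return mu - y_vals

    x0 = np.array([init.vmax, init.km, init.ki])
    result = least_squares(
        residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    fitted = KineticParams(
        init.label,
        vmax=float(result.x[0]),
        km=float(result.x[1]),
        ki=float(result.x[2]),
    )
    return FitResult(
        params=fitted,
        residual_norm=float(np.linalg.norm(result.fun)),
        converged=bool(result.success),
        n_obs=len(obs),
        message=str(result.message),
    )


def search_explaining_params(
    observations: Sequence[DominanceObservation],
    grid_spec: Mapping[str, Mapping[str, Iterable[float]]],
    tie_tol: float = 1e-3,
) -> list[tuple[KineticParams, ...]]:
    """Exhaustive trial-and-error scan for parameter sets explaining dominance.

    ``grid_spec`` maps each population label to per-parameter candidate grids,
    e.g. ``{"Type I": {"vmax": [...], "km": [...], "ki": [...]}, ...}``.
    Every combination in the full cross-product is tested; a combination is
    retained iff :func:`dominant_label` reproduces *every* observation
    (a tie matches nothing).  This mirrors choosing assumed kinetic constants
    by hand until the predicted dominant type matches each enrichment run.
    An empty result is a valid outcome.
    """
    if not observations:
        raise ValueError("need at least one dominance observation")
    labels = list(grid_spec)
    per_label_candidates: list[list[KineticParams]] = []
    for label in labels:
        grids = grid_spec[label]
        cands = [
            KineticParams(label, vmax=v, km=km, ki=ki)
            for v, km, ki in itertools.product(
                grids["vmax"], grids["km"], grids["ki"]
            )
        ]
        if not cands:
            raise ValueError(f"empty grid for {label!r}")
        per_label_candidates.append(cands)

    retained: list[tuple[KineticParams, ...]] = []
    for combo in itertools.product(*per_label_candidates):
        if all(
            dominant_label(combo, obs.concentration, tie_tol) == obs.dominant_label
            for obs in observations
        ):
            retained.append(tuple(combo))
    return retained
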