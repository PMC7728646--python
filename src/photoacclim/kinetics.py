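"""First-order kinetic fitting and the damage–repair equilibrium model.

Two measurements of photosystem II are modelled by the same single
exponential v(t) = baseline + amplitude * exp(-k t):

* the decay of chlorophyll *a* fluorescence yield after a single turnover
  flash in the presence of DCMU, whose rate constant k is the rate of
  S2QA- charge recombination, and
* the loss of light-saturated oxygen evolution under photoinhibitory
  illumination with lincomycin blocking repair, whose rate constant is the
  rate of the damaging reaction of photoinhibition, k_PI.

Without lincomycin, damage (first order in active centres, rate k_PI)
competes with repair (first order in inactive centres, rate k_rec), giving

    dA/dt = -k_PI A + k_rec (A0 - A)
    A(t)  = A_eq + (A0 - A_eq) exp(-(k_PI + k_rec) t),
    A_eq  = A0 k_rec / (k_PI + k_rec),

so PSII activity relaxes to a non-zero equilibrium A_eq set by the two
rate constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .containers import TimeSeries

__all__ = [
    "FitError",
    "FirstOrderFit",
    "DamageRepairModel",
    "fit_first_order",
    "kpi_from_oxygen",
    "simulate_damage_repair",
    "fit_damage_repair",
]


class FitError(RuntimeError):
    """Raised when a kinetic fit cannot be performed or does not converge.

    Carries the last parameter iterate (if any) in :attr:`last_params`.
    """

    def __init__(self, message: str, last_params: dict | None = None):
        super().__init__(message)
        self.last_params = last_params or {}


@dataclass
class FirstOrderFit:
    """Result of a single-exponential least-squares fit."""

    k: float
    amplitude: float
    baseline: float
    role: str = "generic"
    rss: float = 0.0
    n_points: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise FitError(f"fitted rate constant must be positive, got {self.k}")
        if self.rss < 0 or self.n_points < 3:
            raise FitError("invalid fit summary (rss < 0 or fewer than 3 points)")

    @property
    def halflife(self) -> float:
        return np.log(2.0) / self.k

    def predict(self, t) -> np.ndarray:
        return self.baseline + self.amplitude * np.exp(-self.k * np.asarray(t, float))


@dataclass
class DamageRepairModel:
    """Two-state photoinhibition model with concurrent damage and repair."""

    k_PI: float
    k_rec: float
    A0: float

    def __post_init__(self) -> None:
        if self.k_PI < 0 or self.k_rec < 0:
            raise ValueError("rate constants must be non-negative")
        if self.A0 <= 0:
            raise ValueError("initial activity A0 must be positive")

    @property
    def A_eq(self) -> float:
        """Equilibrium activity A0*k_rec/(k_PI + k_rec); 0 when repair is off."""
        total = self.k_PI + self.k_rec
        if total == 0:
            return self.A0
        return self.A0 * self.k_rec / total


def _auto_init_k(t: np.ndarray, v: np.ndarray, baseline0: float) -> float:
    """ln2 over the time at which the decay has lost half its amplitude."""
    amp0 = v[0] - baseline0
    target = baseline0 + amp0 / 2.0
    below = np.flatnonzero(v <= target) if amp0 > 0 else np.flatnonzero(v >= target)
    t_half = t[below[0]] if below.size else t[-1]
    if t_half <= 0:
        t_half = t[-1]
    return float(np.log(2.0) / t_half)


def fit_first_order(series: TimeSeries, fit_baseline: bool = False,
                    init_k: float | None = None,
                    role: str = "generic") -> FirstOrderFit:
    """Least-squares fit of v(t) = baseline + amplitude * exp(-k t).

    Parameters
    ----------
    series
        Signal to fit; needs at least 3 finite points.
    fit_baseline
        If False (default) the baseline is fixed at 0, i.e. the decay is
        assumed to be complete at long times.
    init_k
        Starting value for the rate constant. When omitted it is taken as
        ln 2 over the time of half-amplitude decay. On non-convergence the
        fit is restarted once at 10x and once at 0.1x the initial k.
    role
        Label recorded on the result ("recombination", "k_PI", "generic").

    Raises
    ------
    FitError
        For degenerate input (all values equal: "no decay") or if no
        restart converges; the last iterate is attached to the exception.
    """
    t, v = series.time, series.values
    if len(t) < 3:
        raise FitError("need at least 3 points for a first-order fit")
    if np.ptp(v) == 0:
        raise FitError("no decay: all values are equal")

    baseline0 = float(min(v[-1], v.min())) if fit_baseline else 0.0
    k0 = float(init_k) if init_k is not None else _auto_init_k(t, v, baseline0)
    if k0 <= 0:
        raise FitError(f"initial rate constant must be positive, got {k0}")

    model = lmfit.Model(lambda t, amplitude, k, baseline:
                        baseline + amplitude * np.exp(-k * t))
    last = None
    for k_start in (k0, 10 * k0, 0.1 * k0):
        params = model.make_params(
            amplitude=dict(value=float(v[0] - baseline0)),
            k=dict(value=k_start, min=1e-15),
            baseline=dict(value=baseline0, vary=fit_baseline),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(v, params, t=t)
        last = result
        if result.success and result.params["k"].value > 0:
            return FirstOrderFit(
                k=float(result.params["k"].value),
                amplitude=float(result.params["amplitude"].value),
                baseline=float(result.params["baseline"].value),
                role=role,
                rss=float(np.sum(result.residual**2)),
                n_points=len(t),
                meta={"init_k": k_start, "nfev": result.nfev},
            )
    raise FitError("first-order fit did not converge",
                   last_params={name: p.value for name, p in last.params.items()})


def kpi_from_oxygen(rates: TimeSeries) -> FirstOrderFit:
    """Photoinhibition rate constant from a normalized activity time course.

    ``rates`` should be relative PSII activity (first point 1, see
    :func:`photoacclim.assays.photoinhibition_relative`) measured with
    lincomycin present, so the decay is complete and the baseline is 0.
    """
    return fit_first_order(rates, fit_baseline=False, role="k_PI")


def simulate_damage_repair(model: DamageRepairModel, times) -> TimeSeries:
    """Closed-form activity time course of the damage–repair model."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    a_eq = model.A_eq
    v = a_eq + (model.A0 - a_eq) * np.exp(-(model.k_PI + model.k_rec) * t)
    return TimeSeries(t, v, kind="o2",
                      meta={"k_PI": model.k_PI, "k_rec": model.k_rec,
                            "A0": model.A0, "A_eq": a_eq})


def fit_damage_repair(series: TimeSeries, k_PI_fixed: float) -> DamageRepairModel:
    """Estimate (A0, k_rec) from an activity time course with k_PI known.

    The damaging rate constant is taken from the parallel +lincomycin
    experiment and held fixed; A0 and the repair rate constant k_rec are
    fitted by nonlinear least squares to the closed-form solution. The
    equilibrium activity follows from the model identity
    A_eq = A0 k_rec / (k_PI + k_rec).
    """
    if k_PI_fixed <= 0:
        raise ValueError("k_PI_fixed must be positive")
    t, v = series.time, series.values
    if len(t) < 4:
        raise FitError("need at least 4 points to fit the damage-repair model")

    def _model(t, A0, k_rec):
        a_eq = A0 * k_rec / (k_PI_fixed + k_rec)
        return a_eq + (A0 - a_eq) * np.exp(-(k_PI_fixed + k_rec) * t)

    a0_0 = float(v[0])
    a_eq0 = float(max(v[-1], 0.0))
    if a0_0 > a_eq0 > 0:
        k_rec0 = k_PI_fixed * a_eq0 / (a0_0 - a_eq0)
    else:
        k_rec0 = k_PI_fixed
    model = lmfit.Model(_model)
    params = model.make_params(A0=dict(value=a0_0, min=1e-12),
                               k_rec=dict(value=k_rec0, min=0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(v, params, t=t)
    if not result.success:
        raise FitError("damage-repair fit did not converge",
                       last_params={n: p.value for n, p in result.params.items()})
    return DamageRepairModel(k_PI=k_PI_fixed,
                             k_rec=float(result.params["k_rec"].value),
                             A0=float(result.params["A0"].value))
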