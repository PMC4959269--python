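"""Dose-response curves and Hill-function fitting.

Covers the steady-state stimulus-response of the transcription factors to
direct PPARgamma activation (cooperativity and activation thresholds of the
feedback loops) and the pulse amplitude x duration control of the fraction
of cells that lock into the differentiated state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ensemble import NoiseSpec, run_population
from .errors import FlatCurveError, InputDomainError
from .model import basal_fixed_point, derivatives, simulate
from .params import ModelParameters
from .population_stats import fraction_differentiated
from .protocols import (FeedbackVariant, constant_protocol,
                        rosi_pulse_protocol)

__all__ = [
    "HillFit",
    "fit_hill",
    "default_dose_grid",
    "steady_state_dose_response",
    "ensemble_dose_response_48h",
    "conversion_span",
    "pulse_matrix",
]


@dataclass(frozen=True)
class HillFit:
    floor: float
    ceiling: float
    ec50: float
    hill_n: float
    rss: float
    converged: bool

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.floor + (self.ceiling - self.floor) * d ** self.hill_n / (
            self.ec50 ** self.hill_n + d ** self.hill_n)


def _hill(d, floor, ceiling, log_ec50, n):
    ec50 = 10.0 ** log_ec50
    dn = d ** n
    return floor + (ceiling - floor) * dn / (ec50 ** n + dn)


def fit_hill(doses: Sequence[float], responses: Sequence[float]) -> HillFit:
    """Least-squares 4-parameter Hill fit r(d) = f + (c-f) d^n/(ec50^n+d^n).

    Requires at least 6 positive doses spanning two decades.  The fit is
    multi-started from Hill exponents {0.5, 1, 2, 4} and the best
    residual-sum-of-squares solution is returned.  Degenerate (flat) curves
    raise :class:`FlatCurveError`.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(d) != len(r):
        raise InputDomainError("doses and responses must have equal length")
    if len(d) < 6:
        raise InputDomainError("need at least 6 dose points")
    if np.any(d <= 0):
        raise InputDomainError("doses must be positive")
    if d.max() / d.min() < 100:
        raise InputDomainError("doses must span at least two decades")
    rng = r.max() - r.min()
    if rng < 0.05 * abs(r.max()):
        raise FlatCurveError("response dynamic range below 5% of maximum")

    lo, hi = math.log10(d.min()) - 2, math.log10(d.max()) + 2
    bounds = ([-np.inf, -np.inf, lo, 0.05], [np.inf, np.inf, hi, 12.0])
    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        p0 = [r.min(), r.max(), math.log10(np.median(d)), n0]
        try:
            popt, _ = curve_fit(_hill, d, r, p0=p0, bounds=bounds, maxfev=20000)
        except Exception:
            continue
        rss = float(np.sum((_hill(d, *popt) - r) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return HillFit(float(r.min()), float(r.max()), float(np.median(d)),
                       1.0, float("inf"), False)
    (floor, ceiling, log_ec50, n), rss = best
    if ceiling < floor:  # canonicalize as an increasing curve description
        floor, ceiling = ceiling, floor
    return HillFit(float(floor), float(ceiling), float(10 ** log_ec50),
                   float(n), rss, True)


def default_dose_grid(top: float = 16.0, n: int = 12) -> np.ndarray:
    """Two-fold serial dilutions from ``top`` downward (ascending order)."""
    return top / 2.0 ** np.arange(n - 1, -1, -1)


def steady_state_dose_response(params: ModelParameters,
                               variant: Optional[FeedbackVariant] = None,
                               channel: str = "rosi",
                               doses: Optional[Sequence[float]] = None,
                               readouts: Sequence[str] = ("cebpb", "pparg", "cebpa"),
                               t_settle: float = 400.0,
                               insulin_level: float = 1.0) -> Tuple[pd.DataFrame, Dict[str, HillFit]]:
    """Forward-branch steady-state response to a sustained stimulus.

    Each dose is applied as a constant level on ``channel`` (with the
    insulin channel held at ``insulin_level``; induction of PPARgamma
    requires basal insulin signalling) and the model is integrated from the
    unstimulated basal state for ``t_settle`` hours.  Because the start is
    always the basal state, the curve describes the forward (off-to-on)
    branch; in a hysteretic regime the backward branch differs.  A Hill fit
    is attached per readout.
    """
    variant = variant or FeedbackVariant()
    if t_settle < 240.0:
        raise InputDomainError("t_settle must be >= 240 h")
    doses = np.asarray(default_dose_grid() if doses is None else doses, float)
    init = basal_fixed_point(params, variant)
    rows = []
    for dose in doses:
        levels = {channel: float(dose), "insulin": insulin_level}
        prot = constant_protocol(t_settle, **levels)
        tr = simulate(prot, params, variant, initial=init,
                      dt_out=t_settle / 4, rtol=1e-8, atol=1e-10)
        end = tr.final_state()
        inputs = {c: prot.level(c, t_settle * 0.99) for c in ("gr", "camp", "insulin", "rosi")}
        resid = float(np.linalg.norm(derivatives(end, params, inputs, variant)))
        rows.append({"dose": float(dose), "settled": resid < 1e-6,
                     **{s: getattr(end, s) for s in ("cebpb", "pparg", "cebpa",
                                                     "pakt", "ir", "fat")}})
    curve = pd.DataFrame(rows)
    fits = {r: _try_fit(curve["dose"], curve[r]) for r in readouts}
    return curve, fits


def _try_fit(doses, responses) -> Optional[HillFit]:
    """Hill fit, or None when the curve is unfittable (too few doses, flat)."""
    try:
        return fit_hill(doses, responses)
    except (InputDomainError, FlatCurveError):
        return None


def ensemble_dose_response_48h(params: ModelParameters,
                               doses: Optional[Sequence[float]] = None,
                               n_cells: int = 1000,
                               noise: Optional[NoiseSpec] = None,
                               seed: int = 0,
                               readouts: Sequence[str] = ("cebpb", "pparg", "cebpa"),
                               measure_h: float = 48.0,
                               threshold: Optional[float] = None,
                               variant: Optional[FeedbackVariant] = None) -> Tuple[pd.DataFrame, Dict[str, HillFit]]:
    """Population-mean dose-response measured 48 h after sustained stimulus.

    Mirrors a plate experiment: every dose of the rosiglitazone channel is
    applied to an ensemble of cells with default extrinsic noise (insulin
    present), and each readout's population mean at 48 h is recorded.  The
    single-cell response is switch-like, so the smooth sigmoids seen at the
    population level arise from cell-to-cell threshold variability; Hill
    fits describe these population curves.  The returned table also carries
    the converted fraction per dose (cells above the low/high threshold).
    """
    noise = noise or NoiseSpec()
    doses = np.asarray(default_dose_grid() if doses is None else doses, float)
    if threshold is None:
        threshold = _default_threshold(params)
    rows = []
    # vehicle control first: conversion is reported as the excess over the
    # dose-0 well (same sampled cells, mirroring a paired plate design)
    for dose in np.concatenate([[0.0], doses]):
        prot = rosi_pulse_protocol(float(dose), measure_h, measure_h,
                                   insulin_level=1.0)
        df = run_population(n_cells, prot, params, noise, variant=variant,
                            sample_times=[measure_h], seed=seed)
        ok = df[~df["failed"].astype(bool)]
        row = {"dose": float(dose),
               "frac_high": float((ok["pparg"] > threshold).mean())}
        for r in ("cebpb", "pparg", "cebpa", "pakt", "ir", "fat"):
            row[r] = float(ok[r].mean())
        rows.append(row)
    curve = pd.DataFrame(rows)
    pos = curve[curve["dose"] > 0]
    fits = {r: fit_hill(pos["dose"], pos[r]) for r in readouts}
    return curve, fits


def conversion_span(curve: pd.DataFrame, low: float = 0.05,
                    high: float = 0.95) -> Optional[float]:
    """Fold-range of stimulus between essentially-none and essentially-all
    conversion.

    Conversion at each dose is the stimulus-induced excess fraction over the
    dose-0 vehicle control when the curve contains one (the raw fraction
    otherwise).  Returns the lowest dose converting at least ``high`` of the
    convertible cells over the highest dose converting at most ``low``
    (None when either end is missing).
    """
    pos = curve[curve["dose"] > 0]
    frac = pos["frac_high"].to_numpy(float)
    ctrl = curve.loc[curve["dose"] == 0, "frac_high"]
    if len(ctrl):
        f0 = float(ctrl.iloc[0])
        frac = (frac - f0) / max(1.0 - f0, 1e-12)
    doses = pos["dose"].to_numpy(float)
    lo = doses[frac <= low]
    hi = doses[frac >= high]
    if len(lo) == 0 or len(hi) == 0:
        return None
    return float(hi.min() / lo.max())


def pulse_matrix(amplitudes: Sequence[float], durations: Sequence[float],
                 base: ModelParameters, noise: Optional[NoiseSpec] = None,
                 n_cells: int = 400, total_h: Optional[float] = None,
                 seed: int = 0, threshold: Optional[float] = None,
                 variant: Optional[FeedbackVariant] = None) -> pd.DataFrame:
    """Differentiated fraction after a rosiglitazone pulse, per (amplitude, duration).

    Every condition reuses the same sampled cell population (paired design;
    condition-to-condition differences are not inflated by sampling noise).
    The washout after the longest pulse is at least 24 h.  Fractions use the
    bimodality threshold when the end-state distribution is bimodal, else
    the supplied fixed ``threshold``.
    """
    noise = noise or NoiseSpec()
    durations = sorted(float(x) for x in durations)
    if total_h is None:
        total_h = durations[-1] + 48.0
    if total_h < durations[-1] + 24.0:
        raise InputDomainError("need >= 24 h washout after the longest pulse")
    if threshold is None:
        threshold = _default_threshold(base)
    rows = []
    for amp in amplitudes:
        if amp < 0:
            raise InputDomainError("amplitude must be >= 0")
        for dur in durations:
            prot = rosi_pulse_protocol(amp, dur, total_h, insulin_level=1.0)
            df = run_population(n_cells, prot, base, noise, variant=variant,
                                sample_times=[total_h], seed=seed)
            frac = fraction_differentiated(df, "pparg", total_h,
                                           threshold_rule="auto",
                                           fixed_threshold=threshold)
            rows.append({"amplitude": float(amp), "duration_h": dur,
                         "fraction": frac["fraction"], "ci_low": frac["ci_low"],
                         "ci_high": frac["ci_high"], "n_failed": df.attrs["n_failed"]})
    return pd.DataFrame(rows)


def _default_threshold(base: ModelParameters) -> float:
    """Geometric midpoint between the basal and committed PPARgamma levels."""
    from .protocols import standard_dim_protocol
    tr = simulate(standard_dim_protocol(48, 168), base, dt_out=42.0,
                  rtol=1e-6, atol=1e-9)
    high = max(float(tr.final_state().pparg), 1.0)
    return math.sqrt(high)
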