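"""Population-level statistics on single-cell readout distributions.

The central tool is a bimodality classifier for one-dimensional intensity
distributions: a two-component Gaussian mixture on log10 intensities,
selected against a one-component fit by BIC, with a minimum subpopulation
fraction of 5% and a minimum mode separation of two standard deviations of
the wider component.  The equal-posterior crossing between the component means serves
as the low/high threshold for fraction-differentiated counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture

from .errors import InputDomainError, NumericalError
from .ensemble import NoiseSpec, run_population, sample_cell_params
from .model import ModelState, basal_fixed_point, simulate
from .params import ModelParameters
from .protocols import FeedbackVariant, StimulusProtocol, constant_protocol

__all__ = [
    "BimodalityResult",
    "classify_bimodality",
    "fraction_differentiated",
    "noise_window_scan",
    "preswitch_predictor_ranking",
    "graded_pakt_fat_relation",
]

#: minimum number of values the mixture classifier accepts
MIN_VALUES = 50
#: minimum mixture weight for a real subpopulation
WEIGHT_FLOOR = 0.05
#: minimum separation between component means, in pooled SDs
SEPARATION_SDS = 2.0


@dataclass(frozen=True)
class BimodalityResult:
    is_bimodal: bool
    threshold: Optional[float]  # a.u. (linear scale), None when unimodal
    frac_low: float
    frac_high: float
    mean_low_log10: float
    mean_high_log10: float
    sd_low_log10: float
    sd_high_log10: float
    delta_bic: float  # BIC(1 comp) - BIC(2 comp); positive favours 2


def classify_bimodality(values: Sequence[float], random_state: int = 0) -> BimodalityResult:
    """Classify a 1-D positive-valued distribution as uni- or bimodal.

    Fits one- and two-component Gaussian mixtures to log10 values.  The
    distribution is called bimodal when the two-component model wins on BIC,
    the component means are separated by at least two standard deviations of
    the wider component, and both subpopulations hold at least 5% of the
    values.  The reported threshold is the point between the two means where
    the posterior membership probabilities are equal.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_VALUES:
        raise InputDomainError(f"need >= {MIN_VALUES} finite values, got {len(x)}")
    if np.any(x <= 0):
        raise InputDomainError("values must be positive (log-scale classifier)")
    lx = np.log10(x).reshape(-1, 1)

    if np.ptp(lx) < 1e-12:  # degenerate: all identical
        m = float(lx[0, 0])
        return BimodalityResult(False, None, 1.0, 0.0, m, m, 0.0, 0.0, 0.0)

    g1 = GaussianMixture(1, random_state=random_state).fit(lx)
    g2 = GaussianMixture(2, n_init=5, random_state=random_state,
                         reg_covar=1e-6).fit(lx)
    delta_bic = float(g1.bic(lx) - g2.bic(lx))

    means = g2.means_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    weights = g2.weights_.ravel()
    order = np.argsort(means)
    (m_lo, m_hi), (s_lo, s_hi), (w_lo, w_hi) = means[order], sds[order], weights[order]
    # two real modes must be visible in the data density itself (a valley
    # between peaks); mixture-component geometry alone over-calls bimodality
    # when one component merely absorbs a tail or a bridging continuum
    separated = _n_density_modes(lx.ravel()) >= 2

    thr_log = _equal_posterior_point(m_lo, s_lo, w_lo, m_hi, s_hi, w_hi)
    frac_low = float(np.mean(lx.ravel() < thr_log))
    # the subpopulation floor is applied to the posterior-assigned fractions:
    # raw mixture weights overstate a minor mode when one component merely
    # absorbs the tail of the other
    is_bimodal = ((delta_bic > 0) and separated
                  and min(frac_low, 1.0 - frac_low) >= WEIGHT_FLOOR)

    if not is_bimodal:
        return BimodalityResult(False, None, 1.0, 0.0, float(m_lo), float(m_hi),
                                float(s_lo), float(s_hi), delta_bic)

    return BimodalityResult(True, float(10 ** thr_log), frac_low, 1.0 - frac_low,
                            float(m_lo), float(m_hi), float(s_lo), float(s_hi),
                            delta_bic)


def _n_density_modes(logs: np.ndarray, prominence_frac: float = 0.02) -> int:
    """Number of modes of a Gaussian-KDE density (Scott bandwidth).

    A mode counts only if its peak rises by at least ``prominence_frac`` of
    the maximum density above the surrounding valleys.
    """
    from scipy.signal import find_peaks
    kde = sps.gaussian_kde(logs)
    lo, hi = logs.min(), logs.max()
    pad = 0.05 * (hi - lo) + 1e-9
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    return int(len(peaks))


def _equal_posterior_point(m1, s1, w1, m2, s2, w2) -> float:
    """Crossing point of the two weighted component densities between the means."""
    grid = np.linspace(m1, m2, 2001)
    d = (w1 * sps.norm.pdf(grid, m1, max(s1, 1e-12))
         - w2 * sps.norm.pdf(grid, m2, max(s2, 1e-12)))
    sign = np.sign(d)
    crossings = np.where(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        return 0.5 * (m1 + m2)
    i = crossings[-1]
    # linear interpolation of the sign change
    x0, x1, y0, y1 = grid[i], grid[i + 1], d[i], d[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x0)


def _wilson_ci(k: int, n: int, z: float = 1.959964) -> Tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def fraction_differentiated(table: pd.DataFrame, readout: str = "pparg",
                            time: Optional[float] = None,
                            threshold_rule="auto",
                            fixed_threshold: Optional[float] = None) -> dict:
    """Fraction of cells above the low/high threshold at one sample time.

    ``threshold_rule`` is ``"auto"`` (threshold from the bimodality
    classifier, falling back to ``fixed_threshold`` when the distribution is
    unimodal) or a number used directly.  Returns the fraction with a 95%
    Wilson score interval and the threshold used.
    """
    if time is None:
        time = float(table["time_h"].max())
    sel = table[np.isclose(table["time_h"], time)]
    if len(sel) == 0:
        raise InputDomainError(f"time {time} h not present in table")
    vals = sel.loc[~sel.get("failed", False).astype(bool), readout].to_numpy(float)
    if isinstance(threshold_rule, (int, float)):
        thr = float(threshold_rule)
    elif threshold_rule == "auto":
        res = classify_bimodality(vals)
        if res.is_bimodal:
            thr = res.threshold
        elif fixed_threshold is not None:
            thr = float(fixed_threshold)
        else:
            raise InputDomainError(
                "distribution is unimodal and no fixed threshold was provided")
    else:
        raise InputDomainError(f"unknown threshold rule {threshold_rule!r}")
    k = int(np.sum(vals > thr))
    n = len(vals)
    lo, hi = _wilson_ci(k, n)
    return {"fraction": k / n, "ci_low": lo, "ci_high": hi,
            "threshold": thr, "n": n}


def _cell_is_bistable(cell_params: ModelParameters, variant: FeedbackVariant,
                      low_cut: float, relax_h: float = 400.0) -> bool:
    """Does this cell's own circuit admit two attractors under insulin alone?"""
    prot = constant_protocol(relax_h, insulin=1.0)
    push = ModelState(10.0, 40.0, 15.0, 6.0, 8.0, 0.0)
    try:
        lo = simulate(prot, cell_params, variant,
                      initial=basal_fixed_point(cell_params, variant),
                      dt_out=relax_h / 2, rtol=1e-6, atol=1e-9).final_state()
        hi = simulate(prot, cell_params, variant, initial=push,
                      dt_out=relax_h / 2, rtol=1e-6, atol=1e-9).final_state()
    except Exception:
        return False
    return (hi.pparg > 2.0 * lo.pparg) and (lo.pparg < low_cut)


def noise_window_scan(cv_grid: Sequence[float], protocol: StimulusProtocol,
                      base: ModelParameters, n_cells: int = 1000,
                      seed: int = 0, readout: str = "pparg",
                      noise_template: Optional[NoiseSpec] = None,
                      bist_majority: float = 0.5,
                      bist_subsample: int = 400) -> dict:
    """Scan parameter-noise magnitude for the bimodality 'sweet spot'.

    Each grid value is applied as a uniform scale of the default per-group
    CV ratios (the grid value is the C/EBPbeta/alpha group CV; the PPARgamma
    group is half of it).  For every CV the ensemble is run through the
    protocol (stimulation + washout) and two verdicts are recorded:

    * ``bimodal``  -- the end-state readout distribution is bimodal;
    * ``intact``   -- the majority of cells' individual circuits are still
      bistable (two attractors under insulin alone).  At large CV most
      cells' parameter draws push them outside the bistable region, which is
      what 'breaking the bistability' means here.

    Returns the smallest and largest CV where both hold, plus per-CV
    diagnostics.  The window is reported as empty when no CV qualifies.
    """
    cvs = list(cv_grid)
    if cvs != sorted(cvs):
        raise InputDomainError("cv_grid must be sorted ascending")
    template = noise_template or NoiseSpec()
    ref_cv = max(template.cv(g) for g in ("cebpb", "cebpa", "pparg"))
    det_high = _deterministic_committed_level(protocol, base, readout)
    low_cut = math.sqrt(det_high)  # geometric midpoint between 1 and high

    rows = []
    for cv in cvs:
        noise = template.scaled(cv / ref_cv) if cv > 0 else template.scaled(0.0)
        df = run_population(n_cells, protocol, base, noise,
                            sample_times=[protocol.duration_h], seed=seed)
        vals = df.loc[~df["failed"].astype(bool), readout].to_numpy(float)
        vals = vals[vals > 0]
        bim = classify_bimodality(vals) if len(vals) >= MIN_VALUES else None
        is_bim = bool(bim.is_bimodal) if bim is not None else False
        nsub = min(bist_subsample, n_cells)
        cells = sample_cell_params(base, noise, nsub, seed + 1)
        n_bist = sum(_cell_is_bistable(cp, FeedbackVariant(), low_cut)
                     for cp in cells)
        intact = (n_bist / nsub) >= bist_majority
        rows.append({"cv": cv, "is_bimodal": is_bim, "bistable_fraction": n_bist / nsub,
                     "intact": intact, "frac_high": float(np.mean(vals > low_cut))})

    diag = pd.DataFrame(rows)
    good = diag[diag["is_bimodal"] & diag["intact"]]
    if len(good) == 0:
        return {"cv_lo": None, "cv_hi": None, "diagnostics": diag, "contiguous": True}
    idx = good.index.to_numpy()
    contiguous = bool(np.all(np.diff(idx) == 1))
    return {"cv_lo": float(good["cv"].iloc[0]), "cv_hi": float(good["cv"].iloc[-1]),
            "diagnostics": diag, "contiguous": contiguous}


def _deterministic_committed_level(protocol, base, readout) -> float:
    tr = simulate(protocol, base, dt_out=protocol.duration_h / 4,
                  rtol=1e-6, atol=1e-9)
    return max(float(tr.final_state().pparg if readout == "pparg"
                     else getattr(tr.final_state(), readout)), 1.0)


def preswitch_predictor_ranking(table: pd.DataFrame, t_pre: float,
                                t_final: float,
                                factors: Sequence[str] = ("cebpb", "pparg", "cebpa"),
                                threshold: Optional[float] = None) -> dict:
    """How well does each factor's pre-switch level predict the final fate?

    Labels cells high/low at ``t_final`` (bimodality threshold on PPARgamma
    unless ``threshold`` is given) and scores each factor's level at
    ``t_pre`` as a predictor of the final label by ROC AUC.  Returns per-
    factor AUCs and the factors ranked best-first.
    """
    pre = table[np.isclose(table["time_h"], t_pre)].set_index("cell_id")
    fin = table[np.isclose(table["time_h"], t_final)].set_index("cell_id")
    if len(pre) == 0 or len(fin) == 0:
        raise InputDomainError("t_pre and t_final must both be sample times of the table")
    if threshold is None:
        res = classify_bimodality(fin["pparg"].to_numpy(float))
        if not res.is_bimodal:
            raise InputDomainError("final PPARgamma distribution is not bimodal; "
                                   "provide an explicit threshold")
        threshold = res.threshold
    labels = (fin["pparg"] > threshold).astype(int)
    if labels.nunique() < 2:
        raise InputDomainError("all cells share one final label; AUC undefined")
    common = pre.index.intersection(fin.index)
    aucs = {f: float(roc_auc_score(labels.loc[common], pre.loc[common, f]))
            for f in factors}
    ranking = sorted(aucs, key=aucs.get, reverse=True)
    return {"auc": aucs, "ranking": ranking, "threshold": float(threshold)}


def graded_pakt_fat_relation(table: pd.DataFrame, time: Optional[float] = None,
                             n_deciles: int = 10) -> dict:
    """Within differentiated cells, is fat graded in pAKT rather than PPARgamma?

    Requires the PPARgamma distribution at ``time`` to be bimodal; within
    the high-PPARgamma subpopulation computes Spearman rank correlations of
    fat with pAKT and with PPARgamma, and checks that fat conditioned on
    pAKT deciles stays unimodal (graded, not switch-like).
    """
    if time is None:
        time = float(table["time_h"].max())
    sel = table[np.isclose(table["time_h"], time)]
    sel = sel[~sel.get("failed", False).astype(bool)]
    res = classify_bimodality(sel["pparg"].to_numpy(float))
    if not res.is_bimodal:
        raise InputDomainError("PPARgamma distribution is not bimodal at this time")
    high = sel[sel["pparg"] > res.threshold]
    fat = high["fat"].to_numpy(float)
    if np.ptp(fat) < 1e-12:
        corr_pakt = corr_pparg = 0.0
    else:
        corr_pakt = float(sps.spearmanr(high["pakt"], high["fat"]).statistic)
        corr_pparg = float(sps.spearmanr(high["pparg"], high["fat"]).statistic)
    # graded check: fat within pAKT deciles should stay unimodal
    graded = True
    q = pd.qcut(high["pakt"], min(n_deciles, max(2, len(high) // MIN_VALUES)),
                duplicates="drop")
    for _, grp in high.groupby(q, observed=True):
        vals = grp["fat"].to_numpy(float)
        if len(vals) >= MIN_VALUES and np.all(vals > 0):
            if classify_bimodality(vals).is_bimodal:
                graded = False
    return {"corr_fat_pakt": corr_pakt, "corr_fat_pparg": corr_pparg,
            "graded": graded, "threshold": res.threshold,
            "n_high": int(len(high))}
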