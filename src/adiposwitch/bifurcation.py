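"""Steady-state structure: fixed points, nullclines, hysteresis, commitment.

The intact two-loop circuit is bistable under insulin alone: a low
(preadipocyte) and a high (adipocyte) stable state separated by a saddle.
Removing the PPARgamma->C/EBPbeta feedback (one-loop variant) leaves a
monostable system, which is the model's core explanation for why a single
feedback loop cannot hold the differentiated state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import approx_fprime, root

from .errors import InputDomainError, NumericalError
from .model import (SPECIES, ModelState, Trajectory, basal_fixed_point,
                    derivatives, simulate)
from .params import ModelParameters
from .protocols import FeedbackVariant, StimulusProtocol, constant_protocol

__all__ = [
    "FixedPoint",
    "HysteresisBranches",
    "find_fixed_points",
    "nullclines_one_loop",
    "stimulus_sweep_hysteresis",
    "irreversibility_test",
]


@dataclass(frozen=True)
class FixedPoint:
    state: ModelState
    stable: bool
    inputs: Dict[str, float]
    eigenvalues: Tuple[complex, ...]

    @property
    def pparg(self) -> float:
        return self.state.pparg


def _rhs_at(y, params, inputs, variant):
    return derivatives(np.maximum(y, 0.0), params, inputs, variant)


def find_fixed_points(params: ModelParameters,
                      inputs: Optional[Dict[str, float]] = None,
                      variant: Optional[FeedbackVariant] = None,
                      box: Tuple[float, float] = (1e-3, 60.0),
                      n_starts: int = 40,
                      seed: int = 0,
                      merge_tol: float = 1e-4) -> List[FixedPoint]:
    """Locate fixed points of the model at constant inputs.

    Multi-start Newton (scipy ``root``/hybr) from log-uniform random starts
    in ``box`` plus the basal state and a relaxed high state.  Roots closer
    than ``merge_tol`` (relative) are merged; stability is read off the real
    parts of the finite-difference Jacobian's eigenvalues.
    """
    inputs = dict(inputs or {})
    variant = variant or FeedbackVariant()
    lo, hi = box
    if not (0 <= lo < hi):
        raise InputDomainError("box must satisfy 0 <= lo < hi")
    rng = np.random.default_rng(seed)

    starts = [basal_fixed_point(params, variant).to_array()]
    # a relaxed push-up start helps find the committed state
    push = ModelState(10.0, 40.0, 15.0, 6.0, 8.0, 1.0)
    prot = constant_protocol(400.0, **{k: v for k, v in inputs.items() if v > 0})
    try:
        starts.append(simulate(prot, params, variant, initial=push,
                               dt_out=200.0, rtol=1e-6, atol=1e-9).y[-1])
    except NumericalError:
        pass
    for _ in range(n_starts):
        starts.append(np.exp(rng.uniform(math.log(max(lo, 1e-3)), math.log(hi), 6)))

    roots: List[np.ndarray] = []
    for y0 in starts:
        sol = root(lambda y: _rhs_at(y, params, inputs, variant), y0,
                   method="hybr", tol=1e-12)
        if not sol.success:
            continue
        y = np.maximum(sol.x, 0.0)
        if np.any(y > hi * 2):
            continue
        if float(np.linalg.norm(_rhs_at(y, params, inputs, variant))) > 1e-8:
            continue
        if not any(np.linalg.norm(y - r) / (np.linalg.norm(r) + 1e-12) < merge_tol
                   for r in roots):
            roots.append(y)

    if not roots:
        warnings.warn("no fixed points found in box")
        return []

    out = []
    for y in sorted(roots, key=lambda v: v[SPECIES.index("pparg")]):
        jac = np.array([approx_fprime(y, lambda v, i=i: _rhs_at(v, params, inputs, variant)[i],
                                      1e-7) for i in range(6)])
        eig = np.linalg.eigvals(jac)
        out.append(FixedPoint(ModelState.from_array(y), bool(np.all(eig.real < 0)),
                              inputs, tuple(eig)))
    return out


def nullclines_one_loop(params: ModelParameters,
                        cebpb_levels: Sequence[float],
                        cebpa_grid: Optional[np.ndarray] = None,
                        pakt_clamp: Optional[float] = None,
                        rosi: float = 0.0) -> dict:
    """Nullclines of the PPARgamma/C/EBPalpha subsystem in the (A, P) plane.

    C/EBPbeta is clamped at each requested constant level and pAKT at its
    insulin-on basal value (configurable); the remaining two equations give
    one PPARgamma nullcline per C/EBPbeta level (red curves of a steady-state
    plot) and a single C/EBPalpha nullcline (blue curve).  Both are explicit,
    so the curves are evaluated pointwise and intersections are bracketed on
    the grid.
    """
    p = params
    if any(b < 0 for b in cebpb_levels):
        raise InputDomainError("cebpb levels must be >= 0")
    if cebpa_grid is None:
        cebpa_grid = np.linspace(0.0, 15.0, 601)
    if pakt_clamp is None:
        # insulin-on, zero GR/cAMP resting pAKT with basal IR
        ir0 = basal_fixed_point(p).ir
        pakt_clamp = p.syn_pakt * (p.base_ir + ir0) / p.deg_pakt
    gate = pakt_clamp / (p.alpha3 + pakt_clamp)

    def pparg_null(a_vals, b):
        s = b + np.asarray(a_vals)
        fb = s ** 3 / (p.alpha2 ** 3 + s ** 3)
        return p.syn_pparg * (p.base_pparg + fb * gate) / p.deg_pparg

    def cebpa_null(pg_vals):
        act = np.asarray(pg_vals) * (1.0 + p.rosi_gain * rosi / (p.rosi_k + rosi))
        fb = act ** 3 / (p.alpha4 ** p.alpha4_exp + act ** 3)
        return p.syn_cebpa * (p.base_cebpa + fb) / p.deg_cebpa

    curves = {}
    intersections: Dict[float, List[Tuple[float, float]]] = {}
    for b in cebpb_levels:
        pg = pparg_null(cebpa_grid, b)
        curves[b] = pd.DataFrame({"cebpa": cebpa_grid, "pparg": pg})
        # intersections: solve A = cebpa_null(pparg_null(A, b))
        resid = cebpa_null(pg) - cebpa_grid
        sgn = np.sign(resid)
        hits = []
        for i in np.where(np.diff(sgn) != 0)[0]:
            x0, x1 = cebpa_grid[i], cebpa_grid[i + 1]
            r0, r1 = resid[i], resid[i + 1]
            a = x0 - r0 * (x1 - x0) / (r1 - r0)
            hits.append((float(a), float(pparg_null(a, b))))
        if not hits:
            warnings.warn(f"no nullcline intersection bracketed for cebpb={b}; "
                          "refine the grid")
        intersections[b] = hits

    pg_axis = np.linspace(0.0, float(np.nanmax([c["pparg"].max() for c in curves.values()])) * 1.1 + 1e-9, 601)
    cebpa_curve = pd.DataFrame({"pparg": pg_axis, "cebpa": cebpa_null(pg_axis)})
    return {"pparg_nullclines": curves, "cebpa_nullcline": cebpa_curve,
            "intersections": intersections, "pakt_clamp": float(pakt_clamp)}


@dataclass(frozen=True)
class HysteresisBranches:
    levels: np.ndarray
    forward: np.ndarray   # steady-state PPARgamma, low-to-high sweep
    backward: np.ndarray  # high-to-low sweep
    window: Optional[Tuple[float, float]]  # bistable input interval

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.levels, "forward": self.forward,
                             "backward": self.backward})


def stimulus_sweep_hysteresis(params: ModelParameters,
                              variant: Optional[FeedbackVariant] = None,
                              channel: str = "rosi",
                              levels: Optional[Sequence[float]] = None,
                              insulin_level: float = 1.0,
                              relax_h: float = 500.0,
                              readout: str = "pparg") -> HysteresisBranches:
    """Forward/backward quasi-static sweep of one input channel.

    Each level is held for ``relax_h`` hours starting from the previous
    level's end state (warm start); the forward sweep begins at the basal
    state, the backward sweep returns from the last forward state.  The
    bistable window is where the branches differ by more than 10% relative.
    """
    variant = variant or FeedbackVariant()
    if levels is None:
        levels = np.concatenate([[0.0], 2.0 ** np.arange(-8.0, 3.1, 1.0)])
    levels = np.asarray(sorted(levels), dtype=float)
    if len(levels) < 8:
        raise InputDomainError("need at least 8 sweep levels")

    idx = SPECIES.index(readout)

    def relax(level, init):
        kw = {channel: level, "insulin": insulin_level}
        prot = constant_protocol(relax_h, **{k: v for k, v in kw.items() if v > 0})
        return simulate(prot, params, variant, initial=init,
                        dt_out=relax_h / 2, rtol=1e-7, atol=1e-9).final_state()

    state = basal_fixed_point(params, variant)
    fwd = []
    for lv in levels:
        state = relax(lv, state)
        fwd.append(state.to_array()[idx])
    bwd = [0.0] * len(levels)
    for i in range(len(levels) - 1, -1, -1):
        state = relax(levels[i], state)
        bwd[i] = state.to_array()[idx]

    fwd, bwd = np.array(fwd), np.array(bwd)
    rel = np.abs(bwd - fwd) / np.maximum(np.abs(fwd), 1e-12)
    mask = rel > 0.10
    window = None
    if np.any(mask):
        i0, i1 = np.where(mask)[0][[0, -1]]
        window = (float(levels[i0]), float(levels[i1]))
    return HysteresisBranches(levels, fwd, bwd, window)


def irreversibility_test(params: ModelParameters,
                         variant: Optional[FeedbackVariant] = None,
                         protocol: Optional[StimulusProtocol] = None,
                         relax_h: float = 96.0,
                         insulin_level: float = 1.0) -> dict:
    """Does the circuit stay committed after stimulus withdrawal?

    Runs the protocol (which must contain a washout phase), relaxes a
    further ``relax_h`` hours under insulin alone, and compares the end
    PPARgamma level (log-distance) with the low and high insulin-on fixed
    points.  For a monostable circuit the end state is compared with the
    basal level only and ``committed`` is necessarily False.
    """
    from .protocols import standard_dim_protocol
    variant = variant or FeedbackVariant()
    protocol = protocol or standard_dim_protocol(48.0, 96.0)
    stim_end = max((seg[1] for ch in ("gr", "camp", "rosi")
                    for seg in protocol.channels.get(ch, [])), default=0.0)
    if stim_end >= protocol.duration_h:
        raise InputDomainError("protocol has no washout phase")

    traj = simulate(protocol, params, variant, dt_out=protocol.duration_h / 8)
    tail = constant_protocol(relax_h, insulin=insulin_level)
    end = simulate(tail, params, variant, initial=traj.final_state(),
                   dt_out=relax_h / 2).final_state()

    fps = find_fixed_points(params, {"insulin": insulin_level}, variant)
    stable = [fp for fp in fps if fp.stable]
    low = min(stable, key=lambda fp: fp.pparg) if stable else None
    high = max(stable, key=lambda fp: fp.pparg) if stable else None
    note = None
    if low is None or high is None or high.pparg < 2 * low.pparg:
        committed = False
        note = "system is monostable at zero stimulus; commitment impossible"
    else:
        d_low = abs(math.log(end.pparg / max(low.pparg, 1e-12)))
        d_high = abs(math.log(end.pparg / high.pparg))
        committed = d_high < d_low
    return {"committed": committed, "end_state": end,
            "fixed_points": fps, "note": note}
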