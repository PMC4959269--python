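"""Core six-ODE model of the preadipocyte-to-adipocyte switch.

State variables (relative concentrations, a.u.):

``cebpb``  C/EBPbeta, the stimulus-proximal transcription factor
``pparg``  PPARgamma, the master regulator at the hub of all feedback loops
``cebpa``  C/EBPalpha, partner of PPARgamma in the first feedback loop
``pakt``   phospho-AKT, readout of insulin-receptor pathway activity
``ir``     insulin receptor
``fat``    accumulated lipid (BODIPY-equivalent)

The circuit: glucocorticoid x cAMP drives C/EBPbeta; C/EBPbeta + C/EBPalpha
cooperatively (Hill 3) drive PPARgamma, gated by pAKT; PPARgamma activity
feeds back onto C/EBPalpha (Hill 3, loop 1) and onto C/EBPbeta (Hill 2,
loop 2, higher threshold); C/EBPalpha drives insulin-receptor expression
(loop 3), which raises pAKT and hence PPARgamma; pAKT and PPARgamma activity
jointly drive graded fat accumulation.  cAMP x GR suppresses pAKT synthesis.
Rosiglitazone multiplies PPARgamma activity without adding protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InputDomainError, NumericalError
from .params import ModelParameters
from .protocols import FeedbackVariant, StimulusProtocol

__all__ = [
    "SPECIES",
    "ModelState",
    "Trajectory",
    "pparg_activity",
    "derivatives",
    "simulate",
    "basal_fixed_point",
]

SPECIES = ("cebpb", "pparg", "cebpa", "pakt", "ir", "fat")

#: default integration tolerances (stiff-capable adaptive solver)
RTOL = 1e-8
ATOL = 1e-10
#: tiny negative overshoots up to this magnitude are clipped to zero
CLIP = 1e-8


@dataclass(frozen=True)
class ModelState:
    cebpb: float
    pparg: float
    cebpa: float
    pakt: float = 0.0
    ir: float = 0.0
    fat: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InputDomainError(f"state component {name} must be finite and >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ModelState":
        return cls(*(float(v) for v in arr))


def pparg_activity(pparg: float, rosi_level: float, params: ModelParameters) -> float:
    """Effective PPARgamma activity under a thiazolidinedione dose.

    Ligands boost the activity of existing PPARgamma protein saturably:
    ``activity = pparg * (1 + rosi_gain * rosi / (rosi_k + rosi))``.
    They never add protein, so activity is zero when pparg is zero and equals
    pparg at zero dose.  Accepts a bare pparg value or a :class:`ModelState`.
    """
    if isinstance(pparg, ModelState):
        pparg = pparg.pparg
    if rosi_level < 0:
        raise InputDomainError(f"rosi_level must be >= 0, got {rosi_level}")
    return pparg * (1.0 + params.rosi_gain * rosi_level / (params.rosi_k + rosi_level))


def _rhs(y, p: ModelParameters, gr: float, camp: float, u_ins: float, rosi: float,
         loop2: float, loop3: float, kd_b: float, kd_p: float, kd_a: float,
         kd_i: float, a4e: float):
    """Raw derivative computation on a 6-vector; scalar math for speed."""
    b, pg, a, k, ir, fat = y
    act = pg * (1.0 + p.rosi_gain * rosi / (p.rosi_k + rosi))

    act2 = act * act
    db = p.syn_cebpb * kd_b * (p.base_cebpb + gr * camp
                               + loop2 * act2 / (p.alpha1 * p.alpha1 + act2)) \
        - p.deg_cebpb * b

    s = b + a
    s3 = s * s * s
    a2c = p.alpha2 ** 3
    dpg = p.syn_pparg * kd_p * (p.base_pparg
                                + (s3 / (a2c + s3)) * (k / (p.alpha3 + k))) \
        - p.deg_pparg * pg

    act3 = act2 * act
    da = p.syn_cebpa * kd_a * (p.base_cebpa + act3 / (p.alpha4 ** a4e + act3)) \
        - p.deg_cebpa * a

    dk = p.syn_pakt * u_ins * ((p.base_ir + ir) * p.alpha5 / (p.alpha5 + camp * gr)) \
        - p.deg_pakt * k

    di = p.syn_ir * kd_i * (p.base_ir + loop3 * a / (p.alpha6 + a)) - p.deg_ir * ir

    df = p.syn_fat * (k / (p.alpha7 + k)) * (act / (p.alpha8 + act)) - p.deg_fat * fat
    return (db, dpg, da, dk, di, df)


def _variant_terms(variant: FeedbackVariant):
    return (1.0 if variant.loop2_on else 0.0,
            1.0 if variant.loop3_on else 0.0,
            variant.remaining("cebpb"),
            variant.remaining("pparg"),
            variant.remaining("cebpa"),
            variant.remaining("ir"))


def derivatives(state, params: ModelParameters, inputs_at_t: Mapping[str, float],
                variant: Optional[FeedbackVariant] = None) -> np.ndarray:
    """Time derivatives (a.u./h) of all six species at one instant.

    ``inputs_at_t`` supplies the channel levels ``gr``, ``camp``, ``insulin``
    and ``rosi`` (missing channels default to 0).  The GR level is scaled by
    any ``gr-pathway`` knockdown in the variant.
    """
    variant = variant or FeedbackVariant()
    if isinstance(state, ModelState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (6,):
            raise InputDomainError(f"state must have 6 components, got shape {y.shape}")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise InputDomainError("state components must be finite and >= 0")
    levels = {c: float(inputs_at_t.get(c, 0.0)) for c in ("gr", "camp", "insulin", "rosi")}
    for c, v in levels.items():
        if v < 0:
            raise InputDomainError(f"input {c} must be >= 0, got {v}")
    loop2, loop3, kd_b, kd_p, kd_a, kd_i = _variant_terms(variant)
    gr = levels["gr"] * variant.remaining("gr-pathway")
    out = _rhs(y, params, gr, levels["camp"], levels["insulin"], levels["rosi"],
               loop2, loop3, kd_b, kd_p, kd_a, kd_i, params.alpha4_exp)
    return np.array(out, dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Time grid (h) and state samples of one simulation."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 6), columns in SPECIES order
    protocol: StimulusProtocol
    variant: FeedbackVariant

    def __getitem__(self, species: str) -> np.ndarray:
        return self.y[:, SPECIES.index(species)]

    def at(self, time_h: float) -> ModelState:
        i = int(np.argmin(np.abs(self.t - time_h)))
        if abs(self.t[i] - time_h) > 1e-6:
            raise InputDomainError(f"time {time_h} h not on the trajectory grid")
        return ModelState.from_array(self.y[i])

    def final_state(self) -> ModelState:
        return ModelState.from_array(self.y[-1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(SPECIES))
        df.insert(0, "time_h", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _segment_inputs(protocol: StimulusProtocol, variant: FeedbackVariant, t: float):
    lv = protocol.levels_at(t)
    return (lv["gr"] * variant.remaining("gr-pathway"), lv["camp"],
            lv["insulin"], lv["rosi"])


def simulate(protocol: StimulusProtocol, params: ModelParameters,
             variant: Optional[FeedbackVariant] = None,
             initial: Optional[ModelState] = None,
             dt_out: float = 1.0,
             rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the model through a stimulus protocol.

    The integrator (LSODA, stiff-capable, adaptive) is restarted at every
    protocol breakpoint so the piecewise-constant input discontinuities are
    handled exactly.  Output is sampled on a uniform ``dt_out`` grid with all
    breakpoints included.
    """
    variant = variant or FeedbackVariant()
    if initial is None:
        initial = basal_fixed_point(params, variant)
    y0 = initial.to_array()

    loop2, loop3, kd_b, kd_p, kd_a, kd_i = _variant_terms(variant)
    a4e = params.alpha4_exp

    total = float(protocol.duration_h)
    grid = np.arange(0.0, total + dt_out * 0.5, dt_out)
    if grid[-1] < total - 1e-9:
        grid = np.append(grid, total)
    breaks = protocol.breakpoints()

    ts: List[float] = []
    ys: List[np.ndarray] = []
    y = y0.copy()
    for a, b in zip(breaks, breaks[1:]):
        gr, camp, u_ins, rosi = _segment_inputs(protocol, variant, a)

        def f(t, yy):
            return _rhs(yy, params, gr, camp, u_ins, rosi,
                        loop2, loop3, kd_b, kd_p, kd_a, kd_i, a4e)

        t_eval = grid[(grid >= a - 1e-12) & (grid <= b + 1e-12)]
        if len(t_eval) == 0 or t_eval[0] > a + 1e-12:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b - 1e-12:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(f, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalError(f"integration failed on [{a}, {b}] h: {sol.message}",
                                 diagnostics={"t": a, "y": y.tolist()})
        seg_t, seg_y = sol.t, sol.y.T
        if ts and abs(seg_t[0] - ts[-1]) < 1e-12:
            seg_t, seg_y = seg_t[1:], seg_y[1:]
        ts.extend(seg_t.tolist())
        ys.extend(seg_y)
        y = sol.y[:, -1].copy()

    out = np.array(ys)
    neg = out < 0
    if np.any(out < -CLIP):
        worst = float(out.min())
        raise NumericalError(f"negative state overshoot {worst} exceeds clip tolerance",
                             diagnostics={"min": worst})
    out[neg] = 0.0
    return Trajectory(np.array(ts), out, protocol, variant)


def basal_fixed_point(params: ModelParameters,
                      variant: Optional[FeedbackVariant] = None) -> ModelState:
    """Unstimulated steady state (all input channels zero).

    With zero insulin, pAKT decays to zero, which removes the feedback input
    to PPARgamma; the remaining species then decouple sequentially, so the
    fixed point has a closed form.  It is the unique (hence lowest) fixed
    point at zero inputs and serves as the day-0 initial condition.
    """
    variant = variant or FeedbackVariant()
    p = params
    loop2, loop3, kd_b, kd_p, kd_a, kd_i = _variant_terms(variant)
    pparg = p.syn_pparg * kd_p * p.base_pparg / p.deg_pparg
    a4e = p.alpha4_exp
    cebpa = p.syn_cebpa * kd_a * (p.base_cebpa
                                  + pparg ** 3 / (p.alpha4 ** a4e + pparg ** 3)) / p.deg_cebpa
    cebpb = p.syn_cebpb * kd_b * (p.base_cebpb
                                  + loop2 * pparg ** 2 / (p.alpha1 ** 2 + pparg ** 2)) / p.deg_cebpb
    ir = p.syn_ir * kd_i * (p.base_ir + loop3 * cebpa / (p.alpha6 + cebpa)) / p.deg_ir
    state = ModelState(cebpb=cebpb, pparg=pparg, cebpa=cebpa, pakt=0.0, ir=ir, fat=0.0)
    resid = derivatives(state, params, {}, variant)
    if float(np.linalg.norm(resid)) > 1e-8:
        raise NumericalError("basal fixed point residual too large",
                             diagnostics={"residual": resid.tolist()})
    return state
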