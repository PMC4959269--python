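"""Stimulus protocols and feedback-circuit variants.

A :class:`StimulusProtocol` is a piecewise-constant time course for the four
input channels of the model:

* ``gr``      -- glucocorticoid receptor activation (dexamethasone),
* ``camp``    -- cAMP elevation (IBMX),
* ``insulin`` -- external insulin availability gating pAKT synthesis,
* ``rosi``    -- thiazolidinedione dose, in units of its half-saturation.

A :class:`FeedbackVariant` switches individual feedback loops of the circuit
on or off and applies siRNA-style knockdowns as fractional reductions of the
target's synthesis rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

from .errors import InputDomainError

__all__ = [
    "CHANNELS",
    "Segment",
    "StimulusProtocol",
    "FeedbackVariant",
    "PulseSpec",
    "standard_dim_protocol",
    "rosi_pulse_protocol",
    "constant_protocol",
    "apply_knockdown",
]

CHANNELS = ("gr", "camp", "insulin", "rosi")

#: species whose synthesis rate can be knocked down; "gr-pathway" instead
#: scales the GR input channel.
KNOCKDOWN_TARGETS = ("cebpb", "pparg", "cebpa", "ir", "gr-pathway")

Segment = Tuple[float, float, float]  # (start_h, end_h, level)


def _validate_segments(name: str, segments: Sequence[Segment]) -> List[Segment]:
    segs = sorted((float(a), float(b), float(v)) for a, b, v in segments)
    for a, b, v in segs:
        if b < a:
            raise InputDomainError(f"{name}: segment end {b} before start {a}")
        if v < 0:
            raise InputDomainError(f"{name}: negative level {v}")
    for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
        if a1 < b0:
            raise InputDomainError(f"{name}: overlapping segments at t={a1}")
    return segs


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant input time courses; level 0 where no segment."""

    duration_h: float
    channels: Dict[str, List[Segment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise InputDomainError("protocol duration must be > 0")
        clean = {}
        for name, segs in self.channels.items():
            if name not in CHANNELS:
                raise InputDomainError(f"unknown channel {name!r}")
            clean[name] = _validate_segments(name, segs)
        object.__setattr__(self, "channels", clean)

    def level(self, channel: str, t: float) -> float:
        """Channel level at time ``t`` (segments are [start, end) intervals)."""
        for a, b, v in self.channels.get(channel, ()):
            if a <= t < b:
                return v
        return 0.0

    def levels_at(self, t: float) -> Dict[str, float]:
        return {c: self.level(c, t) for c in CHANNELS}

    def breakpoints(self) -> List[float]:
        """Sorted unique segment boundaries within [0, duration]."""
        pts = {0.0, float(self.duration_h)}
        for segs in self.channels.values():
            for a, b, _ in segs:
                if 0.0 < a < self.duration_h:
                    pts.add(a)
                if 0.0 < b < self.duration_h:
                    pts.add(b)
        return sorted(pts)

    def extended(self, extra_h: float) -> "StimulusProtocol":
        """Same stimuli, with the total duration lengthened by ``extra_h``."""
        return StimulusProtocol(self.duration_h + extra_h,
                                {c: list(s) for c, s in self.channels.items()})


@dataclass(frozen=True)
class FeedbackVariant:
    """Circuit topology switches and knockdown state.

    ``loop2_on`` gates the PPARgamma->C/EBPbeta feedback term, ``loop3_on``
    the C/EBPalpha->insulin-receptor term.  ``knockdown`` maps a species name
    to the *remaining* synthesis fraction in [0, 1].
    """

    loop2_on: bool = True
    loop3_on: bool = True
    knockdown: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frac in self.knockdown.items():
            if name not in KNOCKDOWN_TARGETS:
                raise InputDomainError(f"unknown knockdown target {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise InputDomainError(f"knockdown fraction for {name} not in [0,1]: {frac}")

    def remaining(self, species: str) -> float:
        return self.knockdown.get(species, 1.0)


@dataclass(frozen=True)
class PulseSpec:
    """A single rectangular stimulus pulse on one channel."""

    channel: str
    amplitude: float
    start_h: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InputDomainError(f"unknown channel {self.channel!r}")
        if self.amplitude < 0 or self.duration_h < 0:
            raise InputDomainError("pulse amplitude and duration must be >= 0")


def standard_dim_protocol(stim_h: float = 48.0, total_h: float = 168.0,
                          insulin_after: bool = True) -> StimulusProtocol:
    """The standard differentiation-induction regimen.

    Glucocorticoid and cAMP channels at level 1 for the first ``stim_h``
    hours, then withdrawn; insulin at level 1 throughout when
    ``insulin_after`` is true (both during and after induction), otherwise
    the insulin channel is identically zero (no-insulin control).
    """
    if not 0 <= stim_h <= total_h:
        raise InputDomainError(f"stim_h={stim_h} must lie in [0, total_h={total_h}]")
    channels: Dict[str, List[Segment]] = {}
    if stim_h > 0:
        channels["gr"] = [(0.0, stim_h, 1.0)]
        channels["camp"] = [(0.0, stim_h, 1.0)]
    if insulin_after:
        channels["insulin"] = [(0.0, total_h, 1.0)]
    return StimulusProtocol(total_h, channels)


def rosi_pulse_protocol(amplitude: float, duration_h: float, total_h: float,
                        insulin_level: float = 0.0) -> StimulusProtocol:
    """A rosiglitazone pulse from t=0 followed by washout.

    GR and cAMP stay at zero.  ``insulin_level`` sets a constant insulin
    channel for the whole protocol; the default 0 gives a pure-rosiglitazone
    protocol, while population conversion experiments run it at 1 because
    PPARgamma induction requires basal insulin/pAKT signalling.
    """
    if amplitude < 0:
        raise InputDomainError("pulse amplitude must be >= 0")
    if duration_h > total_h:
        raise InputDomainError("pulse duration exceeds protocol duration")
    channels: Dict[str, List[Segment]] = {}
    if amplitude > 0 and duration_h > 0:
        channels["rosi"] = [(0.0, duration_h, amplitude)]
    if insulin_level > 0:
        channels["insulin"] = [(0.0, total_h, insulin_level)]
    return StimulusProtocol(total_h, channels)


def constant_protocol(total_h: float, **levels: float) -> StimulusProtocol:
    """Constant channel levels for the whole duration (keyword = channel)."""
    channels = {c: [(0.0, total_h, v)] for c, v in levels.items() if v > 0}
    return StimulusProtocol(total_h, channels)


def apply_knockdown(variant: FeedbackVariant, target: str,
                    efficiency: float) -> FeedbackVariant:
    """Return a variant with an siRNA knockdown of ``target`` applied.

    ``efficiency`` is the fraction of synthesis removed; the remaining
    fraction 1-efficiency multiplies the target's synthesis rate (including
    its basal term).  Target ``"gr-pathway"`` instead scales the GR input
    channel, modelling glucocorticoid-receptor knockdown.
    """
    if target not in KNOCKDOWN_TARGETS:
        raise InputDomainError(f"unknown knockdown target {target!r}")
    if not 0.0 <= efficiency <= 1.0:
        raise InputDomainError(f"efficiency must be in [0,1], got {efficiency}")
    kd = dict(variant.knockdown)
    kd[target] = kd.get(target, 1.0) * (1.0 - efficiency)
    return replace(variant, knockdown=kd)
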