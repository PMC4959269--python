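"""Model parameters: rate constants of the six-species adipogenesis switch.

The model tracks relative concentrations of C/EBPbeta, PPARgamma, C/EBPalpha,
phospho-AKT, the insulin receptor and accumulated fat.  Each protein species
has a synthesis scale (``syn_*``, a.u./h), a first-order degradation rate
(``deg_*``, 1/h) and, for the transcription factors and the insulin receptor,
a dimensionless basal-expression term (``base_*``).  The ``alpha*`` constants
are half-saturation points of the Hill terms coupling the species.

Units convention: concentrations are normalised so that every transcription
factor sits at 1.0 in the unstimulated (zero-input) steady state of the
reference parameter set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .errors import InputDomainError

__all__ = [
    "ModelParameters",
    "load_params",
    "save_params",
    "reference_params",
    "params_hash",
]

_SYN_FIELDS = ("syn_cebpb", "syn_pparg", "syn_cebpa", "syn_pakt", "syn_ir", "syn_fat")
_DEG_FIELDS = ("deg_cebpb", "deg_pparg", "deg_cebpa", "deg_pakt", "deg_ir", "deg_fat")
_BASE_FIELDS = ("base_cebpb", "base_pparg", "base_cebpa", "base_ir")
_ALPHA_FIELDS = tuple(f"alpha{i}" for i in range(1, 9))


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the six-ODE model.

    ``rosi_gain`` and ``rosi_k`` couple the rosiglitazone input channel to
    PPARgamma activity (saturable fold-boost); ``alpha4_exp`` selects the
    Hill exponent used in the C/EBPalpha activation denominator (3 for the
    dimensionally consistent form, 2 for the alternative with mismatched
    exponents in numerator and denominator).
    """

    syn_cebpb: float
    syn_pparg: float
    syn_cebpa: float
    syn_pakt: float
    syn_ir: float
    syn_fat: float
    deg_cebpb: float
    deg_pparg: float
    deg_cebpa: float
    deg_pakt: float
    deg_ir: float
    deg_fat: float
    base_cebpb: float
    base_pparg: float
    base_cebpa: float
    base_ir: float
    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    alpha5: float
    alpha6: float
    alpha7: float
    alpha8: float
    rosi_gain: float = 0.0
    rosi_k: float = 1.0
    alpha4_exp: float = 3.0

    def __post_init__(self) -> None:
        for name in _SYN_FIELDS + _BASE_FIELDS + ("rosi_gain",):
            if getattr(self, name) < 0:
                raise InputDomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in _DEG_FIELDS:
            if getattr(self, name) <= 0:
                raise InputDomainError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in _ALPHA_FIELDS + ("rosi_k",):
            if getattr(self, name) <= 0:
                raise InputDomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.alpha4_exp not in (2.0, 3.0):
            raise InputDomainError("alpha4_exp must be 2 or 3")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def scaled(self, factors: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with each named field multiplied by its factor."""
        changes = {k: getattr(self, k) * v for k, v in factors.items()}
        return self.replace(**changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_params(source) -> ModelParameters:
    """Read a parameter set from a JSON file path, file object, or dict.

    Unknown keys are rejected so that typos in config files fail loudly.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    elif hasattr(source, "read"):
        data = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise InputDomainError(f"unknown parameter keys: {sorted(unknown)}")
    missing = {f.name for f in dataclasses.fields(ModelParameters) if f.default is dataclasses.MISSING} - set(data)
    if missing:
        raise InputDomainError(f"missing parameter keys: {sorted(missing)}")
    return ModelParameters(**{k: float(v) for k, v in data.items()})


def save_params(params: ModelParameters, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def reference_params() -> ModelParameters:
    """The calibrated reference parameter set shipped with the package.

    Produced by :func:`adiposwitch.calibration.calibrate_reference_params`
    against the model's documented behavioural targets (bistability of the
    intact circuit, monostability of the one-loop variant, dose-response
    cooperativity and thresholds, commitment timing).
    """
    text = resources.files("adiposwitch.data").joinpath("reference_params.json").read_text()
    return load_params(json.loads(text))


def params_hash(params: ModelParameters) -> str:
    """Short stable hash identifying a parameter set in reports."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
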