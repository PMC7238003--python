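"""Parameter containers, physiological defaults and validation.

All quantities use one internal unit system: flows and clearances in L/h,
volumes in L, amounts in mg and concentrations in mg/L (any self-consistent
mass unit works the same way because the model is linear; the morphine-like
and inhibitor fixtures use umol so that cellular concentrations are in uM and
can be compared with an inhibition constant quoted in uM).

The intestine-liver unit is perfused by portal venous blood flow ``q_pv``
(approximately 75% of total liver blood flow ``q_h``) and hepatic arterial
flow ``q_ha`` (the remaining 25%).  The flow-model variants differ only in
``f_q``, the fraction of the portal-destined intestinal flow that perfuses
the metabolically active enterocyte region:

* ``TM``   (traditional model)        f_q = 1
* ``QGUT`` (Q_Gut model)              f_q = 0.484
* ``SFM``  (segregated flow model)    f_q < 0.2 (default 0.1)
* ``SSFM`` (segmental SFM)            f_q as SFM, >= 2 serial segments
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Variant",
    "Physiology",
    "FlowModelSpec",
    "DrugParams",
    "DoseEvent",
    "ParameterBundle",
    "validate",
    "default_physiology",
    "load_config",
]

#: f_q below this value is considered consistent with the segregated flow model.
SFM_FQ_RANGE = (0.0, 0.2)

#: Default enterocyte-flow fractions per variant.
DEFAULT_FQ = {"TM": 1.0, "QGUT": 0.484, "SFM": 0.1, "SSFM": 0.1}


class Variant(str, enum.Enum):
    """Intestinal flow-model variant."""

    TM = "TM"
    SFM = "SFM"
    QGUT = "QGUT"
    SSFM = "SSFM"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True, frozen=False)


def _require_positive(obj, fields):
    for name in fields:
        value = getattr(obj, name)
        if value is None:
            continue
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


def _require_nonnegative(obj, fields):
    for name in fields:
        value = getattr(obj, name)
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


class Physiology(_Strict):
    """Blood flows and compartment volumes of the intestine-liver unit.

    ``q_h`` is derived as ``q_pv + q_ha`` and must not be supplied
    inconsistently.  ``q_sma`` (superior mesenteric arterial flow) defaults to
    ``q_pv``; when smaller, the difference ``q_pv - q_sma`` joins the portal
    vein downstream of the intestine without intestinal exposure.
    """

    q_pv: float = 0.75
    q_ha: float = 0.25
    q_sma: Optional[float] = None
    v_b: float = 0.20
    v_lumen: float = 0.005
    v_eb: float = 0.0008
    v_ec: float = 0.008
    v_ser: float = 0.008
    v_lb: float = 0.004
    v_lc: float = 0.02

    @model_validator(mode="after")
    def _validate(self) -> "Physiology":
        _require_positive(
            self,
            ["q_pv", "v_b", "v_lumen", "v_eb", "v_ec", "v_ser", "v_lb", "v_lc"],
        )
        # q_ha = 0 (no hepatic arterial flow) is a meaningful limiting case:
        # it makes hepatic metabolite formation route-identical under the TM
        if self.q_ha < 0:
            raise ValueError(f"q_ha must be non-negative, got {self.q_ha}")
        if self.q_sma is None:
            object.__setattr__(self, "q_sma", self.q_pv)
        _require_positive(self, ["q_sma"])
        if self.q_sma > self.q_pv + 1e-12 * self.q_pv:
            raise ValueError(
                f"q_sma ({self.q_sma}) cannot exceed q_pv ({self.q_pv}): all "
                "superior mesenteric flow drains into the portal vein"
            )
        return self

    @property
    def q_h(self) -> float:
        """Total liver blood flow, ``q_pv + q_ha`` by mass balance."""
        return self.q_pv + self.q_ha


def default_physiology(q_h: float, **volumes) -> Physiology:
    """Physiology with the canonical 75/25 portal-venous / hepatic-arterial split.

    Parameters
    ----------
    q_h : total liver blood flow (L/h); must be > 0.
    **volumes : optional volume overrides forwarded to :class:`Physiology`.
    """
    if not q_h > 0:
        raise ValueError(f"q_h must be strictly positive, got {q_h}")
    return Physiology(q_pv=0.75 * q_h, q_ha=0.25 * q_h, **volumes)


class FlowModelSpec(_Strict):
    """Model variant plus the enterocyte-flow split fraction ``f_q``."""

    variant: Variant = Variant.SFM
    f_q: Optional[float] = None
    n_segments: int = 3

    @model_validator(mode="after")
    def _validate(self) -> "FlowModelSpec":
        if self.f_q is None:
            object.__setattr__(self, "f_q", DEFAULT_FQ[self.variant.value])
        if not (0.0 < self.f_q <= 1.0):
            raise ValueError(f"f_q out of (0,1]: got {self.f_q}")
        if self.variant is Variant.TM and abs(self.f_q - 1.0) > 0:
            raise ValueError("variant TM requires f_q = 1 (the undivided intestine)")
        if self.variant is Variant.SSFM and self.n_segments < 2:
            raise ValueError(f"SSFM requires n_segments >= 2, got {self.n_segments}")
        return self

    @property
    def sfm_consistent(self) -> bool:
        """True when f_q lies in the segregated-flow range (< 0.2)."""
        return SFM_FQ_RANGE[0] < self.f_q < SFM_FQ_RANGE[1]


class DrugParams(_Strict):
    """Absorption, binding and transport/intrinsic clearances of one drug.

    Intrinsic clearances act on the unbound tissue concentration
    (``fu_i``/``fu_h``-scaled); the basolateral influx clearances ``cl_d1_*``
    act on the unbound blood concentration (``fu_b``-scaled).  ``cl_int_h``
    is derived as ``cl_int_met_h + cl_int_sec_h``.
    """

    f_a: float = 1.0
    k_a: float = 1.0
    fu_b: float = 1.0
    fu_i: float = 1.0
    fu_h: float = 1.0
    cl_d1_i: float = 0.0
    cl_d2_i: float = 0.0
    cl_int_met1_i: float = 0.0
    cl_int_met2_i: float = 0.0
    cl_int_sec_i: float = 0.0
    cl_d1_h: float = 0.0
    cl_d2_h: float = 0.0
    cl_int_met_h: float = 0.0
    cl_int_sec_h: float = 0.0
    cl_r: float = 0.0
    #: fraction of hepatically formed metabolite excreted into bile (rest urine)
    p_bile: float = 1.0
    #: route intestinal pathway-2 product into the urinary M2 pool
    merge_met2: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "DrugParams":
        for name in ("f_a", "fu_b", "fu_i", "fu_h"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} out of (0,1]: got {value}")
        if not (0.0 <= self.p_bile <= 1.0):
            raise ValueError(f"p_bile out of [0,1]: got {self.p_bile}")
        _require_positive(self, ["k_a"])
        _require_nonnegative(
            self,
            [
                "cl_d1_i", "cl_d2_i", "cl_int_met1_i", "cl_int_met2_i",
                "cl_int_sec_i", "cl_d1_h", "cl_d2_h", "cl_int_met_h",
                "cl_int_sec_h", "cl_r",
            ],
        )
        return self

    @property
    def cl_int_h(self) -> float:
        """Total hepatic intrinsic clearance (metabolic + biliary secretory)."""
        return self.cl_int_met_h + self.cl_int_sec_h

    @property
    def luminal_loss(self) -> float:
        """Net intestinal intrinsic loss L = met1 + met2 + sec*(1 - f_a).

        Secreted drug re-enters the lumen and is reabsorbed with probability
        ``f_a``, so only the fraction ``1 - f_a`` of apical secretion is a net
        loss at steady state.
        """
        return (
            self.cl_int_met1_i
            + self.cl_int_met2_i
            + self.cl_int_sec_i * (1.0 - self.f_a)
        )


class DoseEvent(_Strict):
    """A single administration: route ``po`` (lumen) or ``iv`` (central blood)."""

    route: str
    amount: float
    time: float = 0.0

    @model_validator(mode="after")
    def _validate(self) -> "DoseEvent":
        if self.route not in ("po", "iv"):
            raise ValueError(f"route must be 'po' or 'iv', got {self.route!r}")
        if not self.amount > 0:
            raise ValueError(f"amount must be strictly positive, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        return self


class ParameterBundle(_Strict):
    """A validated (physiology, drug, flow-model) triple."""

    physiology: Physiology
    drug: DrugParams
    spec: FlowModelSpec

    def to_dict(self) -> dict:
        out = {
            "physiology": self.physiology.model_dump(),
            "drug": self.drug.model_dump(),
            "spec": self.spec.model_dump(),
        }
        out["spec"]["variant"] = self.spec.variant.value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterBundle":
        return cls(
            physiology=Physiology(**data.get("physiology", {})),
            drug=DrugParams(**data.get("drug", {})),
            spec=FlowModelSpec(**data.get("spec", {})),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ParameterBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def validate(
    physiology: Union[Physiology, dict, None] = None,
    drug: Union[DrugParams, dict, None] = None,
    spec: Union[FlowModelSpec, dict, None] = None,
) -> ParameterBundle:
    """Validate raw inputs into a :class:`ParameterBundle`.

    Accepts model instances or plain dicts (snake_case keys exactly matching
    the field names; unknown keys raise).  Derived fields (``q_h``,
    ``cl_int_h``, variant-default ``f_q``) are available on the result.
    """
    if not isinstance(physiology, Physiology):
        physiology = Physiology(**(physiology or {}))
    if not isinstance(drug, DrugParams):
        drug = DrugParams(**(drug or {}))
    if not isinstance(spec, FlowModelSpec):
        spec = FlowModelSpec(**(spec or {}))
    return ParameterBundle(physiology=physiology, drug=drug, spec=spec)


def load_config(path: Union[str, Path]) -> ParameterBundle:
    """Read a JSON config file into a validated bundle."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed JSON in {path}: line {exc.lineno} column {exc.colno}: {exc.msg}"
        ) from exc
    return ParameterBundle.from_dict(data)
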