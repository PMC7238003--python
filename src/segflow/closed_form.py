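"""Steady-state availability equations of the intestine-liver first-pass unit.

The common closed-form solution covers the traditional (TM), segregated-flow
(SFM) and Q_Gut variants through the single split fraction ``f_q``:

    F_I = f_q*Q_PV*CL_d2I /
          { f_q*Q_PV*CL_d2I + (f_q*Q_PV + fu_B*CL_d1I) * L }
    L   = CL_int_met1I + CL_int_met2I + CL_int_secI * (1 - F_a)

    F_H = Q_H*(CL_d2H + CL_intH) /
          { Q_H*(CL_d2H + CL_intH) + fu_B*CL_d1H*CL_intH }

    F_sys = F_a * F_I * F_H  =  (AUC_po/Dose_po) / (AUC_iv/Dose_iv)

Both factors follow from steady-state mass balance over a vascular/cellular
two-compartment organ: for the intestine, absorbed drug enters the enterocyte
cell, exchanges with the enterocyte blood at fu_B*CL_d1I (in) and CL_d2I
(out), and is lost at the net intrinsic clearance L; only the fraction
``1 - F_a`` of apically secreted drug is a net loss because secreted drug
re-enters the lumen pool and is reabsorbed with probability F_a.

For drug arriving from the circulation, only the fraction ``f_q`` of portal
flow samples the enterocyte region, so whole-organ extraction of circulating
drug is bounded by f_q — the flow-bypass mechanism behind route-dependent
intestinal metabolism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .params import DrugParams, FlowModelSpec, ParameterBundle, Physiology

__all__ = [
    "AvailabilityResult",
    "ContributionResult",
    "FqEstimate",
    "availability",
    "flow_averaged_pv",
    "first_pass_contributions",
    "circulating_extraction",
    "systemic_clearance",
    "fq_from_route_extractions",
]


@dataclass(frozen=True)
class AvailabilityResult:
    """Intestinal/hepatic availabilities and systemic bioavailability."""

    f_i: float
    f_h: float
    f_sys: float
    e_i: float
    e_h: float
    e_i_circ: float

    def to_dict(self) -> dict:
        return {
            "f_i": self.f_i,
            "f_h": self.f_h,
            "f_sys": self.f_sys,
            "e_i": self.e_i,
            "e_h": self.e_h,
            "e_i_circ": self.e_i_circ,
        }


@dataclass(frozen=True)
class ContributionResult:
    """Intestinal vs hepatic shares of first-pass removal.

    ``frac_i + frac_h == 1`` whenever any first-pass removal occurs; with no
    removal at all both fractions are 0 and ``no_removal`` is set.
    """

    frac_i: float
    frac_h: float
    c_pv_bar: float
    no_removal: bool = False

    def to_dict(self) -> dict:
        return {
            "frac_i": self.frac_i,
            "frac_h": self.frac_h,
            "c_pv_bar": self.c_pv_bar,
            "no_removal": self.no_removal,
        }


@dataclass(frozen=True)
class FqEstimate:
    """f_q estimate from paired-route extraction ratios.

    ``permeability_limited_caveat`` flags that the estimator f_q = E_circ/E_po
    is exact only in the permeability-nonlimited limit (CL_d >> intrinsic
    clearance); with finite transport it is an approximation.
    """

    f_q: float
    sfm_consistent: bool
    permeability_limited_caveat: bool = True


def _intestinal_availability(drug: DrugParams, phys: Physiology, f_q: float) -> float:
    flow = f_q * phys.q_sma
    loss = drug.luminal_loss
    numer = flow * drug.cl_d2_i
    denom = numer + (flow + drug.fu_b * drug.cl_d1_i) * loss
    if denom == 0.0:
        # cl_d2_i = 0 with no intestinal intrinsic clearance: the organ does
        # not touch the drug at all, so it passes through unextracted.
        warnings.warn(
            "no intestinal disposition (cl_d2_i = 0 and all intestinal "
            "intrinsic clearances 0); returning F_I = 1",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0
    return numer / denom


def _hepatic_availability(drug: DrugParams, phys: Physiology) -> float:
    numer = phys.q_h * (drug.cl_d2_h + drug.cl_int_h)
    denom = numer + drug.fu_b * drug.cl_d1_h * drug.cl_int_h
    if denom == 0.0:
        warnings.warn(
            "no hepatic disposition (cl_d2_h = 0 and cl_int_h = 0); "
            "returning F_H = 1",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0
    return numer / denom


def availability(
    drug: DrugParams, phys: Physiology, spec: FlowModelSpec
) -> AvailabilityResult:
    """Closed-form F_I, F_H, F_sys and circulating-drug intestinal extraction."""
    f_i = _intestinal_availability(drug, phys, spec.f_q)
    f_h = _hepatic_availability(drug, phys)
    return AvailabilityResult(
        f_i=f_i,
        f_h=f_h,
        f_sys=drug.f_a * f_i * f_h,
        e_i=1.0 - f_i,
        e_h=1.0 - f_h,
        e_i_circ=circulating_extraction(drug, phys, spec),
    )


def flow_averaged_pv(c_a: float, f_i: float, f_q: float) -> float:
    """Flow-averaged portal venous concentration for arterial input ``c_a``.

    The enterocyte stream (fraction f_q of portal flow) leaves at F_I*c_a,
    the serosal bypass stream leaves unextracted, so
    C_PV = c_a * [f_q*F_I + (1 - f_q)].
    """
    if c_a < 0:
        raise ValueError(f"c_a must be >= 0, got {c_a}")
    if not (0.0 <= f_i <= 1.0):
        raise ValueError(f"f_i out of [0,1]: got {f_i}")
    if not (0.0 < f_q <= 1.0):
        raise ValueError(f"f_q out of (0,1]: got {f_q}")
    return c_a * (f_q * f_i + (1.0 - f_q))


def first_pass_contributions(
    f_i: float, e_h: float, phys: Physiology, f_q: float
) -> ContributionResult:
    """Intestinal vs hepatic shares of removal for circulating drug.

    The intestinal removal velocity is f_q*Q_PV*(1-F_I)*C_A; the liver
    removes the fraction E_H of everything it receives — the flow-averaged
    portal stream plus hepatic arterial inflow.
    """
    if not (0.0 <= f_i <= 1.0):
        raise ValueError(f"f_i out of [0,1]: got {f_i}")
    if not (0.0 <= e_h <= 1.0):
        raise ValueError(f"e_h out of [0,1]: got {e_h}")
    if not (0.0 < f_q <= 1.0):
        raise ValueError(f"f_q out of (0,1]: got {f_q}")
    c_pv_bar = flow_averaged_pv(1.0, f_i, f_q)
    v_i = f_q * phys.q_pv * (1.0 - f_i)
    v_h = e_h * (phys.q_pv * c_pv_bar + phys.q_ha)
    total = v_i + v_h
    if total == 0.0:
        return ContributionResult(
            frac_i=0.0, frac_h=0.0, c_pv_bar=c_pv_bar, no_removal=True
        )
    frac_i = v_i / total
    frac_h = v_h / total
    return ContributionResult(frac_i=frac_i, frac_h=frac_h, c_pv_bar=c_pv_bar)


def circulating_extraction(
    drug: DrugParams, phys: Physiology, spec: FlowModelSpec
) -> float:
    """Whole-intestine extraction of circulating (arterial) drug, E_I,circ.

    Steady-state balance for arterial input into the enterocyte blood gives

        E_I,circ = f_q * fu_B*CL_d1I*L /
                   [ f_q*Q_PV*(CL_d2I + L) + fu_B*CL_d1I*L ]

    which satisfies E_I,circ <= f_q for every parameter set: the serosal
    bypass caps how much circulating drug the enterocytes can see.
    """
    loss = drug.luminal_loss
    if loss == 0.0:
        return 0.0
    f_q = spec.f_q
    uptake = drug.fu_b * drug.cl_d1_i * loss
    denom = f_q * phys.q_sma * (drug.cl_d2_i + loss) + uptake
    if denom == 0.0:
        return 0.0
    return f_q * uptake / denom


def systemic_clearance(
    drug: DrugParams, phys: Physiology, spec: FlowModelSpec
) -> float:
    """Total systemic (blood) clearance from the central compartment.

    Per circulation pass, the intestine removes E_I,circ of the portal-bound
    stream and the liver removes E_H of its total inflow (portal effluent plus
    hepatic arterial); renal clearance acts on central blood directly:

        CL_sys = Q_PV*E_I,circ + E_H*(Q_H - Q_PV*E_I,circ) + CL_R
    """
    e_circ = circulating_extraction(drug, phys, spec)
    e_h = 1.0 - _hepatic_availability(drug, phys)
    intestinal = phys.q_sma * e_circ
    return intestinal + e_h * (phys.q_h - intestinal) + drug.cl_r


def fq_from_route_extractions(e_po: float, e_circ: float) -> FqEstimate:
    """Estimate f_q from paired oral and intravenous intestinal extractions.

    In the permeability-nonlimited limit E_I,circ -> f_q*(1 - F_I), so
    f_q ~= E_circ / E_po.  A value < 0.2 is consistent with segregated flow;
    = 1 is consistent with the traditional model.
    """
    if not (0.0 < e_po < 1.0):
        raise ValueError(f"e_po out of (0,1): got {e_po}")
    if not (0.0 < e_circ < 1.0):
        raise ValueError(f"e_circ out of (0,1): got {e_circ}")
    if e_circ > e_po:
        raise ValueError(
            f"e_circ ({e_circ}) > e_po ({e_po}) is inconsistent with a "
            "split-flow intestine (circulating extraction cannot exceed oral)"
        )
    f_q = e_circ / e_po
    return FqEstimate(f_q=f_q, sfm_consistent=f_q < 0.2)


def availability_from_bundle(bundle: ParameterBundle) -> AvailabilityResult:
    """Convenience wrapper over :func:`availability`."""
    return availability(bundle.drug, bundle.physiology, bundle.spec)
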