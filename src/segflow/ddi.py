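"""Drug-drug interaction prediction under TM vs SFM flow models.

Two tiers:

* **static** — the perpetrator is summarized by constant scaling factors
  ``r_I, r_H`` on the victim's intestinal and hepatic intrinsic clearances
  (competitive inhibition at fixed unbound inhibitor concentration gives
  ``r = 1 + I_u/K_i``; induction gives a divisor < 1, i.e. a fold multiplier
  on the clearances).  AUC ratios come from the closed-form availabilities
  and systemic clearance; metabolite fold-changes from exact AUC sink solves.

* **dynamic** — the perpetrator's own linear kinetics are simulated and its
  unbound enterocyte-cell and liver-cell concentrations scale the victim's
  intrinsic clearances time-dependently by ``1/(1 + C_u(t)/K_i)``; the victim
  becomes a linear time-varying system solved by stiff integration with an
  exact linear tail correction once the inhibitor is gone.

Because > 80% of the intestinal flow bypasses the enterocytes under the SFM,
an orally dosed perpetrator attains far higher enterocyte exposure than an
intravenous one, and an orally dosed victim is far more sensitive to
intestinal inhibition — the route-dependent DDI signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import model_validator
from scipy.integrate import solve_ivp

from . import closed_form, engine
from .params import DoseEvent, DrugParams, FlowModelSpec, Physiology, _Strict

__all__ = [
    "PerpetratorParams",
    "DDIResult",
    "scale_intrinsic",
    "static_ddi",
    "induction",
    "simulate_pair",
    "route_grid",
]

ROUTES = ("po", "iv")


class PerpetratorParams(_Strict):
    """Perpetrator drug, interaction mechanism and dosing.

    ``ki_i`` / ``ki_h`` are competitive inhibition constants toward the
    victim's intestinal / hepatic intrinsic clearances, in the same
    concentration units as the simulation (use ``math.inf`` for no effect at
    a site).  ``fold_i`` / ``fold_h`` are induction multipliers (> 1 induces).
    """

    drug: DrugParams
    ki_i: float = math.inf
    ki_h: float = math.inf
    fold_i: float = 1.0
    fold_h: float = 1.0
    doses: List[DoseEvent] = []

    @model_validator(mode="after")
    def _validate(self) -> "PerpetratorParams":
        for name in ("ki_i", "ki_h", "fold_i", "fold_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        return self


@dataclass(frozen=True)
class DDIResult:
    """AUC ratios and metabolite fold-changes, by victim route."""

    aucr_po: float
    aucr_iv: float
    delta_m1_po: float
    delta_m2_po: float
    delta_m1_iv: float
    delta_m2_iv: float

    def to_dict(self) -> dict:
        return {
            "aucr_po": self.aucr_po,
            "aucr_iv": self.aucr_iv,
            "delta_m1_po": self.delta_m1_po,
            "delta_m2_po": self.delta_m2_po,
            "delta_m1_iv": self.delta_m1_iv,
            "delta_m2_iv": self.delta_m2_iv,
        }


def scale_intrinsic(drug: DrugParams, r_i: float = 1.0, r_h: float = 1.0) -> DrugParams:
    """Divide all intestinal intrinsic clearances by ``r_i`` and both hepatic
    intrinsic clearances by ``r_h`` (one K_i per site)."""
    if not (r_i > 0 and r_h > 0):
        raise ValueError(f"interaction factors must be > 0, got r_i={r_i}, r_h={r_h}")
    return drug.model_copy(
        update={
            "cl_int_met1_i": drug.cl_int_met1_i / r_i,
            "cl_int_met2_i": drug.cl_int_met2_i / r_i,
            "cl_int_sec_i": drug.cl_int_sec_i / r_i,
            "cl_int_met_h": drug.cl_int_met_h / r_h,
            "cl_int_sec_h": drug.cl_int_sec_h / r_h,
        }
    )


def _metabolite_fractions(
    drug: DrugParams, phys: Physiology, spec: FlowModelSpec
) -> Dict[str, float]:
    model = engine.build_model(drug, phys, spec)
    out = {}
    for route in ROUTES:
        ev = [DoseEvent(route=route, amount=1.0, time=0.0)]
        sinks = engine.sink_totals_to_infinity(model, ev)
        out[f"m1_{route}"] = float(sinks[model.sinks.index("urine_M1")])
        out[f"m2_{route}"] = float(
            sinks[model.sinks.index("bile_M2")]
            + sinks[model.sinks.index("urine_M2")]
        )
    return out


def static_ddi(
    victim: DrugParams,
    phys: Physiology,
    spec: FlowModelSpec,
    r_i: float = 1.0,
    r_h: float = 1.0,
) -> DDIResult:
    """Closed-form DDI tier at constant interaction factors.

    AUC_po = F_a*F_I*F_H*Dose/CL_sys and AUC_iv = Dose/CL_sys, so

        AUCR_po = (F_sys,i / F_sys,c) * (CL_sys,c / CL_sys,i)
        AUCR_iv =  CL_sys,c / CL_sys,i

    where the intravenous ratio responds only through systemic clearance
    (hepatic plus circulating-intestinal extraction).
    """
    inhibited = scale_intrinsic(victim, r_i, r_h)
    av_c = closed_form.availability(victim, phys, spec)
    av_i = closed_form.availability(inhibited, phys, spec)
    cl_c = closed_form.systemic_clearance(victim, phys, spec)
    cl_i = closed_form.systemic_clearance(inhibited, phys, spec)
    if cl_i <= 0 or cl_c <= 0:
        raise ValueError("systemic clearance is zero; AUC ratio undefined")
    aucr_iv = cl_c / cl_i
    aucr_po = (av_i.f_sys / av_c.f_sys) * aucr_iv

    frac_c = _metabolite_fractions(victim, phys, spec)
    frac_i = _metabolite_fractions(inhibited, phys, spec)

    def _fold(key: str) -> float:
        return frac_i[key] / frac_c[key] if frac_c[key] > 0 else math.nan

    return DDIResult(
        aucr_po=aucr_po,
        aucr_iv=aucr_iv,
        delta_m1_po=_fold("m1_po"),
        delta_m2_po=_fold("m2_po"),
        delta_m1_iv=_fold("m1_iv"),
        delta_m2_iv=_fold("m2_iv"),
    )


def induction(
    victim: DrugParams,
    phys: Physiology,
    spec: FlowModelSpec,
    fold_i: float = 1.0,
    fold_h: float = 1.0,
) -> DDIResult:
    """Enzyme/transporter induction: multiply intrinsic clearances by the fold.

    Equivalent to :func:`static_ddi` with divisors ``1/fold``; AUC ratios fall
    below 1, and under the SFM an intestinal-only induction lowers the oral
    AUC far more than the intravenous one.
    """
    if fold_i <= 0 or fold_h <= 0:
        raise ValueError("induction folds must be > 0")
    return static_ddi(victim, phys, spec, r_i=1.0 / fold_i, r_h=1.0 / fold_h)


def _split_victim_matrices(
    victim: DrugParams, phys: Physiology, spec: FlowModelSpec
) -> Tuple[engine.ModelMatrix, np.ndarray, np.ndarray, np.ndarray]:
    """Decompose the victim system as A(t) = A_base + s_I(t)*A_I + s_H(t)*A_H."""
    full = engine.build_model(victim, phys, spec)
    no_int_i = engine.build_model(
        victim.model_copy(
            update={"cl_int_met1_i": 0.0, "cl_int_met2_i": 0.0, "cl_int_sec_i": 0.0}
        ),
        phys,
        spec,
    )
    no_int_h = engine.build_model(
        victim.model_copy(update={"cl_int_met_h": 0.0, "cl_int_sec_h": 0.0}),
        phys,
        spec,
    )
    a_i = full.A - no_int_i.A
    a_h = full.A - no_int_h.A
    a_base = full.A - a_i - a_h
    return full, a_base, a_i, a_h


def simulate_pair(
    victim: DrugParams,
    perpetrator: PerpetratorParams,
    phys: Physiology,
    spec: FlowModelSpec,
    victim_route: str = "po",
    perp_route: str = "po",
    victim_dose: float = 1.0,
    t_end: float = 200.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    constant_conc: Optional[Tuple[float, float]] = None,
) -> Dict[str, float]:
    """Dynamic DDI tier: co-simulate perpetrator and victim.

    The perpetrator follows its own linear system (with static induction
    folds applied to the victim separately if set); its unbound cellular
    concentrations modulate the victim's intrinsic clearances.  After
    ``t_end`` the remaining victim amounts are propagated with the exact
    linear (by then uninhibited) tail so the AUC extends to infinity.

    ``constant_conc = (cu_ec, cu_lc)`` replaces the perpetrator simulation
    with fixed unbound cellular concentrations (an infusion held at steady
    state); the tail then keeps the inhibited matrix, and the result should
    agree with the closed-form static tier.
    """
    if victim_route not in ROUTES or perp_route not in ROUTES:
        raise ValueError("routes must be 'po' or 'iv'")

    if perpetrator.doses:
        p_doses = [d for d in perpetrator.doses if d.route == perp_route]
        if not p_doses:  # re-route the configured dose(s) for the grid
            p_doses = [
                DoseEvent(route=perp_route, amount=d.amount, time=d.time)
                for d in perpetrator.doses
            ]
    else:
        p_doses = []

    present = bool(p_doses) or constant_conc is not None
    interacts = (
        not (math.isinf(perpetrator.ki_i) and math.isinf(perpetrator.ki_h))
        or perpetrator.fold_i != 1.0
        or perpetrator.fold_h != 1.0
    )
    base_victim = victim
    if present:
        base_victim = scale_intrinsic(
            victim, r_i=1.0 / perpetrator.fold_i, r_h=1.0 / perpetrator.fold_h
        )
    v_full, a_base, a_i, a_h = _split_victim_matrices(base_victim, phys, spec)

    if not (present and interacts):
        # absent (or inert) perpetrator: exact neutrality by construction
        ev = [DoseEvent(route=victim_route, amount=victim_dose, time=0.0)]
        auc0 = engine.auc_to_infinity(v_full, ev)
        i_c = v_full.index("central")
        auc_c = auc0[i_c] / v_full.volumes[i_c]
        return {"aucr": 1.0, "delta_m1": 1.0, "delta_m2": 1.0,
                "auc_with": auc_c, "auc_control": auc_c}

    if constant_conc is not None:
        return _constant_conc_pair(
            v_full, victim, phys, spec, a_base, a_i, a_h, perpetrator,
            constant_conc, victim_route, victim_dose, t_end, rtol, atol,
        )

    p_model = engine.build_model(perpetrator.drug, phys, spec)

    n_p = p_model.n_dyn
    n_v = v_full.A.shape[0]
    i_ec = p_model.index("ec")
    i_lc = p_model.index("lc")
    v_ec = p_model.volumes[i_ec]
    v_lc = p_model.volumes[i_lc]
    fu_i_p = perpetrator.drug.fu_i
    fu_h_p = perpetrator.drug.fu_h
    i_central_v = v_full.index("central")
    v_b = v_full.volumes[i_central_v]

    a_p = p_model.a_dyn

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        p = y[:n_p]
        v = y[n_p : n_p + n_v]
        cu_ec = fu_i_p * p[i_ec] / v_ec
        cu_lc = fu_h_p * p[i_lc] / v_lc
        s_i = 1.0 / (1.0 + cu_ec / perpetrator.ki_i)
        s_h = 1.0 / (1.0 + cu_lc / perpetrator.ki_h)
        dv = (a_base + s_i * a_i + s_h * a_h) @ v
        dauc = v[i_central_v] / v_b
        return np.concatenate([a_p @ p, dv, [dauc]])

    y0 = np.zeros(n_p + n_v + 1)
    for d in p_doses:
        if d.time != 0.0:
            raise ValueError("perpetrator doses must be at t = 0 in this tier")
        y0[p_model.input_map[d.route]] += d.amount
    y0[n_p + v_full.input_map[victim_route]] = victim_dose

    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"DDI integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    v_end = y_end[n_p : n_p + n_v]
    auc_numeric = y_end[-1]

    # exact tail with the (by-then uninhibited) victim system
    n_dyn = v_full.n_dyn
    tail_auc = _tail_auc(v_full, v_end[:n_dyn])
    auc = auc_numeric + tail_auc[i_central_v] / v_b
    sink_rows = v_full.A[n_dyn:, :n_dyn]
    sinks_inf = v_end[n_dyn:] + sink_rows @ tail_auc

    # control: the unmodified victim alone, exact
    v_ctrl = engine.build_model(victim, phys, spec)
    ev = [DoseEvent(route=victim_route, amount=victim_dose, time=0.0)]
    auc0 = engine.auc_to_infinity(v_ctrl, ev)
    sinks0 = engine.sink_totals_to_infinity(v_ctrl, ev, auc0)
    auc_control = auc0[i_central_v] / v_b

    idx = {name: k for k, name in enumerate(v_full.sinks)}
    m1 = sinks_inf[idx["urine_M1"]]
    m2 = sinks_inf[idx["bile_M2"]] + sinks_inf[idx["urine_M2"]]
    m1_0 = sinks0[idx["urine_M1"]]
    m2_0 = sinks0[idx["bile_M2"]] + sinks0[idx["urine_M2"]]
    return {
        "aucr": auc / auc_control,
        "delta_m1": m1 / m1_0 if m1_0 > 0 else math.nan,
        "delta_m2": m2 / m2_0 if m2_0 > 0 else math.nan,
        "auc_with": auc,
        "auc_control": auc_control,
    }


def _constant_conc_pair(
    v_full: engine.ModelMatrix,
    victim: DrugParams,
    phys: Physiology,
    spec: FlowModelSpec,
    a_base: np.ndarray,
    a_i: np.ndarray,
    a_h: np.ndarray,
    perpetrator: PerpetratorParams,
    constant_conc: Tuple[float, float],
    victim_route: str,
    victim_dose: float,
    t_end: float,
    rtol: float,
    atol: float,
) -> Dict[str, float]:
    cu_ec, cu_lc = constant_conc
    s_i = 1.0 / (1.0 + cu_ec / perpetrator.ki_i)
    s_h = 1.0 / (1.0 + cu_lc / perpetrator.ki_h)
    a_t = a_base + s_i * a_i + s_h * a_h
    n_dyn = v_full.n_dyn
    i_c = v_full.index("central")
    v_b = v_full.volumes[i_c]

    def rhs(t, y):
        dy = a_t @ y[:-1]
        return np.concatenate([dy, [y[i_c] / v_b]])

    y0 = np.zeros(a_t.shape[0] + 1)
    y0[v_full.input_map[victim_route]] = victim_dose
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"DDI integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    # tail keeps the inhibited matrix (inhibitor held at steady state)
    inhibited = engine.ModelMatrix(
        states=v_full.states, sinks=v_full.sinks, A=a_t,
        input_map=v_full.input_map, volumes=v_full.volumes, meta=v_full.meta,
    )
    tail = _tail_auc(inhibited, y_end[:n_dyn])
    auc = y_end[-1] + tail[i_c] / v_b
    sinks_inf = y_end[n_dyn:-1] + a_t[n_dyn:, :n_dyn] @ tail

    v_ctrl = engine.build_model(victim, phys, spec)
    ev = [DoseEvent(route=victim_route, amount=victim_dose, time=0.0)]
    auc0 = engine.auc_to_infinity(v_ctrl, ev)
    sinks0 = engine.sink_totals_to_infinity(v_ctrl, ev, auc0)
    idx = {name: k for k, name in enumerate(v_full.sinks)}
    m1 = sinks_inf[idx["urine_M1"]]
    m2 = sinks_inf[idx["bile_M2"]] + sinks_inf[idx["urine_M2"]]
    m1_0 = sinks0[idx["urine_M1"]]
    m2_0 = sinks0[idx["bile_M2"]] + sinks0[idx["urine_M2"]]
    auc_control = auc0[i_c] / v_b
    return {
        "aucr": auc / auc_control,
        "delta_m1": m1 / m1_0 if m1_0 > 0 else math.nan,
        "delta_m2": m2 / m2_0 if m2_0 > 0 else math.nan,
        "auc_with": auc,
        "auc_control": auc_control,
    }


def _tail_auc(model: engine.ModelMatrix, x_end: np.ndarray) -> np.ndarray:
    a = model.a_dyn
    outflow = -np.diag(a) > 0
    inflow = (a - np.diag(np.diag(a)) > 0).any(axis=1) | (x_end > 0)
    active = outflow | inflow
    tail = np.zeros(model.n_dyn)
    if active.any():
        tail[active] = np.linalg.solve(
            a[np.ix_(active, active)], -x_end[active]
        )
    return tail


def route_grid(
    victim: DrugParams,
    perpetrator: PerpetratorParams,
    phys: Physiology,
    spec: FlowModelSpec,
    **kwargs,
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Dynamic-tier results over the full {po, iv} x {po, iv} route grid,
    keyed by (victim_route, perp_route)."""
    return {
        (vr, pr): simulate_pair(
            victim, perpetrator, phys, spec, victim_route=vr, perp_route=pr, **kwargs
        )
        for vr in ROUTES
        for pr in ROUTES
    }
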