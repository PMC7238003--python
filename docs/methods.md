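# Methods

## The model

`segflow` treats the small intestine and the liver as a serially arranged
first-pass unit embedded in a closed circulation. The intestine is perfused
by portal-destined blood flow (Q_PV, by default equal to the superior
mesenteric flow Q_SMA and to 75% of total liver blood flow Q_H); the liver
additionally receives hepatic arterial flow Q_HA (25% of Q_H). The model
variants differ in exactly one number, f_Q — the fraction of the intestinal
flow that perfuses the metabolically active enterocyte region:

| variant | f_Q | meaning |
|---|---|---|
| TM (traditional) | 1 | the whole intestinal flow sees the enterocytes |
| Q_Gut | 0.484 | villous-flow fraction used by the Q_Gut model |
| SFM (segregated flow) | < 0.2 (default 0.1) | most flow shunts through the inactive serosa |
| SSFM (segmental SFM) | as SFM | three serial segments, heterogeneous enzymes/transporters |

Each organ is a vascular/cellular compartment pair: blood exchanges with the
cell at basolateral influx/efflux transport clearances (fu_B·CL_d1 inward,
CL_d2 outward, the latter scaled by the tissue unbound fraction), and all
intrinsic clearances (metabolic and secretory) act on the unbound cellular
concentration. This two-compartment structure is required — a flow-limited
single compartment cannot reproduce the closed-form availability's grouping
(f_Q·Q_PV + fu_B·CL_d1I), which we verified by symbolic steady-state
reduction before writing the simulator.

The closed-form tier evaluates

    F_I  = f_Q·Q_PV·CL_d2I / { f_Q·Q_PV·CL_d2I + (f_Q·Q_PV + fu_B·CL_d1I)·L }
    L    = CL_int,met1I + CL_int,met2I + CL_int,secI·(1 − F_a)
    F_H  = Q_H·(CL_d2H + CL_intH) / { Q_H·(CL_d2H + CL_intH) + fu_B·CL_d1H·CL_intH }
    F_sys = F_a·F_I·F_H

together with the flow-averaged portal concentration
C̄_PV = C_A·[f_Q·F_I + (1 − f_Q)], the intestinal/hepatic shares of
first-pass removal, and the whole-organ extraction of *circulating* drug

    E_I,circ = f_Q·fu_B·CL_d1I·L / [ f_Q·Q_PV·(CL_d2I + L) + fu_B·CL_d1I·L ] ,

which is bounded by f_Q: the serosal shunt is what makes intestinal
extraction route-dependent. E_I,circ is not printed in the closed-form
source for the availabilities; we derived it from the steady-state balance
of the same two-compartment topology (arterial input into the enterocyte
blood), and verified numerically that it converges to 1 − F_I in the
permeability-nonlimited TM limit. Systemic blood clearance follows as
CL_sys = Q_PV·E_I,circ + E_H·(Q_H − Q_PV·E_I,circ) + CL_R and is verified in
the tests against the exact intravenous AUC of the simulator.

## The simulator

The kinetic tier is a linear, time-invariant compartmental system over
amounts (lumen, enterocyte blood/cell, serosa, liver blood/cell, central
blood, plus cumulative sinks). Design choices:

* **Absorption.** F_a is realized kinetically as competing first-order
  absorption (k_a, lumen → enterocyte cell) and luminal loss
  (k_loss = k_a·(1 − F_a)/F_a), so the absorbed fraction is exactly F_a.
  Apically secreted drug re-enters the same lumen pool and faces the same
  split, which reproduces the CL_int,secI·(1 − F_a) net-loss factor of the
  closed form at steady state.
* **Serosa.** A non-eliminating, non-partitioning flow-through compartment
  carrying (1 − f_Q)·Q_SMA. At f_Q = 1 it carries no flow and the SFM graph
  degenerates exactly to the TM.
* **Metabolites.** Tracked as cumulative formed amounts, not simulated
  species: the intestinal metabolite (M1) is routed to urine (a polar
  conjugate formed in the gut wall cannot reach bile), the hepatic
  metabolite (M2) is split bile/urine by `p_bile`. The second intestinal
  metabolic pathway keeps its own sink by default; `merge_met2` routes it
  into the urinary M2 pool instead. These routing fractions are
  configuration, not biology fixed by the model.
* **Solution.** Time courses are exact matrix exponentials (`scipy.linalg.expm`
  stepped over the output grid); AUCs to infinity solve `A_dyn·x = −dose`
  directly, and cumulative sinks at infinity are the sink rows applied to
  those AUCs. A trapezoid + exact-tail cross-check is kept in the tests.
  States that are structurally isolated (the serosa under TM) are excluded
  from the solves; a drug trapped in a non-eliminating cycle raises an
  explicit singularity error rather than returning a number.
* **Route-specific availabilities.** Single-pass oral and intravenous
  intestinal availabilities are computed exactly by cutting recirculation in
  the AUC system (making the central compartment, or the liver blood,
  absorbing) instead of by approximate flux bookkeeping. The oral F_I divides
  portal appearance by *primary* absorption (an enterocyte-absorbing solve),
  charging re-secretion losses to F_I exactly as the closed form does.

The simulator and the closed form are two independent routes to the same
steady-state quantities; their agreement (to ~1e−9 on availabilities, 0.5%
allowed on F_sys) is enforced in the acceptance tests.

Mass balance (states + sinks = dose) holds to < 1e−8 relative at every
output time and is asserted on every simulation by default.

## Units

Flows and clearances are L/h, volumes L, amounts mg, concentrations mg/L.
Being linear, the model is invariant to the mass unit; the inhibitor
fixtures use µmol so that cellular concentrations are in µM and comparable
with an inhibition constant quoted in µM. AUC-derived fractions are
invariant to any rescaling of compartment volumes (tested).

## Drug–drug interactions

Two tiers:

* **Static:** constant factors r_I = 1 + I_u/K_i,I and r_H = 1 + I_u/K_i,H
  divide the intestinal and hepatic intrinsic clearances (one K_i per site;
  induction is the multiplicative inverse). AUC ratios follow from the
  closed form: AUCR_iv = CL_sys,control/CL_sys,inhibited and
  AUCR_po = (F_sys ratio)·AUCR_iv. Metabolite fold-changes come from exact
  sink solves.
* **Dynamic:** the perpetrator's own linear kinetics are co-integrated with
  the victim; the perpetrator's unbound enterocyte-cell and liver-cell
  concentrations scale the victim's intrinsic clearances by 1/(1 + C_u(t)/K_i),
  making the victim linear time-varying (LSODA, rtol 1e−10, atol 1e−12, with
  an exact linear tail once the inhibitor is gone). Holding the inhibitor
  concentration constant must and does reproduce the static tier.

On route equality under the TM: the quantity that is route-blind is the
*fractional inhibition of intestinal metabolite formation* (ΔM1), not the
AUC ratio — the oral AUC ratio additionally carries the F_I change that both
models share. The tests therefore assert ΔM1 route-equality for the TM and
AUC-ratio dominance of the oral/oral combination for the SFM, which is also
how the in-vivo evidence is framed.

## Estimation and model discrimination

Fitting uses a Gaussian likelihood on log observations (multiplicative
error, matching the generator's lognormal noise), i.e. unweighted least
squares on log-transformed positive values; observations at or below the
LLOQ are excluded. Optimization is trust-region-reflective least squares
with Latin-hypercube multistarts inside bounds (log-spaced for clearances,
uniform for f_Q), all randomness behind one user seed. AICc
(−2·logL + 2k + 2k(k+1)/(n−k−1), k counting the profiled variance) is used
because paired-route animal studies are small. The TM is the SFM constrained
at f_Q = 1; `discriminate` exploits the nesting by warm-starting the SFM fit
from the TM solution, so the SFM can never lose to its own special case
through an optimizer miss, and reports a nested F-test beside ΔAICc.

The objective and weighting are this package's own documented choices; the
historical fits that motivated the workflow did not publish theirs.

## Synthetic data

The generator emulates a paired-route (oral/intraduodenal vs intravenous)
study with plasma parent drug and cumulative urinary/biliary metabolite
amounts — the observables that discriminate the flow models, since biliary
metabolite can only be hepatic while urinary metabolite is mixed. Defaults:
12 geometrically spaced sampling times per route over a 12 h horizon (about
five elimination half-lives of the morphine-like fixture), 5% lognormal CV
when noise is requested, noise applied to increments of cumulative analytes
and re-cumulated so observed excretion stays monotone. The `morphine_like`
fixture uses the in-vivo split fraction f_Q = 0.10 with clearances sized so
both organs contribute materially (oral E_I ≈ 0.63, E_H ≈ 0.58 by the
closed form), keeping f_Q identifiable.

What the generator does *not* emulate: inter-individual variability,
absorption-phase complexities (dissolution, gastric emptying, pH),
metabolite kinetics, enterohepatic recycling, or assay drop-outs. Passing
the recovery tests therefore shows the estimator is consistent and the
discrimination workflow is calibrated *under the model's own error
structure*, not that real studies of this size always identify f_Q.

## Replicate-study sizes and tolerances

The parameter-recovery study uses 50 seeded replicates (plus 20 replicates
of the TM-generated null arm) at 5% CV with 3 multistarts per fit plus the
nested warm start; these sizes give stable medians in minutes on one core.
Observed performance: median |f_Q| error ~1–2% (tolerance 30%), SFM
preferred on SFM data in ~100% of replicates (threshold 90%), median null
ΔAICc within a few units of zero. Tolerances used elsewhere: 1e−12 on the
contribution-share identity, 1e−9 closed-form vs hand arithmetic, 1e−6 on
ODE-level model reductions and route identities, 0.5% simulator vs closed
form, 1% static-vs-dynamic DDI tiers.

## Known limitations

* Kinetics are linear throughout; no Michaelis–Menten saturation, no
  mechanism-based inactivation, no enzyme turnover for induction.
* The Q_Gut variant is represented as the common solution at f_Q = 0.484,
  not by the original Q_Gut formula F_I = Q_Gut/(Q_Gut + fu_B·CL_int); the
  two coincide only when transport does not limit tissue access.
* Metabolites have no disposition kinetics of their own; urine/bile routing
  is instantaneous.
* The route-identity of hepatic metabolite formation under the TM is exact
  only with no hepatic arterial inflow and non-limiting permeability; the
  tests condition on exactly those limits.
* The 0.484 villous-flow fraction is taken as given, not derived from
  cardiac output.
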