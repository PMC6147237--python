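# Methods

## Signalling network

The H1 cascade is modelled as a Petri net whose places are molecular
species and whose transitions are elementary mass-action reactions. Every
rate constant is 1 in arbitrary "Petri-net time units": the model is
deliberately semi-quantitative, encoding topology and relative pool sizes
rather than measured kinetics, and time is interpreted only as the relative
order of events. Two execution semantics share one network object:

* **Stochastic** — Gillespie's direct method over integer token counts,
  with combinatorial propensities for stoichiometries above one
  (`n(n−1)/2` for a homodimerisation); the continuum ODE mode uses the
  plain power law. The case-study roster never uses stoichiometry > 1, so
  the distinction is latent but implemented and tested.
* **Continuum** — `dS/dt = N v(S)` integrated with LSODA and the analytic
  mass-action Jacobian.

Catalysts are read arcs ("modifiers"): they multiply the rate linearly and
have zero net stoichiometry. Effectors the literature names but does not
mechanise (calcineurin between Ca²⁺ and NFAT, IκB between IKK and NF-κB,
ATP behind cAMP synthesis) are collapsed into single catalytic steps — the
roster encodes effector→target links, not every intermediate. Boundary
("clamped") species hold their amount constant while still contributing to
rates; the sustained-stimulus configuration clamps the ligand at the dose,
and a finite depleting ligand pool (clamp off, optional degradation
reaction) is the configuration for transient demonstrations.

One reaction was added beyond the effector→target roster: PIP₂ basal
turnover (`PIP2 → ∅`, k = 1). The PIP₂ pool has a constant synthesis
source; without stimulation its only sinks (PLCβ hydrolysis, PI3K
phosphorylation) are off, so a pre-stimulus steady state would not exist.
With the turnover reaction the unstimulated network has a unique fixed
point: every activated species at zero, PIP₂ at synthesis/turnover = 1,
each reporter at ε/k_dec.

**Reporters.** Each transcription factor X drives its luciferase by
`∅ → Luc_X` (rate 1 × X*), plus basal transcription at fixed ε = 0.01 and
first-order decay. ε is fixed, not fitted: it only sets the pre-stimulus
baseline that makes fold changes finite, and fitting it would trade off
exactly against the TF pool sizes.

**Conserved moieties** are computed as a rational basis of the left null
space of the stoichiometric matrix restricted to unclamped species (exact
arithmetic via sympy), scaled to primitive integers, with a small-integer
recombination pass toward nonnegative vectors. On the H1 roster this
recovers the 17 expected invariants — one per protein activation cycle,
the Ca²⁺ store, the BTK pool, and two for the G-protein heterotrimer
(trimer+Gαq-forms and trimer+Gβγ).

**Steady states** are found by integrating to a horizon (default 10⁴ time
units) and then Newton-polishing the unclamped species, with one equation
per conserved moiety replaced by a linear constraint pinning that moiety's
total to its initial value — so conservation laws are preserved exactly,
and the (rank-deficient) raw root problem becomes well posed. The
refinement is rejected if it strays far from the integrated state or goes
negative, which also prevents a divergent system from "converging" to a
distant unstable fixed point. Convergence demands a relative residual
`max |dS_i/dt|/(1+|S_i|) < 1e-10`; non-convergence raises, with a flag
when the horizon tail is still moving (possible oscillation).

## Calibration

The measured quantity is the fold change in reporter signal: stimulated
over unstimulated steady state. Fitted parameters are the 16 moiety totals
plus the dose (all on log10 scale, bounds 10⁻²–10³); rates stay at 1. The
objective is the sum of squared *relative* residuals `((pred−obs)/obs)²`.
SD-weighting is available but off by default: the measured SDs span two
orders of magnitude and would effectively delete the noisiest factor from
the fit. Optimisation is seeded multi-start (default 32 starts, the first
at the all-ones nominal model, the rest log-uniform) trust-region least
squares; remaining starts are skipped once a start reaches an objective of
1e-10, since additional starts cannot improve a numerically exact fit.

With 17 parameters against five data points the fit is badly
over-parameterised — by design. The optimum is non-identifiable; the
package asserts and reports only the predicted fold changes, never the
recovered parameter values. Self-consistency (calibrating against the
model's own predictions) reaches objective < 1e-6, and the measured table
is fit to ~1e-17.

## Metabolic control analysis

Scaled concentration control coefficients `C_j^s = ∂ln S*_s/∂ln k_j` are
estimated by central differences in ln k: each rate constant is scaled by
(1+δ) and 1/(1+δ) (δ = 0.01 default) and the steady state re-solved from
the unperturbed state, which keeps the moiety totals fixed. The symmetric
geometric spacing matters: the naive (1+δ)/(1−δ) pair is asymmetric in
ln k and leaves a first-order error term that inflates the summation-
theorem residual from ~2×10⁻⁶ to ~1.5×10⁻⁴ at δ = 0.01. The observables
are the five luciferase species (the measured proxies of transcriptional
activity), not the active TF species. Reactions with zero steady-state
flux get coefficient 0 with a flag; failed perturbed solves become NaN
with a flag, never silent zeros. Exports include the raw matrix and a
per-column |C|/max|C| "fraction of maximum sensitivity" variant.

Two structural facts about the roster shape the rankings. First, because
only the reporter's decay reaction has coefficient exactly −1, the decay
row is always the column maximum, with transcription/basal splitting
(fold−1)/fold and 1/fold of the remaining unit. Second, PIP₂ synthesis and
BTK:PIP₃ association have *identical* control over the ATF2 reporter: at
steady state the free PIP₃ level is independent of the association rate
(binding and unbinding balance), so both rates act through the same
`1/(1+κ·PIP3)` factor. Similarly the ER Ca²⁺ release, reuptake, IP₃-decay
and PIP₂-synthesis coefficients for the Mef2 reporter coincide to within
finite-difference noise. Rankings are therefore reported with stable
roster-order tie-breaking, and assertions about rank positions use a 1e-4
relative tie tolerance.

## Dose-response and tissue EC50

The Hill model is the standard four-parameter form with the denominator
`EC50ⁿ + Lⁿ`, fit on the log10 EC50 scale by seeded multi-start
least squares (lmfit), reporting asymptotic standard errors. The
tissue-specific EC50 follows from occupancy matching: assuming the same
amount of bound receptor yields the half-maximal response in every tissue
(a deliberate simplification — the measured response is proximal to
binding, attenuating downstream amplification differences), solving
`R·L/(Kd+L) = EC50/(Kd+EC50)` for L gives
`EC50ᵢ = Kd·EC50/(R(Kd+EC50) − EC50)`. R is relative to the reference
cell-line lysate (R = 1). The closed form is verified against a numeric
root of the occupancy equation to 1e-10 relative. When
`R(Kd+EC50) ≤ EC50` the matched occupancy is unreachable at any
concentration and the package raises rather than extrapolating. Note one
labelling caveat inherited from the source data: the BO row of the
receptor table is labelled "skeletal muscle" in the measurement table but
glossed as bone by the tissue maps; the code keeps the code-to-bone
mapping and records the label verbatim.

## PBPK model

A standard perfusion-limited structure: venous pool → lungs → arterial
pool → 12 parallel tissue compartments, with spleen, small intestine and
colon draining through the portal vein into the liver (oral first pass).
Reference 70-kg human volumes and flows are embedded as a versioned
constants table (the receptor data are relative, so species choice only
scales the plumbing; flows are fractions of a 390 L/h cardiac output and
sum to it by construction). Partition coefficients are predicted from a
tissue-composition table in the Poulin–Theil style — lipid/water
partitioning from log P, with the pH-7.4 distribution coefficient
replacing P for adipose (ionisation correction for acids/bases). Hepatic
elimination is well-stirred (`CLint · fu` on the liver's plasma-equivalent
concentration); renal clearance acts on the kidney. Oral absorption is a
first-order gut-lumen depot with `ka = 2·Peff/r` over an effective
small-intestinal radius of 1.75 cm. Boluses are instantaneous state
additions and the linear system is integrated piecewise between dose
times; cumulative elimination is carried as a state so mass balance
(body + lumen + eliminated = administered) is checked to 0.1% of the dose
on every simulation. The kinetics are linear, so dose proportionality is
exact and oral AUC can never exceed IV AUC at equal dose.

**Response coupling.** Tissue responses evaluate the Hill curve (with the
occupancy-matched tissue EC50) against the tissue's plasma-equivalent
concentration `C_t/Kp_t` in mol/L. The default uses the *total*
plasma-equivalent concentration: the in vitro dose-response that anchors
the curve reports total applied ligand, and coupling on totals keeps the
in vitro and in vivo scales commensurate without a tissue-binding
correction for which no data exist in this workflow. The free-drug
convention (`fu·C_t/Kp_t`) is available as `basis="unbound"`; with a
highly bound compound it uniformly scales concentrations down by fu and
lowers all responses.

**Drug fixture.** The lisuride-like property set (MW 338.45, logP 2.57,
base pKa 7.86, fu 0.30, Peff 4×10⁻⁴ cm/s, CLint 250 L/h, renal 1 L/h) is
a synthetic fixture assembled once from typical published ranges for the
compound class; it is never asserted against measured data. The IV
regimen interprets a "25 µg/mL" dosing solution as a 1-mL bolus
(0.025 mg). With this fixture the oral 0.1 mg regimen takes the colon —
lowest tissue EC50 by virtue of the highest receptor expression — to
about 76% of its response span (29.8% vs the 36.55% plateau), above its
half-maximal point for ~4 h, longer than any other tissue, while IV
dosing reaches liver, brain and gut earlier than oral.

PK calibration fits {CLint, ka} to a venous concentration series by
least squares on log concentrations (seeded multi-start, bounds
CLint 1–10⁴ L/h, ka 0.05–20 h⁻¹); the fitted ka is folded back into the
effective permeability so the drug file round-trips.

## Synthetic data generators

The fixture generators emulate the three measured inputs: the assay table
(lognormal, mean-preserving, configurable CV around the measured fold
changes), dose-response points (nine half-log-spaced doses through the
reference Hill curve with Gaussian % noise), and a venous PK series (the
package's own PBPK forward model at the fixture truth with lognormal
noise — a stand-in for an external IV reference dataset, generated rather
than measured). Every file header records the seed and files regenerate
bit-identically. What passing tests show, therefore, is internal
consistency — round-trip recovery, statistical calibration of the noise
models, and the structural properties above — not agreement with any
external measurement beyond the embedded case-study tables.

## Numerical choices and problem sizes

* ODE tolerances rtol 1e-8 / atol 1e-12 (steady-state runs); PBPK at
  rtol 1e-10 for the 0.1% mass-balance margin.
* Steady-state horizon 10⁴ time units, Newton residual 1e-10 relative.
* MCA δ = 0.01 with a δ/2 convergence check (<1% relative or 1e-6
  absolute per entry).
* Stochastic/continuum consistency uses the H1 network token-scaled ×100
  (rate constants converted as k·scale^(1−order)), a 200-seed ensemble at
  t = 5, compared within 3 Monte-Carlo standard errors. At this scale the
  O(1/Ω) finite-size deviation between ensemble mean and ODE (~0.4%
  relative) is comparable to the ensemble standard error, which is the
  intended regime for the check.
* Monte-Carlo oracles run at 200 replicates (Hill-fit bias), 20
  replicates (PK clearance bias) and 1000 draws (fixture CV) — sizes
  chosen to keep the statistical assertions decisive at default suite
  runtimes of about a minute.

## Known limitations

* The signalling model is qualitative: all rates equal, no receptor
  desensitisation or internalisation, no transcription-to-protein delay;
  fold changes are matched at steady state, not at the 6-h assay
  endpoint, and no mapping from Petri-net time to wall-clock time is
  attempted.
* MCA rankings inherit the non-identifiability of the calibration:
  rank *structure* (which classes of reactions carry control) is robust;
  individual percentages are not, and the package does not report them as
  findings.
* The PBPK stage is perfusion-limited only — no permeability-limited
  tissues, enterohepatic recirculation, metabolites or population
  variability — and the drug fixture is synthetic, so tissue-response
  outputs are illustrative of the workflow, not predictions for a real
  compound.
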