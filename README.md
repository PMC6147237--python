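# receptox

Off-target receptor toxicity modelling: a combined signalling-network /
pharmacokinetic workbench for asking *"if a drug binds this receptor it was
never designed for, where in the body and when does that matter?"*

Many adverse drug reactions start with a molecular initiating event: the
compound activates a receptor off-target. `receptox` chains the three in
silico stages needed to turn a transcription-factor reporter readout of such
an event into a whole-body risk picture:

1. **Signalling model** (`receptox.network`, `receptox.h1`) — a stochastic
   Petri net / mass-action ODE model of the histamine H1 GPCR cascade, from
   ligand binding through the Gαq (PLCβ → IP₃/DAG → Ca²⁺, PKC) and Gβγ
   (AC → cAMP → PKA; PI3K → PIP₃ → BTK/Akt) arms to five luciferase
   reporters (NFAT, NF-κB, CREB, Mef2, ATF2). All rate constants are 1 in
   qualitative Petri-net time units; the model is parameterised by conserved
   moiety totals and the ligand dose.
2. **Calibration + metabolic control analysis** (`receptox.calibration`,
   `receptox.mca`) — fits the moiety totals and dose so the steady-state
   reporter fold changes match measured assay data, then computes scaled
   concentration control coefficients `C_j^s = ∂ln S*_s / ∂ln k_j` for every
   reaction to rank sensitive perturbation points upstream of each
   transcription factor.
3. **Tissue translation** (`receptox.pharmacology`, `receptox.pbpk`) — a
   four-parameter Hill dose-response
   `R(L) = Min + (Max−Min)·Lⁿ/(EC50ⁿ + Lⁿ)`, occupancy-matched
   tissue-specific EC50s `EC50ᵢ = Kd·EC50 / (Rᵢ(Kd+EC50) − EC50)` from
   relative receptor expression, and a perfusion-limited whole-body PBPK
   model (14 compartments, portal first pass, hepatic + renal clearance)
   that maps any dose regimen to per-tissue receptor-activation time
   courses.

The shipped case study is the H1 receptor with a lisuride-like partial
agonist (Max ≈ 36.6% of the full-agonist response); measured inputs (assay
fold changes, Hill/Kd parameters, tissue receptor table) are embedded in
`receptox.data`.

## Worked example

```python
from receptox import data, h1, mca
from receptox.calibration import CalibrationConfig, calibrate
from receptox.network import find_steady_state
from receptox.pbpk import DoseRegimen, simulate_pbpk, tissue_response_map

res = calibrate(data.table1_assay(), CalibrationConfig(seed=1))
print(f"objective: {res.objective:.2e}")
for f in h1.FACTORS:
    print(f"{f:5s} measured {res.observed[f]:.2f}  model {res.predicted[f]:.3f}")

net = h1.build_h1_network(res.spec)
ss = find_steady_state(net, h1.default_state(res.spec, stimulated=True, network=net))
C = mca.control_coefficients(net, ss, [res.spec.reporter_map[f] for f in h1.FACTORS])
for rid, frac in mca.rank_sensitive_reactions(C, "Luc_Mef2", exclude_direct=True)[:4]:
    print(f"  {rid:15s} {frac:.3f}")

oral = simulate_pbpk(data.lisuride_like_drug(), data.human_physiology(),
                     DoseRegimen("oral", 0.1), 24.0)
rmap = tissue_response_map(oral, data.table2_hill(), data.table2_binding(),
                           data.table3_receptor())
print("peak colon response: %.1f%% (Max = 36.55%%)" % rmap.responses["CO"].max())
```

prints

```
objective: 1.34e-17
NFAT  measured 1.97  model 1.970
NFkB  measured 2.18  model 2.180
CREB  measured 1.54  model 1.540
Mef2  measured 2.74  model 2.740
ATF2  measured 1.67  model 1.670
  mef2_deact      1.000
  mef2_act        1.000
  pip2_synthesis  0.983
  ip3_decay       0.983
peak colon response: 29.8% (Max = 36.55%)
```

The calibration reproduces all five measured fold changes essentially
exactly (the parameter set itself is non-identifiable; only the fold
changes are meaningful). The Mef2 ranking shows that, after the reporter's
own activation cycle, distant upstream reactions — PIP₂ synthesis, IP₃
turnover, ER calcium release — carry nearly the same control as the direct
ones, which is what makes them useful screening targets. In the PBPK stage
the colon, with the highest relative receptor expression (R = 25.9) and
hence the lowest tissue EC50 (≈1.8×10⁻¹⁰ mol/L), responds closest to the
partial-agonist plateau and stays elevated longest after an oral dose.

A command-line interface mirrors the library:

```bash
receptox --seed 1 --out-dir out pipeline          # fixtures → calibrate → MCA → Hill → PBPK
receptox --seed 1 --out-dir out calibrate         # single stages
receptox --out-dir out pbpk --route oral --dose-mg 0.1
```

Every run appends a record (seed, input hashes, outputs, version) to
`out/manifest.json`.

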