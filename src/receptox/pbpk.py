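"""Perfusion-limited whole-body PBPK model coupled to receptor responses.

Structure: venous pool → lungs → arterial pool → parallel organ
compartments, with splenic, small-intestinal and colonic venous outflow
routed through the portal vein into the liver (so orally absorbed drug is
subject to hepatic first pass). Each tissue is well stirred and
perfusion-limited with a predicted tissue:plasma partition coefficient Kp.
Elimination is hepatic (well-stirred, intrinsic clearance × fraction
unbound on the liver's plasma-equivalent concentration) plus renal
clearance on the kidney. Oral dosing fills a gut-lumen depot absorbed
first-order into the small-intestinal tissue with ka derived from the
effective permeability and small-intestinal geometry. The kinetics are
linear throughout, so dose proportionality holds exactly.

Tissue receptor-activation maps evaluate the Hill dose-response at each
tissue's occupancy-matched EC50 against that tissue's plasma-equivalent
drug concentration over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .pharmacology import hill_response, tissue_ec50

__all__ = [
    "DrugProperties",
    "Physiology",
    "DoseRegimen",
    "PBPKResult",
    "ResponseMap",
    "PBPKError",
    "predict_partition_coefficients",
    "simulate_pbpk",
    "tissue_response_map",
    "calibrate_pk",
    "TISSUE_CODE_TO_COMPARTMENT",
]


class PBPKError(RuntimeError):
    pass


#: organ compartments perfused in parallel from the arterial pool
ORGANS = ("lung", "heart", "kidney", "liver", "spleen", "small_intestine",
          "colon", "brain", "bone", "muscle", "adipose", "rest")
PORTAL = ("spleen", "small_intestine", "colon")
_STATE = ("venous", "arterial") + ORGANS + ("gut_lumen", "eliminated")

#: reported tissue codes → PBPK compartments (code BO is mapped to the bone
#: compartment; see the receptor-table docstring for the labelling caveat)
TISSUE_CODE_TO_COMPARTMENT = {
    "HE": "heart", "LU": "lung", "KI": "kidney", "LI": "liver",
    "BO": "bone", "BR": "brain", "SP": "spleen", "SI": "small_intestine",
    "CO": "colon",
}

_SI_RADIUS_CM = 1.75  # effective small-intestinal radius for ka = 2*Peff/r


@dataclass
class DrugProperties:
    """Physicochemical and disposition properties of the compound."""

    molecular_weight: float          # g/mol
    log_p: float                     # octanol:water
    pka: float
    ionization_class: str            # neutral | acid | base
    solubility: float                # mg/mL
    effective_permeability: float    # units of 1e-4 cm/s
    fraction_unbound: float          # (0, 1]
    intrinsic_clearance: float       # L/h
    renal_clearance: float = 0.0     # L/h
    blood_plasma_ratio: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.ionization_class not in ("neutral", "acid", "base"):
            raise ValueError("ionization_class must be neutral, acid or base")
        if not 0 < self.fraction_unbound <= 1:
            raise ValueError("fraction_unbound must be in (0, 1]")
        for f in ("molecular_weight", "solubility", "effective_permeability",
                  "blood_plasma_ratio"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.intrinsic_clearance < 0 or self.renal_clearance < 0:
            raise ValueError("clearances must be nonnegative")

    @property
    def ka(self):
        """First-order oral absorption rate (1/h) from effective
        permeability: ka = 2*Peff/r over the small-intestinal radius."""
        peff_cm_h = self.effective_permeability * 1e-4 * 3600.0
        return 2.0 * peff_cm_h / _SI_RADIUS_CM

    def to_yaml(self, path):
        doc = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Physiology:
    """Compartment volumes (L) and blood flows (L/h); flows must sum to the
    cardiac output within 1% and portal flows route into the liver inlet."""

    volumes: dict
    flows: dict
    cardiac_output: float
    body_weight: float

    def __post_init__(self):
        missing_v = set(ORGANS) | {"venous", "arterial"}
        missing_v -= set(self.volumes)
        if missing_v:
            raise ValueError(f"missing volumes for {sorted(missing_v)}")
        organ_flows = [f for k, f in self.flows.items() if k != "lung"]
        if abs(sum(organ_flows) - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ValueError("organ flows must sum to cardiac output within 1%")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("volumes must be positive")

    @property
    def liver_inflow(self):
        return self.flows["liver"] + sum(self.flows[p] for p in PORTAL)


@dataclass
class DoseRegimen:
    route: str                      # "iv" | "oral"
    amount_mg: float                # per bolus
    times_h: tuple = (0.0,)

    def __post_init__(self):
        self.route = self.route.lower()
        if self.route not in ("iv", "oral"):
            raise ValueError("route must be 'iv' or 'oral'")
        if self.amount_mg < 0:
            raise ValueError("dose amount must be nonnegative")
        if any(b < a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("bolus times must be nondecreasing")

    @property
    def total_dose(self):
        return self.amount_mg * len(self.times_h)


@dataclass
class PBPKResult:
    """Tissue drug concentrations over time plus bookkeeping needed by the
    response map (partition coefficients, drug, dose)."""

    times: np.ndarray               # h
    concentrations: pd.DataFrame    # time × compartment, mg/L
    eliminated: np.ndarray          # cumulative, mg
    gut_lumen: np.ndarray           # mg remaining unabsorbed
    dose_admin: float               # mg
    kps: dict
    drug: DrugProperties
    regimen: DoseRegimen
    physiology: Physiology

    def mass_balance_error(self):
        """Max relative deviation of (body + lumen + eliminated) from the
        administered dose, as a fraction of the dose."""
        vols = self.physiology.volumes
        body = sum(self.concentrations[c].to_numpy() * vols[c]
                   for c in self.concentrations.columns)
        total = body + self.eliminated + self.gut_lumen
        if self.dose_admin == 0:
            return float(np.max(np.abs(total)))
        # only after the first bolus has entered
        t0 = min(self.regimen.times_h)
        mask = self.times >= t0
        admin = np.array([self.regimen.amount_mg *
                          sum(1 for tb in self.regimen.times_h if tb <= t)
                          for t in self.times])
        err = np.abs(total[mask] - admin[mask]) / self.dose_admin
        return float(err.max())

    def auc(self, compartment="venous"):
        return float(np.trapezoid(self.concentrations[compartment].to_numpy(),
                                  self.times))

    def to_csv(self, path):
        df = self.concentrations.copy()
        df.insert(0, "time_h", self.times)
        df.to_csv(path, index=False)


@dataclass
class ResponseMap:
    """Per-tissue % receptor-activation response over time."""

    times: np.ndarray
    responses: pd.DataFrame         # time × tissue code, % response
    basis: str = "total"

    def to_csv(self, path):
        df = self.responses.copy()
        df.insert(0, "time_h", self.times)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# partition coefficients
# ---------------------------------------------------------------------------


def _log_d(drug, ph=7.4):
    if drug.ionization_class == "base":
        return drug.log_p - math.log10(1.0 + 10.0 ** (drug.pka - ph))
    if drug.ionization_class == "acid":
        return drug.log_p - math.log10(1.0 + 10.0 ** (ph - drug.pka))
    return drug.log_p


def predict_partition_coefficients(drug, composition=None):
    """Tissue:plasma partition coefficients from tissue composition.

    Lipid/water partitioning in the Poulin-Theil style: each tissue's
    affinity is P*(f_nl + 0.3 f_pl) + (f_w + 0.7 f_pl), normalised by the
    same expression for plasma; for adipose the octanol:water P is replaced
    by the pH-7.4 distribution coefficient D (the ionised fraction of an
    acid/base does not partition into neutral storage lipid). All Kp are
    positive; identical composition rows give identical Kp.
    """
    from .data import TISSUE_COMPOSITION

    comp = composition or TISSUE_COMPOSITION
    missing = set(ORGANS) - set(comp)
    if missing:
        raise PBPKError(f"missing tissue composition for {sorted(missing)}")
    p = 10.0 ** drug.log_p
    d = 10.0 ** _log_d(drug)

    def affinity(row, part):
        return part * (row["nlipid"] + 0.3 * row["plipid"]) + \
            (row["water"] + 0.7 * row["plipid"])

    plasma = comp["plasma"]
    kps = {}
    for t in ORGANS:
        part = d if t == "adipose" else p
        kps[t] = affinity(comp[t], part) / affinity(plasma, part)
    return kps


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _build_matrix(drug, phys, kps, ka):
    """Linear ODE system matrix over amounts (mg) in `_STATE` order."""
    n = len(_STATE)
    ix = {c: i for i, c in enumerate(_STATE)}
    V = phys.volumes
    Q = phys.flows
    bp = drug.blood_plasma_ratio
    M = np.zeros((n, n))
    co = phys.cardiac_output

    def out_conc(c):  # tissue venous-blood concentration per unit amount
        return bp / (kps[c] * V[c])

    # venous pool: collects non-portal organs + liver outflow, feeds lungs
    M[ix["venous"], ix["venous"]] -= co / V["venous"]
    M[ix["lung"], ix["venous"]] += co / V["venous"]
    # lungs -> arterial
    M[ix["lung"], ix["lung"]] -= co * out_conc("lung")
    M[ix["arterial"], ix["lung"]] += co * out_conc("lung")
    # arterial -> organs
    for t in ORGANS:
        if t == "lung":
            continue
        M[ix["arterial"], ix["arterial"]] -= Q[t] / V["arterial"]
        M[ix[t], ix["arterial"]] += Q[t] / V["arterial"]
    # organ outflows
    for t in ORGANS:
        if t in ("lung", "liver"):
            continue
        dest = "liver" if t in PORTAL else "venous"
        M[ix[t], ix[t]] -= Q[t] * out_conc(t)
        M[ix[dest], ix[t]] += Q[t] * out_conc(t)
    # liver outflow at total inlet flow
    q_li = phys.liver_inflow
    M[ix["liver"], ix["liver"]] -= q_li * out_conc("liver")
    M[ix["venous"], ix["liver"]] += q_li * out_conc("liver")
    # elimination: hepatic intrinsic (on unbound liver plasma) + renal
    cl_h = drug.intrinsic_clearance * drug.fraction_unbound / (kps["liver"] * V["liver"])
    M[ix["liver"], ix["liver"]] -= cl_h
    M[ix["eliminated"], ix["liver"]] += cl_h
    cl_r = drug.renal_clearance * drug.fraction_unbound / (kps["kidney"] * V["kidney"])
    M[ix["kidney"], ix["kidney"]] -= cl_r
    M[ix["eliminated"], ix["kidney"]] += cl_r
    # gut lumen -> small-intestinal tissue
    M[ix["gut_lumen"], ix["gut_lumen"]] -= ka
    M[ix["small_intestine"], ix["gut_lumen"]] += ka
    return M, ix


def simulate_pbpk(drug, phys, regimen, t_end, n_points=400, kps=None,
                  ka=None, rtol=1e-10, atol=1e-12, extra_times=None):
    """Simulate tissue concentration time courses for a dose regimen.

    Bolus doses are applied as instantaneous amount additions (venous pool
    for IV, gut lumen for oral) and the linear system is integrated
    piecewise between bolus times. Mass balance (amount in body + lumen +
    eliminated = administered) holds within 0.1% of the dose and is checked.
    """
    if t_end <= 0:
        raise PBPKError("t_end must be positive")
    kps = kps or predict_partition_coefficients(drug)
    ka_eff = drug.ka if ka is None else float(ka)
    M, ix = _build_matrix(drug, phys, kps, ka_eff)
    t_eval = np.unique(np.concatenate([
        np.linspace(0.0, t_end, n_points),
        np.asarray(extra_times, dtype=float) if extra_times is not None else [],
        [t for t in regimen.times_h if t <= t_end]]))
    t_eval = t_eval[t_eval <= t_end]
    y = np.zeros(len(_STATE))
    depot = ix["venous"] if regimen.route == "iv" else ix["gut_lumen"]
    out = np.zeros((t_eval.size, len(_STATE)))
    boluses = [t for t in regimen.times_h if t <= t_end]
    n_boluses = len(boluses)
    bolus_at = {}
    for t in boluses:
        bolus_at[t] = bolus_at.get(t, 0) + 1
    segments = sorted({0.0, t_end} | set(boluses))
    ti = 0
    for si, a in enumerate(segments):
        if a in bolus_at:
            y[depot] += regimen.amount_mg * bolus_at[a]
        # record grid points at (or before) the segment start
        while ti < t_eval.size and t_eval[ti] <= a:
            out[ti] = y
            ti += 1
        if si + 1 == len(segments):
            break
        b = segments[si + 1]
        # integrate over (a, b]; the point at b itself is recorded by the
        # next segment start so that bolus additions at b are included
        seg_t = np.append(t_eval[(t_eval > a) & (t_eval < b)], b)
        sol = solve_ivp(lambda t, x: M @ x, (a, b), y, t_eval=seg_t,
                        method="LSODA", rtol=rtol, atol=atol,
                        jac=lambda t, x: M)
        if not sol.success:
            raise PBPKError(f"PBPK integration failed: {sol.message}")
        for k in range(seg_t.size - 1):
            out[ti] = sol.y[:, k]
            ti += 1
        y = sol.y[:, -1]
    while ti < t_eval.size:
        out[ti] = y
        ti += 1
    vols = phys.volumes
    conc = {c: out[:, ix[c]] / vols[c] for c in ("venous", "arterial") + ORGANS}
    res = PBPKResult(times=t_eval,
                     concentrations=pd.DataFrame(conc),
                     eliminated=out[:, ix["eliminated"]],
                     gut_lumen=out[:, ix["gut_lumen"]],
                     dose_admin=regimen.amount_mg * len(boluses),
                     kps=kps, drug=drug, regimen=regimen, physiology=phys)
    if res.dose_admin > 0 and res.mass_balance_error() > 1e-3:
        raise PBPKError(
            f"mass balance violated: {res.mass_balance_error():.2e} of dose")
    return res


# ---------------------------------------------------------------------------
# receptor response map
# ---------------------------------------------------------------------------


def tissue_response_map(result, hill, binding, table, basis="total"):
    """Receptor-activation time course per tissue.

    For each reported tissue code the local Hill curve (reference
    parameters with EC50 replaced by the occupancy-matched tissue EC50) is
    evaluated against the tissue's plasma-equivalent drug concentration in
    mol/L: ``C_t/Kp_t`` for ``basis="total"`` (default; commensurate with
    the total-medium concentrations of the in vitro dose-response assay) or
    ``fu * C_t/Kp_t`` for ``basis="unbound"`` (free-drug hypothesis).
    Unreachable-response tissues propagate their error.
    """
    if basis not in ("total", "unbound"):
        raise ValueError("basis must be 'total' or 'unbound'")
    drug = result.drug
    factor = drug.fraction_unbound if basis == "unbound" else 1.0
    cols = {}
    for code in table.codes:
        comp = TISSUE_CODE_TO_COMPARTMENT[code]
        ec50_i = tissue_ec50(binding, hill, table.abundance(code), tissue=code)
        local = replace(hill, log_ec50=math.log10(ec50_i), stderr=None)
        c_molar = (result.concentrations[comp].to_numpy() / result.kps[comp]
                   * factor) / drug.molecular_weight * 1e-3
        cols[code] = hill_response(c_molar, local)
    return ResponseMap(times=result.times, responses=pd.DataFrame(cols), basis=basis)


# ---------------------------------------------------------------------------
# PK calibration
# ---------------------------------------------------------------------------


@dataclass
class PKCalibrationResult:
    drug: DrugProperties            # fitted copy
    ka: float
    objective: float                # sum of squared log-residuals
    residuals: np.ndarray
    n_starts_run: int
    seed: int
    converged: bool


def calibrate_pk(times_h, conc_mg_per_l, drug, phys, regimen,
                 bounds=((1.0, 1e4), (0.05, 20.0)), n_starts=6, seed=0,
                 t_pad=1.05):
    """Fit {intrinsic clearance, ka} to an observed venous concentration
    series by weighted least squares on log concentrations.

    Seeded multi-start (log-uniform within bounds). Returns the fitted
    :class:`DrugProperties` copy (with the effective permeability
    back-computed so the fitted ka round-trips) plus diagnostics.
    """
    times = np.asarray(times_h, dtype=float)
    obs = np.asarray(conc_mg_per_l, dtype=float)
    if times.size < 6:
        raise PBPKError("need at least 6 time points")
    keep = obs > 0
    if not keep.any():
        raise PBPKError("all observations are zero/censored; nothing to fit")
    times_f, obs_f = times[keep], np.log(obs[keep])
    kps = predict_partition_coefficients(drug)
    t_end = float(times.max()) * t_pad

    def residuals(theta):
        cl, ka = 10.0 ** theta
        d = replace(drug, intrinsic_clearance=cl)
        try:
            sim = simulate_pbpk(d, phys, regimen, t_end, kps=kps, ka=ka,
                                n_points=50, extra_times=times_f)
        except PBPKError:
            return np.full(times_f.size, 1e3)
        pred = np.interp(times_f, sim.times, sim.concentrations["venous"].to_numpy())
        pred = np.maximum(pred, 1e-300)
        return np.log(pred) - obs_f

    lb = np.log10([bounds[0][0], bounds[1][0]])
    ub = np.log10([bounds[0][1], bounds[1][1]])
    rng = np.random.default_rng(seed)
    starts = [np.array([math.log10(max(drug.intrinsic_clearance, bounds[0][0])),
                        math.log10(min(max(drug.ka, bounds[1][0]), bounds[1][1]))])]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(lb, ub))
    best = None
    n_run = 0
    for theta0 in starts:
        n_run += 1
        sol = least_squares(residuals, np.clip(theta0, lb, ub), bounds=(lb, ub),
                            method="trf")
        cost = float(np.sum(sol.fun ** 2))
        if np.isfinite(cost) and (best is None or cost < best[0]):
            best = (cost, sol.x, sol.status)
        if best and best[0] < 1e-12:
            break
    if best is None:
        raise PBPKError("PK calibration failed from every start")
    cost, theta, status = best
    cl, ka = 10.0 ** theta
    peff = ka * _SI_RADIUS_CM / 2.0 / 3600.0 / 1e-4
    fitted = replace(drug, intrinsic_clearance=float(cl),
                     effective_permeability=float(peff))
    return PKCalibrationResult(drug=fitted, ka=float(ka), objective=cost,
                               residuals=residuals(theta), n_starts_run=n_run,
                               seed=seed, converged=bool(status > 0))
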