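"""Calibration of the H1 model against transcription-factor reporter assays.

The measured quantity is the fold change in relative luciferase units per
transcription factor: stimulated over pre-stimulus reporter signal at steady
state. The fitted parameters are the conserved moiety totals and the ligand
dose; all rate constants stay at 1. Because the system is large and the data
are five numbers, the optimum is non-identifiable — only the predicted fold
changes (not the recovered parameter values) are meaningful, and the suite
asserts exactly that.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import h1
from .network import SteadyStateConfig, SteadyStateError, find_steady_state

__all__ = [
    "AssayDataset",
    "CalibrationConfig",
    "CalibrationResult",
    "CalibrationError",
    "reporter_fold_changes",
    "predict_fold_changes",
    "calibrate",
]


class CalibrationError(RuntimeError):
    """All optimizer starts failed; carries the best partial result."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


_ALIASES = {
    "nfat": "NFAT", "nf-kb": "NFkB", "nfkb": "NFkB", "nf-κb": "NFkB",
    "creb": "CREB", "mef2": "Mef2", "atf2": "ATF2",
}


def canonical_factor(name):
    key = str(name).strip().lower().replace("κ", "k")
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(f"unknown transcription factor name {name!r}")


@dataclass
class AssayDataset:
    """Per-factor fold changes with uncertainties (one record per factor)."""

    records: list  # of (factor, fold_change, sd)

    def __post_init__(self):
        recs = [(canonical_factor(f), float(fc), float(sd)) for f, fc, sd in self.records]
        names = [r[0] for r in recs]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if any(fc <= 0 for _, fc, _ in recs):
            raise ValueError("fold changes must be positive")
        if any(sd < 0 for _, _, sd in recs):
            raise ValueError("SDs must be nonnegative")
        self.records = recs

    def as_dict(self):
        return {f: fc for f, fc, _ in self.records}

    def sds(self):
        return {f: sd for f, _, sd in self.records}

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, comment="#")
        return cls(list(df[["factor", "fold_change", "sd"]].itertuples(index=False, name=None)))

    def to_csv(self, path, header_comment=None):
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("factor,fold_change,sd\n")
            for f, fc, sd in self.records:
                fh.write(f"{f},{fc:.10g},{sd:.10g}\n")


def reporter_fold_changes(network, state_on, state_off, reporter_map, ss_config=None):
    """Generic steady-state fold change per reporter: stimulated over basal.

    Solves the steady state from each initial condition and returns
    ``{factor: Luc_on / Luc_off}``. Steady-state failures propagate with the
    offending configuration named.
    """
    try:
        ss_on = find_steady_state(network, state_on, ss_config)
    except SteadyStateError as e:
        raise SteadyStateError(f"stimulated steady state failed: {e}",
                               residual=e.residual, state=e.state) from e
    try:
        ss_off = find_steady_state(network, state_off, ss_config)
    except SteadyStateError as e:
        raise SteadyStateError(f"unstimulated steady state failed: {e}",
                               residual=e.residual, state=e.state) from e
    out = {}
    for factor, luc in reporter_map.items():
        i = network.species_index[luc]
        out[factor] = float(ss_on.amounts[i] / ss_off.amounts[i])
    return out


def predict_fold_changes(spec, ss_config=None, network=None):
    """Steady-state reporter fold changes of the H1 model for a spec.

    The stimulated condition clamps the ligand at the dose (sustained
    stimulation); the unstimulated condition has zero ligand.
    """
    spec.validate()
    net = network or h1.build_h1_network(spec)
    on = h1.default_state(spec, stimulated=True, network=net)
    off = h1.default_state(spec, stimulated=False, network=net)
    return reporter_fold_changes(net, on, off, spec.reporter_map, ss_config)


@dataclass
class CalibrationConfig:
    """Multi-start least-squares settings.

    Residuals are relative by default, ``(pred - obs)/obs``; SD weighting
    (``(pred - obs)/sd``) is available but off because the measured SDs span
    two orders of magnitude and would effectively discard the noisiest
    factor. Starts sample moiety totals and dose log-uniformly within
    ``bounds``; the first start is the all-ones nominal model.
    """

    n_starts: int = 32
    bounds: tuple = (1e-2, 1e3)
    seed: int = 0
    sd_weighting: bool = False
    stop_objective: float = 1e-10  # skip remaining starts once this is reached
    max_nfev: int = 400
    ss_config: SteadyStateConfig = field(default_factory=SteadyStateConfig)


@dataclass
class CalibrationResult:
    spec: h1.PathwaySpec            # fitted moiety totals and dose
    predicted: dict                 # factor -> fold change at the optimum
    objective: float                # sum of squared residuals
    observed: dict
    seed: int
    n_starts_run: int
    converged: bool
    start_diagnostics: list         # per start: dict(objective, nfev, status)

    @property
    def moiety_totals(self):
        return dict(self.spec.moiety_totals)

    @property
    def dose(self):
        return float(self.spec.dose)

    def to_json(self, path):
        doc = {"moiety_totals": {k: float(v) for k, v in self.spec.moiety_totals.items()},
               "dose": float(self.spec.dose),
               "basal_rate": float(self.spec.basal_rate),
               "predicted_fold_changes": {k: float(v) for k, v in self.predicted.items()},
               "observed_fold_changes": {k: float(v) for k, v in self.observed.items()},
               "objective": float(self.objective), "seed": int(self.seed),
               "n_starts_run": int(self.n_starts_run), "converged": bool(self.converged),
               "start_diagnostics": self.start_diagnostics}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            doc = json.load(fh)
        spec = h1.PathwaySpec(moiety_totals=doc["moiety_totals"], dose=doc["dose"],
                              basal_rate=doc.get("basal_rate", 0.01))
        return cls(spec=spec, predicted=doc["predicted_fold_changes"],
                   objective=doc["objective"], observed=doc["observed_fold_changes"],
                   seed=doc["seed"], n_starts_run=doc["n_starts_run"],
                   converged=doc["converged"],
                   start_diagnostics=doc.get("start_diagnostics", []))


_PARAM_ORDER = tuple(h1.MOIETY_NAMES) + ("dose",)


def _theta_to_spec(theta, base_spec):
    vals = 10.0 ** np.asarray(theta, dtype=float)
    totals = {name: float(v) for name, v in zip(h1.MOIETY_NAMES, vals)}
    return base_spec.replace(moiety_totals=totals, dose=float(vals[-1]))


def calibrate(data, config=None, base_spec=None):
    """Fit moiety totals and dose to an assay dataset.

    Seeded multi-start trust-region least squares in log10 parameter space.
    Returns the best :class:`CalibrationResult`; raises
    :class:`CalibrationError` carrying the best partial result if every
    start fails to produce a finite objective.
    """
    cfg = config or CalibrationConfig()
    base_spec = base_spec or h1.PathwaySpec()
    obs = data.as_dict()
    missing = set(h1.FACTORS) - set(obs)
    if missing:
        raise ValueError(f"assay data must cover all five reporters; missing {sorted(missing)}")
    sds = data.sds()
    if cfg.sd_weighting and any(sds[f] <= 0 for f in h1.FACTORS):
        raise ValueError("SD weighting requires positive SDs")
    lo, hi = cfg.bounds
    if lo <= 0 or hi <= lo:
        raise ValueError("bounds must be positive with hi > lo")
    net = h1.build_h1_network(base_spec)  # structure reused; amounts vary per eval
    y = np.array([obs[f] for f in h1.FACTORS])
    w = np.array([sds[f] if cfg.sd_weighting else obs[f] for f in h1.FACTORS])

    def residuals(theta):
        spec = _theta_to_spec(theta, base_spec)
        try:
            pred = predict_fold_changes(spec, cfg.ss_config, network=net)
        except SteadyStateError:
            return np.full(y.size, 1e3)
        p = np.array([pred[f] for f in h1.FACTORS])
        return (p - y) / w

    rng = np.random.default_rng(cfg.seed)
    llo, lhi = np.log10(lo), np.log10(hi)
    starts = [np.zeros(len(_PARAM_ORDER))]
    starts[0][:] = np.clip(0.0, llo, lhi)
    for _ in range(cfg.n_starts - 1):
        starts.append(rng.uniform(llo, lhi, size=len(_PARAM_ORDER)))

    best = None
    diags = []
    n_run = 0
    for theta0 in starts:
        n_run += 1
        try:
            sol = least_squares(residuals, theta0, bounds=(llo, lhi),
                                method="trf", max_nfev=cfg.max_nfev)
            cost = float(np.sum(sol.fun ** 2))
            diags.append({"objective": cost, "nfev": int(sol.nfev), "status": int(sol.status)})
            if np.isfinite(cost) and (best is None or cost < best[0]):
                best = (cost, sol.x, sol.status)
        except Exception as e:  # noqa: BLE001 - per-start failure is diagnostic data
            diags.append({"objective": float("inf"), "nfev": 0, "status": f"error: {e}"})
        if best is not None and best[0] <= cfg.stop_objective:
            break

    if best is None or not np.isfinite(best[0]):
        raise CalibrationError("all optimizer starts failed",
                               best=diags)
    cost, theta, status = best
    spec = _theta_to_spec(theta, base_spec)
    predicted = predict_fold_changes(spec, cfg.ss_config, network=net)
    return CalibrationResult(spec=spec, predicted=predicted, objective=cost,
                             observed=obs, seed=cfg.seed, n_starts_run=n_run,
                             converged=bool(status > 0), start_diagnostics=diags)
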