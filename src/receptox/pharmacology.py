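"""Receptor pharmacology: Hill dose-response and tissue-specific EC50 scaling.

The dose-response model is the standard four-parameter Hill curve

    Response(L) = Min + (Max - Min) * L^n / (EC50^n + L^n)

with the response in percent of the reference maximum and ligand
concentration L in mol/L. A partial agonist plateaus below 100% (for
lisuride at H1, Max ≈ 36.6%).

Tissue-specific EC50 values follow from occupancy matching: assuming the
same amount of bound receptor produces a half-maximal response in every
tissue, a tissue with relative receptor abundance R reaches that bound
amount at

    EC50_i = Kd * EC50 / (R * (Kd + EC50) - EC50),

the solution of R * L/(Kd + L) = EC50/(Kd + EC50). Higher receptor
expression therefore lowers the effective EC50; the precondition
R*(Kd+EC50) > EC50 guards the case where the matched occupancy is
unreachable at any concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "HillParams",
    "BindingParams",
    "TissueReceptorTable",
    "DoseResponseError",
    "ResponseUnreachableError",
    "hill_response",
    "fit_hill",
    "tissue_ec50",
]


class DoseResponseError(RuntimeError):
    """Dose-response fitting failed or the data are degenerate."""


class ResponseUnreachableError(ValueError):
    """Receptor expression too low to reach the matched occupancy."""


@dataclass
class HillParams:
    """Four-parameter Hill curve: Min/Max in % response, log10 EC50 in
    mol/L, Hill coefficient n (dimensionless)."""

    min_pct: float
    max_pct: float
    log_ec50: float
    n: float
    stderr: dict | None = None

    def __post_init__(self):
        if not self.max_pct > self.min_pct:
            raise ValueError("Max must exceed Min")
        if not self.n > 0:
            raise ValueError("Hill coefficient must be positive")

    @property
    def ec50(self):
        return 10.0 ** self.log_ec50


@dataclass
class BindingParams:
    """Ligand-receptor dissociation equilibrium constant, mol/L."""

    kd: float

    def __post_init__(self):
        if not self.kd > 0:
            raise ValueError("Kd must be positive")


@dataclass
class TissueReceptorTable:
    """Relative receptor abundance per tissue, normalised to the reference
    cell line (R = 1)."""

    records: list  # of (code, name, R)

    def __post_init__(self):
        codes = [c for c, _, _ in self.records]
        if len(set(codes)) != len(codes):
            raise ValueError("tissue codes must be unique")
        if any(r <= 0 for _, _, r in self.records):
            raise ValueError("receptor abundances must be positive")

    def abundance(self, code):
        for c, _, r in self.records:
            if c == code:
                return float(r)
        raise KeyError(f"unknown tissue code {code!r}")

    @property
    def codes(self):
        return [c for c, _, _ in self.records]

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, comment="#")
        return cls(list(df[["code", "name", "R"]].itertuples(index=False, name=None)))

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("code,name,R\n")
            for c, n, r in self.records:
                fh.write(f"{c},{n},{r}\n")


def hill_response(L, params):
    """Percent response at ligand concentration(s) ``L`` (mol/L).

    Monotone nondecreasing in L and bounded in [Min, Max]; L = 0 returns
    Min exactly and L = EC50 returns (Min+Max)/2 for any n.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be nonnegative")
    ec50 = params.ec50
    with np.errstate(divide="ignore"):
        # (L/EC50)^n form is stable for very small L
        ratio = (L / ec50) ** params.n
    frac = ratio / (1.0 + ratio)
    frac = np.where(L == 0, 0.0, frac)
    out = params.min_pct + (params.max_pct - params.min_pct) * frac
    return float(out) if out.ndim == 0 else out


def fit_hill(doses, responses, n_starts=8, seed=0):
    """Least-squares fit of the four-parameter Hill curve.

    Fits on the log10 EC50 scale with seeded multi-start initialisation and
    returns :class:`HillParams` with asymptotic standard errors in
    ``stderr``. Requires at least five dose points spanning the transition;
    flat responses raise :class:`DoseResponseError`.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size != responses.size:
        raise ValueError("doses and responses must have equal length")
    if doses.size < 5:
        raise DoseResponseError("need at least 5 dose points spanning the transition")
    if np.ptp(responses) < 1e-9:
        raise DoseResponseError("responses are flat; Hill parameters are degenerate")
    pos = doses > 0
    if pos.sum() < 4:
        raise DoseResponseError("need at least 4 positive doses")

    def model(x, min_pct, max_pct, log_ec50, n):
        ratio = np.where(x > 0, (x / 10.0 ** log_ec50) ** n, 0.0)
        return min_pct + (max_pct - min_pct) * ratio / (1.0 + ratio)

    gm = lmfit.Model(model)
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(doses[pos].min()), np.log10(doses[pos].max())
    guesses = [0.5 * (lo + hi)] + list(rng.uniform(lo, hi, size=max(0, n_starts - 1)))
    best = None
    for g in guesses:
        params = gm.make_params(
            min_pct=dict(value=float(responses.min()), min=-50, max=150),
            max_pct=dict(value=float(responses.max()), min=-50, max=200),
            log_ec50=dict(value=float(g), min=lo - 4, max=hi + 4),
            n=dict(value=1.0, min=1e-3, max=10.0))
        try:
            res = gm.fit(responses, params, x=doses)
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise DoseResponseError("Hill fit did not converge from any start")
    p = best.params
    if not p["max_pct"].value > p["min_pct"].value:
        raise DoseResponseError("degenerate fit: Max <= Min")
    stderr = {k: (p[k].stderr if p[k].stderr is not None else float("nan"))
              for k in ("min_pct", "max_pct", "log_ec50", "n")}
    return HillParams(min_pct=p["min_pct"].value, max_pct=p["max_pct"].value,
                      log_ec50=p["log_ec50"].value, n=p["n"].value, stderr=stderr)


def tissue_ec50(binding, params, R, tissue=None):
    """Occupancy-matched tissue EC50 (mol/L) for relative abundance ``R``.

    ``R = 1`` returns the reference EC50 exactly; the value is strictly
    decreasing in R. Raises :class:`ResponseUnreachableError` (naming the
    tissue when given) if R is too small for the matched occupancy to be
    reachable.
    """
    if R <= 0:
        raise ValueError("receptor abundance must be positive")
    kd, ec50 = binding.kd, params.ec50
    denom = R * (kd + ec50) - ec50
    if denom <= 0:
        label = f" in tissue {tissue!r}" if tissue else ""
        raise ResponseUnreachableError(
            f"half-maximal receptor occupancy unreachable{label}: "
            f"R*(Kd+EC50) = {R * (kd + ec50):.3e} <= EC50 = {ec50:.3e}")
    return kd * ec50 / denom


def tissue_ec50_table(binding, params, table):
    """``{tissue code: EC50_i}`` over a :class:`TissueReceptorTable`."""
    return {c: tissue_ec50(binding, params, r, tissue=c) for c, _, r in table.records}
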