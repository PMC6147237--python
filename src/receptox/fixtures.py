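"""Seeded synthetic-data generators for every pipeline input.

Each generator draws around a configured "truth" — by default the measured
case-study values (assay fold changes, dose-response parameters) or the
lisuride-like drug fixture (venous PK) — with a configurable noise level,
and writes a plain CSV whose header comment records the seed so every file
is regenerable bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as _data
from .calibration import AssayDataset
from .pbpk import DoseRegimen, simulate_pbpk
from .pharmacology import hill_response

__all__ = [
    "FixtureConfig",
    "generate_assay_fixture",
    "generate_doseresponse_fixture",
    "generate_pk_fixture",
]


@dataclass
class FixtureConfig:
    """Seed, noise levels and sample sizes for the generators.

    ``assay_cv`` is the lognormal coefficient of variation of the fold
    changes; ``dr_sigma_pct`` the Gaussian response noise (% response) on
    the dose-response points; ``pk_cv`` the lognormal noise on venous
    concentrations. Truth values default to the case-study tables.
    """

    seed: int = 0
    assay_cv: float = 0.0
    assay_truth: dict | None = None
    dr_sigma_pct: float = 0.0
    dr_n_doses: int = 9
    pk_cv: float = 0.0
    pk_times_h: tuple = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    pk_dose_mg: float = 0.025
    pk_route: str = "iv"


def _lognormal_around(rng, truth, cv, size=None):
    """Mean-preserving lognormal draws: E[X] = truth, CV[X] = cv."""
    if cv == 0:
        return np.broadcast_to(np.asarray(truth, dtype=float), np.shape(truth) if size is None else size).copy()
    sigma2 = np.log1p(cv ** 2)
    z = rng.standard_normal(size if size is not None else np.shape(truth))
    return np.asarray(truth) * np.exp(np.sqrt(sigma2) * z - sigma2 / 2.0)


def generate_assay_fixture(cfg, path=None):
    """Synthetic transcription-factor assay table (factor, fold_change, sd).

    Fold changes are drawn lognormally (mean-preserving) around the truth;
    the written ``sd`` column is the implied lognormal SD truth*cv.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = cfg.assay_truth or _data.table1_assay().as_dict()
    factors = list(truth)
    fcs = _lognormal_around(rng, [truth[f] for f in factors], cfg.assay_cv)
    ds = AssayDataset([(f, float(fc), float(truth[f] * cfg.assay_cv))
                       for f, fc in zip(factors, fcs)])
    if path is not None:
        ds.to_csv(path, header_comment=f"seed={cfg.seed} cv={cfg.assay_cv}")
    return ds


def generate_doseresponse_fixture(cfg, path=None, hill=None):
    """Synthetic dose-response points: half-log-spaced doses around the
    reference EC50 pushed through the Hill curve plus Gaussian noise."""
    rng = np.random.default_rng(cfg.seed + 1)
    hill = hill or _data.table2_hill()
    n = cfg.dr_n_doses
    logs = hill.log_ec50 + 0.5 * (np.arange(n) - (n - 1) / 2.0)
    doses = 10.0 ** logs
    resp = hill_response(doses, hill) + rng.normal(0.0, cfg.dr_sigma_pct, size=n)
    df = pd.DataFrame({"dose_molar": doses, "response_pct": resp})
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# seed={cfg.seed} sigma_pct={cfg.dr_sigma_pct}\n")
            df.to_csv(fh, index=False)
    return df


def generate_pk_fixture(cfg, path=None, drug=None, phys=None):
    """Synthetic venous PK series from the PBPK model at the configured
    truth, with lognormal observation noise. Stands in for an external IV
    reference dataset; it is generated, not measured."""
    rng = np.random.default_rng(cfg.seed + 2)
    drug = drug or _data.lisuride_like_drug()
    phys = phys or _data.human_physiology()
    regimen = DoseRegimen(cfg.pk_route, cfg.pk_dose_mg)
    t_end = max(cfg.pk_times_h) * 1.02
    sim = simulate_pbpk(drug, phys, regimen, t_end)
    venous = np.interp(np.asarray(cfg.pk_times_h), sim.times,
                       sim.concentrations["venous"].to_numpy())
    obs = _lognormal_around(rng, venous, cfg.pk_cv)
    df = pd.DataFrame({"time_h": cfg.pk_times_h, "conc_mg_per_L": obs})
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# seed={cfg.seed} cv={cfg.pk_cv} route={cfg.pk_route} "
                     f"dose_mg={cfg.pk_dose_mg}\n")
            df.to_csv(fh, index=False)
    return df


def write_all(cfg, out_dir):
    """Write the full fixture set into a directory; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"assay": out / "assay.csv",
             "dose_response": out / "dose_response.csv",
             "pk": out / "venous_pk.csv",
             "receptor": out / "receptor_table.csv"}
    generate_assay_fixture(cfg, paths["assay"])
    generate_doseresponse_fixture(cfg, paths["dose_response"])
    generate_pk_fixture(cfg, paths["pk"])
    _data.table3_receptor().to_csv(paths["receptor"])
    return paths
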