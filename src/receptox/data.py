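"""Reference input data: measured tables, physiology and drug fixtures.

The assay, dose-response and receptor-expression tables are the measured
inputs of the workflow (in-paper data for the histamine H1 / lisuride case
study). The physiology constants and the tissue composition table are
standard reference values used by the PBPK plumbing. The lisuride property
set is a synthetic fixture: physicochemical placeholders assembled from
typical published ranges for the compound class, never asserted as ground
truth — the pipeline treats it as "a lisuride-like drug".
"""

from __future__ import annotations

from .calibration import AssayDataset
from .pharmacology import BindingParams, HillParams, TissueReceptorTable

__all__ = [
    "table1_assay",
    "table2_hill",
    "table2_binding",
    "table3_receptor",
    "lisuride_like_drug",
    "human_physiology",
    "TISSUE_COMPOSITION",
]


def table1_assay():
    """Measured fold changes in relative luciferase units (mean ± SD, n=3)
    for HeLa cells expressing H1 stimulated with histamine for 6 h."""
    return AssayDataset([
        ("NFAT", 1.97, 0.063),
        ("NFkB", 2.18, 1.47),
        ("CREB", 1.54, 0.027),
        ("Mef2", 2.74, 1.31),
        ("ATF2", 1.67, 8.99),
    ])


def table2_hill():
    """Fitted lisuride/H1 dose-response parameters (with reported SEs)."""
    return HillParams(min_pct=7.98, max_pct=36.55, log_ec50=-7.968, n=0.8411,
                      stderr={"min_pct": 1.066, "max_pct": 0.5863,
                              "log_ec50": 0.06724, "n": 0.1009})


def table2_binding():
    """Lisuride/H1 dissociation equilibrium constant."""
    return BindingParams(kd=8e-9)


def table3_receptor():
    """Relative H1 receptor amounts in murine tissue (immunoblot, relative
    to HeLa lysate = 1). The BO row is recorded with its source label
    "Skeletal muscle" although downstream tissue maps treat the code BO as
    the bone compartment (the code-to-organ gloss used by the response
    maps); the discrepancy is inherited from the source tables and flagged
    here rather than silently resolved."""
    return TissueReceptorTable([
        ("HE", "Heart", 5.60),
        ("LU", "Lungs", 3.56),
        ("KI", "Kidney", 6.64),
        ("LI", "Liver", 11.63),
        ("BO", "Skeletal muscle", 3.88),
        ("BR", "Brain", 5.78),
        ("SP", "Spleen", 5.83),
        ("SI", "Small intestine", 5.56),
        ("CO", "Large intestine", 25.90),
    ])


def lisuride_like_drug():
    """Synthetic lisuride-like drug property fixture.

    Placeholder values chosen once from typical published ranges for the
    compound (an extensively metabolised, lipophilic, weakly basic ergoline
    of MW 338): they parameterise the worked example and the test fixtures
    and are not asserted against any measured dataset.
    """
    from .pbpk import DrugProperties

    return DrugProperties(
        name="lisuride-like (synthetic fixture)",
        molecular_weight=338.45,     # g/mol
        log_p=2.57,
        pka=7.86,
        ionization_class="base",
        solubility=0.06,             # mg/mL
        effective_permeability=4.0,  # 1e-4 cm/s
        fraction_unbound=0.30,
        blood_plasma_ratio=1.0,
        intrinsic_clearance=250.0,   # L/h
        renal_clearance=1.0,         # L/h
    )


#: fractional tissue composition (water, neutral lipid, phospholipid),
#: standard reference values used for partition-coefficient prediction
TISSUE_COMPOSITION = {
    "plasma":          {"water": 0.960, "nlipid": 0.0035, "plipid": 0.00225},
    "adipose":         {"water": 0.180, "nlipid": 0.790, "plipid": 0.0020},
    "bone":            {"water": 0.439, "nlipid": 0.074, "plipid": 0.0011},
    "brain":           {"water": 0.770, "nlipid": 0.051, "plipid": 0.0565},
    "small_intestine": {"water": 0.718, "nlipid": 0.0487, "plipid": 0.0163},
    "colon":           {"water": 0.718, "nlipid": 0.0487, "plipid": 0.0163},
    "heart":           {"water": 0.758, "nlipid": 0.0115, "plipid": 0.0166},
    "kidney":          {"water": 0.783, "nlipid": 0.0207, "plipid": 0.0162},
    "liver":           {"water": 0.751, "nlipid": 0.0348, "plipid": 0.0252},
    "lung":            {"water": 0.811, "nlipid": 0.0030, "plipid": 0.0090},
    "muscle":          {"water": 0.760, "nlipid": 0.0238, "plipid": 0.0072},
    "spleen":          {"water": 0.788, "nlipid": 0.0201, "plipid": 0.0198},
    "rest":            {"water": 0.730, "nlipid": 0.0280, "plipid": 0.0110},
}


def human_physiology():
    """Reference 70-kg adult physiology (versioned constants, v1).

    Volumes in L, flows in L/h. Organ flows are fractions of a 390 L/h
    cardiac output and sum to it by construction (the rest-of-body
    compartment takes the remainder); spleen, small-intestinal and colonic
    venous outflow routes into the liver inlet (portal convention).
    """
    from .pbpk import Physiology

    co = 390.0  # L/h ~ 6.5 L/min
    frac = {
        "heart": 0.04, "kidney": 0.19, "brain": 0.12, "muscle": 0.17,
        "adipose": 0.05, "bone": 0.05, "spleen": 0.03,
        "small_intestine": 0.10, "colon": 0.04, "liver": 0.065,  # hepatic artery
    }
    flows = {k: f * co for k, f in frac.items()}
    flows["rest"] = co * (1.0 - sum(frac.values()))
    volumes = {
        "venous": 3.5, "arterial": 1.7, "lung": 0.53,
        "heart": 0.33, "kidney": 0.31, "liver": 1.80, "spleen": 0.18,
        "small_intestine": 0.64, "colon": 0.36, "brain": 1.45,
        "bone": 10.5, "muscle": 29.0, "adipose": 14.3,
    }
    body_weight = 70.0
    volumes["rest"] = body_weight - sum(volumes.values())
    return Physiology(volumes=volumes, flows=flows, cardiac_output=co,
                      body_weight=body_weight)
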