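"""Histamine H1 receptor signalling pathway (Petri-net roster).

The network follows the canonical H1 cascade: ligand binding activates the
receptor; the heterotrimeric G protein dissociates into Gαq and Gβγ arms.
The Gαq arm runs PLCβ → PIP2 hydrolysis → IP3/DAG; IP3 releases ER calcium
(activating NFAT, Mef2 and one CREB route) while DAG drives PKC → IKK →
NF-κB. The Gβγ arm runs AC → cAMP → PKA (second CREB route) and
PI3K → PIP3, with PIP3 recruiting BTK (the BTK:PIP3 complex activates ATF2)
and Akt (second NF-κB route). Each of the five transcription factors drives
a luciferase reporter with basal transcription and first-order decay, so a
pre-stimulus baseline exists and fold changes are finite.

All rate constants are 1 in arbitrary Petri-net units; the model is
parameterised only by the conserved moiety totals, the ligand dose and the
fixed basal transcription rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .network import NetworkError, Reaction, ReactionNetwork, Species

__all__ = [
    "PathwaySpec",
    "FACTORS",
    "MOIETY_NAMES",
    "build_h1_network",
    "default_state",
    "direct_reporter_reactions",
    "write_pathway_spec",
    "read_pathway_spec",
    "export_mepn",
]

#: canonical transcription-factor names (order fixed)
FACTORS = ("NFAT", "NFkB", "CREB", "Mef2", "ATF2")

#: fitted moiety totals (protein pools, the calcium store and the receptor)
MOIETY_NAMES = (
    "receptor", "g_protein", "plc_beta", "calcium",
    "nfat", "mef2", "creb", "pkc", "ikk", "nfkb",
    "ac", "pka", "pi3k", "btk", "akt", "atf2",
)

#: moiety name -> (species initially holding the pool, all member species)
MOIETY_MEMBERS = {
    "receptor": ("H1R", ("H1R", "H1R_act")),
    "g_protein": ("Gabg", ("Gabg", "Gaq_act", "Gaq_inact", "Gbg_act")),
    "plc_beta": ("PLCb_i", ("PLCb_i", "PLCb_act")),
    "calcium": ("Ca_ER", ("Ca_ER", "Ca_cyt")),
    "nfat": ("NFAT_i", ("NFAT_i", "NFAT_act")),
    "mef2": ("Mef2_i", ("Mef2_i", "Mef2_act")),
    "creb": ("CREB_i", ("CREB_i", "CREB_act")),
    "pkc": ("PKC_i", ("PKC_i", "PKC_act")),
    "ikk": ("IKK_i", ("IKK_i", "IKK_act")),
    "nfkb": ("NFkB_i", ("NFkB_i", "NFkB_act")),
    "ac": ("AC_i", ("AC_i", "AC_act")),
    "pka": ("PKA_i", ("PKA_i", "PKA_act")),
    "pi3k": ("PI3K_i", ("PI3K_i", "PI3K_act")),
    "btk": ("BTK", ("BTK", "BTK_PIP3")),
    "akt": ("Akt_i", ("Akt_i", "Akt_act")),
    "atf2": ("ATF2_i", ("ATF2_i", "ATF2_act")),
}

_ACTIVE_SPECIES = (
    "H1R_act", "Gaq_act", "Gbg_act", "PLCb_act", "IP3", "DAG", "Ca_cyt",
    "NFAT_act", "Mef2_act", "CREB_act", "PKC_act", "IKK_act", "NFkB_act",
    "AC_act", "cAMP", "PKA_act", "PI3K_act", "PIP3", "BTK_PIP3",
    "ATF2_act", "Akt_act",
)


@dataclass
class PathwaySpec:
    """Parameterisation of the H1 model.

    ``moiety_totals`` are the conserved pool sizes (one per activation cycle,
    one for the G-protein heterotrimer, one for the ER calcium store and one
    for the receptor); ``dose`` is the ligand amount introduced at t=0;
    ``basal_rate`` is the fixed basal reporter transcription rate ε.
    ``ligand_clamped`` keeps the ligand at the dose for a sustained stimulus
    (the calibration/MCA configuration); with it off and a positive
    ``ligand_decay_rate`` the ligand is a finite, depleting pool — the
    transient-demonstration configuration.
    """

    moiety_totals: dict = field(
        default_factory=lambda: {m: 1.0 for m in MOIETY_NAMES})
    dose: float = 1.0
    basal_rate: float = 0.01
    ligand_clamped: bool = True
    ligand_decay_rate: float = 0.0
    reporter_map: dict = field(
        default_factory=lambda: {f: f"Luc_{f}" for f in FACTORS})

    def validate(self):
        missing = set(MOIETY_NAMES) - set(self.moiety_totals)
        if missing:
            raise NetworkError(f"missing moiety totals: {sorted(missing)}")
        if any(v < 0 for v in self.moiety_totals.values()):
            raise NetworkError("moiety totals must be nonnegative")
        if self.dose <= 0:
            raise NetworkError("dose must be positive")
        if self.basal_rate <= 0:
            raise NetworkError("basal transcription rate must be positive")
        if set(self.reporter_map) != set(FACTORS):
            raise NetworkError(
                f"reporter map must cover exactly {FACTORS}, got {sorted(self.reporter_map)}")

    def replace(self, **kw):
        d = {"moiety_totals": dict(self.moiety_totals), "dose": self.dose,
             "basal_rate": self.basal_rate, "ligand_clamped": self.ligand_clamped,
             "ligand_decay_rate": self.ligand_decay_rate,
             "reporter_map": dict(self.reporter_map)}
        d.update(kw)
        return PathwaySpec(**d)


def _species_roster(spec):
    sp = [Species("L", "ligand (histamine / agonist)", clamped=spec.ligand_clamped),
          Species("H1R", "histamine H1 receptor, free"),
          Species("H1R_act", "ligand-bound (active) H1 receptor"),
          Species("Gabg", "G-protein heterotrimer"),
          Species("Gaq_act", "dissociated active Gαq"),
          Species("Gaq_inact", "hydrolysed (GDP) Gαq"),
          Species("Gbg_act", "dissociated Gβγ complex"),
          Species("PLCb_i", "phospholipase Cβ, inactive"),
          Species("PLCb_act", "phospholipase Cβ, active"),
          Species("PIP2", "phosphatidylinositol 4,5-bisphosphate"),
          Species("IP3", "inositol trisphosphate"),
          Species("DAG", "diacylglycerol"),
          Species("Ca_ER", "ER calcium store"),
          Species("Ca_cyt", "cytosolic calcium"),
          Species("PKC_i", "protein kinase C, inactive"),
          Species("PKC_act", "protein kinase C, active"),
          Species("IKK_i", "IκB kinase, inactive"),
          Species("IKK_act", "IκB kinase, active"),
          Species("AC_i", "adenylate cyclase, inactive"),
          Species("AC_act", "adenylate cyclase, active"),
          Species("cAMP", "cyclic AMP"),
          Species("PKA_i", "protein kinase A, inactive"),
          Species("PKA_act", "protein kinase A, active"),
          Species("PI3K_i", "PI3 kinase, inactive"),
          Species("PI3K_act", "PI3 kinase, active"),
          Species("PIP3", "phosphatidylinositol (3,4,5)-trisphosphate"),
          Species("BTK", "Bruton tyrosine kinase, free"),
          Species("BTK_PIP3", "BTK:PIP3 membrane complex"),
          Species("Akt_i", "Akt, inactive"),
          Species("Akt_act", "Akt, active")]
    for f in FACTORS:
        sp.append(Species(f"{f}_i", f"{f} transcription factor, inactive"))
        sp.append(Species(f"{f}_act", f"{f} transcription factor, active"))
    for f in FACTORS:
        sp.append(Species(spec.reporter_map[f], f"luciferase reporter for {f}"))
    return sp


def build_h1_network(spec=None):
    """Assemble the H1 signalling :class:`ReactionNetwork` from a spec.

    Every reaction is elementary mass action with rate constant 1, except
    the per-reporter basal transcription (rate ε). Effector→target links the
    literature names but does not mechanise (calcineurin, IκB, ATP) are
    collapsed into single catalytic steps with the effector as a modifier.
    """
    spec = spec or PathwaySpec()
    spec.validate()
    R = Reaction
    rx = [
        R("bind", {"L": 1, "H1R": 1}, {"H1R_act": 1}, name="ligand-receptor binding"),
        R("unbind", {"H1R_act": 1}, {"L": 1, "H1R": 1}, name="ligand-receptor unbinding"),
        R("g_dissoc", {"Gabg": 1}, {"Gaq_act": 1, "Gbg_act": 1}, ["H1R_act"],
          name="G-protein dissociation"),
        R("gaq_hydrolysis", {"Gaq_act": 1}, {"Gaq_inact": 1}, name="Gαq GTP hydrolysis"),
        R("g_reassoc", {"Gaq_inact": 1, "Gbg_act": 1}, {"Gabg": 1},
          name="heterotrimer reassociation"),
        R("plcb_act", {"PLCb_i": 1}, {"PLCb_act": 1}, ["Gaq_act"], name="PLCβ activation"),
        R("plcb_deact", {"PLCb_act": 1}, {"PLCb_i": 1}, name="PLCβ deactivation"),
        R("pip2_synthesis", {}, {"PIP2": 1}, name="PIP2 synthesis"),
        R("pip2_turnover", {"PIP2": 1}, {}, name="PIP2 basal turnover"),
        R("pip2_hydrolysis", {"PIP2": 1}, {"IP3": 1, "DAG": 1}, ["PLCb_act"],
          name="PIP2 hydrolysis to IP3 + DAG"),
        R("ip3_decay", {"IP3": 1}, {}, name="IP3 degradation"),
        R("dag_decay", {"DAG": 1}, {}, name="DAG degradation"),
        R("ca_release", {"Ca_ER": 1}, {"Ca_cyt": 1}, ["IP3"],
          name="IP3-gated calcium release from the ER"),
        R("ca_reuptake", {"Ca_cyt": 1}, {"Ca_ER": 1}, name="calcium reuptake into the ER"),
        R("nfat_act", {"NFAT_i": 1}, {"NFAT_act": 1}, ["Ca_cyt"], name="NFAT activation"),
        R("nfat_deact", {"NFAT_act": 1}, {"NFAT_i": 1}, name="NFAT deactivation"),
        R("mef2_act", {"Mef2_i": 1}, {"Mef2_act": 1}, ["Ca_cyt"], name="Mef2 activation"),
        R("mef2_deact", {"Mef2_act": 1}, {"Mef2_i": 1}, name="Mef2 deactivation"),
        R("creb_act_ca", {"CREB_i": 1}, {"CREB_act": 1}, ["Ca_cyt"],
          name="CREB activation (calcium route)"),
        R("pkc_act", {"PKC_i": 1}, {"PKC_act": 1}, ["DAG"], name="PKC activation"),
        R("pkc_deact", {"PKC_act": 1}, {"PKC_i": 1}, name="PKC deactivation"),
        R("ikk_act", {"IKK_i": 1}, {"IKK_act": 1}, ["PKC_act"], name="IKK activation"),
        R("ikk_deact", {"IKK_act": 1}, {"IKK_i": 1}, name="IKK deactivation"),
        R("nfkb_act_ikk", {"NFkB_i": 1}, {"NFkB_act": 1}, ["IKK_act"],
          name="NF-κB activation (IKK route)"),
        R("nfkb_deact", {"NFkB_act": 1}, {"NFkB_i": 1}, name="NF-κB deactivation"),
        R("ac_act", {"AC_i": 1}, {"AC_act": 1}, ["Gbg_act"], name="AC activation"),
        R("ac_deact", {"AC_act": 1}, {"AC_i": 1}, name="AC deactivation"),
        R("camp_synthesis", {}, {"cAMP": 1}, ["AC_act"], name="cAMP synthesis"),
        R("camp_decay", {"cAMP": 1}, {}, name="cAMP degradation"),
        R("pka_act", {"PKA_i": 1}, {"PKA_act": 1}, ["cAMP"], name="PKA activation"),
        R("pka_deact", {"PKA_act": 1}, {"PKA_i": 1}, name="PKA deactivation"),
        R("creb_act_pka", {"CREB_i": 1}, {"CREB_act": 1}, ["PKA_act"],
          name="CREB activation (PKA route)"),
        R("creb_deact", {"CREB_act": 1}, {"CREB_i": 1}, name="CREB deactivation"),
        R("pi3k_act", {"PI3K_i": 1}, {"PI3K_act": 1}, ["Gbg_act"], name="PI3K activation"),
        R("pi3k_deact", {"PI3K_act": 1}, {"PI3K_i": 1}, name="PI3K deactivation"),
        R("pip2_phosphorylation", {"PIP2": 1}, {"PIP3": 1}, ["PI3K_act"],
          name="PIP2 phosphorylation to PIP3"),
        R("pip3_dephosphorylation", {"PIP3": 1}, {"PIP2": 1},
          name="PIP3 dephosphorylation"),
        R("btk_pip3_bind", {"BTK": 1, "PIP3": 1}, {"BTK_PIP3": 1},
          name="BTK:PIP3 association"),
        R("btk_pip3_unbind", {"BTK_PIP3": 1}, {"BTK": 1, "PIP3": 1},
          name="BTK:PIP3 dissociation"),
        R("atf2_act", {"ATF2_i": 1}, {"ATF2_act": 1}, ["BTK_PIP3"], name="ATF2 activation"),
        R("atf2_deact", {"ATF2_act": 1}, {"ATF2_i": 1}, name="ATF2 deactivation"),
        R("akt_act", {"Akt_i": 1}, {"Akt_act": 1}, ["PIP3"], name="Akt activation"),
        R("akt_deact", {"Akt_act": 1}, {"Akt_i": 1}, name="Akt deactivation"),
        R("nfkb_act_akt", {"NFkB_i": 1}, {"NFkB_act": 1}, ["Akt_act"],
          name="NF-κB activation (Akt route)"),
    ]
    for f in FACTORS:
        luc = spec.reporter_map[f]
        rx.append(R(f"tx_{f}", {}, {luc: 1}, [f"{f}_act"],
                    name=f"{f}-driven reporter transcription"))
        rx.append(R(f"basal_{f}", {}, {luc: 1}, rate_constant=spec.basal_rate,
                    name=f"basal {f} reporter transcription"))
        rx.append(R(f"dec_{f}", {luc: 1}, {}, name=f"{f} reporter decay"))
    if spec.ligand_decay_rate > 0 and not spec.ligand_clamped:
        rx.append(R("ligand_decay", {"L": 1}, {}, rate_constant=spec.ligand_decay_rate,
                    name="ligand degradation"))
    net = ReactionNetwork(_species_roster(spec), rx)
    _check_roster(net, spec)
    return net


def _check_roster(net, spec):
    used = set()
    for r in net.reactions:
        used |= set(r.reactants) | set(r.products) | set(r.modifiers)
    orphans = {s.id for s in net.species} - used
    if orphans:
        raise NetworkError(f"orphan species in roster: {sorted(orphans)}")
    for f, luc in spec.reporter_map.items():
        if luc not in net.species_index:
            raise NetworkError(f"reporter {f} maps to unknown species {luc!r}")


def default_state(spec=None, stimulated=False, network=None):
    """Initial marking: every moiety fully inactive, calcium in the ER,
    PIP pool in PIP2, reporters at their basal level ε/k_dec, ligand at the
    dose (stimulated) or zero."""
    spec = spec or PathwaySpec()
    spec.validate()
    net = network or build_h1_network(spec)
    amounts = {}
    for name, (holder, _members) in MOIETY_MEMBERS.items():
        amounts[holder] = spec.moiety_totals[name]
    amounts["PIP2"] = 1.0  # basal steady level: synthesis k / turnover k
    for f in FACTORS:
        amounts[spec.reporter_map[f]] = spec.basal_rate  # ε / k_dec with k_dec = 1
    amounts["L"] = spec.dose if stimulated else 0.0
    return net.state(amounts)


def direct_reporter_reactions(factor, spec=None):
    """The reporter's own transcription/basal/decay reaction ids for a factor."""
    if factor not in FACTORS:
        raise NetworkError(f"unknown factor {factor!r}")
    return (f"tx_{factor}", f"basal_{factor}", f"dec_{factor}")


# ---------------------------------------------------------------------------
# structured-text spec file and mEPN-style export
# ---------------------------------------------------------------------------


def write_pathway_spec(spec, path):
    doc = {"moiety_totals": {k: float(v) for k, v in spec.moiety_totals.items()},
           "dose": float(spec.dose), "basal_rate": float(spec.basal_rate),
           "ligand_clamped": bool(spec.ligand_clamped),
           "ligand_decay_rate": float(spec.ligand_decay_rate),
           "reporter_map": dict(spec.reporter_map)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_pathway_spec(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    spec = PathwaySpec(**doc)
    spec.validate()
    return spec


def export_mepn(network, path):
    """Node/edge list (TSV) mirroring the Petri-net layout for diagram tools.

    Nodes are species (``place``) and reactions (``transition``); edges carry
    ``consume``/``produce``/``catalyse`` roles.
    """
    with open(path, "w") as fh:
        fh.write("kind\tid\tlabel\n")
        for s in network.species:
            fh.write(f"place\t{s.id}\t{s.name or s.id}\n")
        for r in network.reactions:
            fh.write(f"transition\t{r.id}\t{r.name or r.id}\n")
        fh.write("\nsource\ttarget\trole\tweight\n")
        for r in network.reactions:
            for sp, st in r.reactants.items():
                fh.write(f"{sp}\t{r.id}\tconsume\t{st}\n")
            for sp, st in r.products.items():
                fh.write(f"{r.id}\t{sp}\tproduce\t{st}\n")
            for sp in r.modifiers:
                fh.write(f"{sp}\t{r.id}\tcatalyse\t1\n")
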