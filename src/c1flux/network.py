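"""Core central-metabolism network with C1-assimilation modules.

The model covers formate/methanol/acetate uptake, the THF-mediated C1
route (FtfL/Fch/MtdA), the glycine cleavage system run in the synthetic
(condensing) direction, serine and pyruvate formation, the TCA cycle with
glyoxylate shunt and anaplerosis, a glycine-oxidase branch, lumped
biomass drains and lumped energy metabolism.  Carbon atom maps are
curated for the labeling subnetwork so positional-isotopomer simulations
can be run on top of any flux solution.

Carbon indexing is 1-based.  Conventions:

* pyruvate C1 (carboxyl) .. C3 (methyl) inherit serine C1..C3;
* acetate C1 (carboxyl), C2 (methyl) map onto acetyl-CoA C1, C2;
* oxaloacetate C1..C4 with the pyruvate-carboxylase CO2 entering at C4;
* 2-ketoglutarate carbons derive from citrate as
  C1<-OAA C4, C2<-OAA C3, C3<-OAA C2, C4<-AcCoA C2, C5<-AcCoA C1,
  with the decarboxylated carbon being OAA C1;
* succinate and fumarate are treated as symmetric molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StrainConfig",
    "AtomMapViolation",
    "build_core_model",
    "validate_atom_maps",
    "STRAIN_PRESETS",
    "MODULE_REACTIONS",
    "DEFAULT_COFACTOR_PARAMS",
    "DEFAULT_BIOMASS_DRAINS",
]

INF = float("inf")


@dataclass(frozen=True)
class Metabolite:
    """A pool in the network; ``n_carbons`` drives isotopomer state size."""

    id: str
    name: str = ""
    n_carbons: int = 0
    compartment: str = "cytosol"
    symmetric: bool = False

    def __post_init__(self):
        if self.n_carbons < 0:
            raise ValueError(f"{self.id}: n_carbons must be >= 0")
        if self.symmetric and self.n_carbons < 2:
            raise ValueError(f"{self.id}: symmetric requires n_carbons >= 2")
        if self.compartment not in ("cytosol", "external"):
            raise ValueError(f"{self.id}: unknown compartment {self.compartment!r}")


@dataclass
class Reaction:
    """Stoichiometry plus an optional carbon atom map.

    ``atom_map`` maps ``(substrate_id, carbon_index)`` to
    ``(product_id, carbon_index)`` with 1-based indices, covering every
    carbon of every carbon-bearing substrate and product.
    """

    id: str
    stoichiometry: dict[str, Fraction | int | float]
    reversible: bool = False
    bounds: tuple[float, float] = (0.0, INF)
    atom_map: dict[tuple[str, int], tuple[str, int]] | None = None
    enzyme_label: str = ""
    name: str = ""

    def __post_init__(self):
        lo, hi = self.bounds
        if lo > hi:
            raise ValueError(f"{self.id}: bounds[0] > bounds[1]")
        if not self.reversible and lo < 0:
            raise ValueError(f"{self.id}: irreversible reaction with negative lower bound")

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass(frozen=True)
class AtomMapViolation:
    reaction_id: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.reaction_id}: {self.message}"


DEFAULT_COFACTOR_PARAMS: dict[str, float] = {
    # Effective P/O ratios (mol ATP per mol cofactor reoxidised) and ATP
    # maintenance terms.  These are documented package defaults, not
    # experimentally fitted values.
    "po_nadh": 1.5,
    "po_fadh2": 1.0,
    "gam_atp": 50.0,  # growth-associated ATP, mmol gCDW^-1
    "ngam_atp": 0.92,  # non-growth maintenance, mmol gCDW^-1 h^-1
}

# Lumped biomass precursor drains, mmol per gCDW.  Chosen so that total
# drained carbon is ~41 mmol C per gCDW (~0.49 gC/gCDW); package default,
# not taken from any publication.
DEFAULT_BIOMASS_DRAINS: dict[str, float] = {
    "pyr": 7.0,    # pyruvate/PEP/triose/sugar requirements, lumped
    "accoa": 2.5,
    "oaa": 1.7,
    "akg": 1.1,
    "ser": 0.5,
    "gly": 0.6,
    "mlthf": 0.3,  # C1 units for purines/methionine etc.
    "nadph": 11.0,
    # gam_atp from cofactor params is added on top of these.
}


def _metabolites() -> list[Metabolite]:
    M = Metabolite
    return [
        M("for", "formate", 1),
        M("co2", "carbon dioxide", 1),
        M("meoh", "methanol", 1),
        M("fald", "formaldehyde", 1),
        M("ac", "acetate", 2),
        M("fthf", "10-formyl-THF (C1 unit)", 1),
        M("methf", "5,10-methenyl-THF (C1 unit)", 1),
        M("mlthf", "5,10-methylene-THF (C1 unit)", 1),
        M("gly", "glycine", 2),
        M("ser", "serine", 3),
        M("pyr", "pyruvate", 3),
        M("accoa", "acetyl-CoA (acetyl carbons)", 2),
        M("oaa", "oxaloacetate", 4),
        M("icit", "isocitrate (citrate/isocitrate pool)", 6),
        M("akg", "2-ketoglutarate", 5),
        M("succoa", "succinyl-CoA (succinyl carbons)", 4),
        M("succ", "succinate", 4, symmetric=True),
        M("fum", "fumarate", 4, symmetric=True),
        M("mal", "malate", 4),
        M("glx", "glyoxylate", 2),
        M("acald", "acetaldehyde", 2),
        M("nh3", "ammonia", 0),
        M("atp", "ATP", 0),
        M("adp", "ADP", 0),
        M("nad", "NAD+", 0),
        M("nadh", "NADH", 0),
        M("nadp", "NADP+", 0),
        M("nadph", "NADPH", 0),
        M("fad", "FAD", 0),
        M("fadh2", "FADH2", 0),
    ]


def _amap(pairs: list[tuple[str, int, str, int]]) -> dict[tuple[str, int], tuple[str, int]]:
    return {(s, i): (p, j) for s, i, p, j in pairs}


def _reaction_library(
    cofactor_params: Mapping[str, float],
    biomass_drains: Mapping[str, float],
) -> list[Reaction]:
    R = Reaction
    po_n = cofactor_params["po_nadh"]
    po_f = cofactor_params["po_fadh2"]
    gam = cofactor_params["gam_atp"]
    ngam = cofactor_params["ngam_atp"]
    b = dict(biomass_drains)

    biomass_stoich: dict[str, float] = {
        "pyr": -b["pyr"], "accoa": -b["accoa"], "oaa": -b["oaa"],
        "akg": -b["akg"], "ser": -b["ser"], "gly": -b["gly"],
        "mlthf": -b["mlthf"],
        "nadph": -b["nadph"], "nadp": b["nadph"],
        "atp": -gam, "adp": gam,
        "nh3": -(b["ser"] + b["gly"]),  # token N demand of the drained amino acids
    }

    rxns = [
        # --- exchanges -------------------------------------------------
        # Substrate uptakes default closed; FluxConstraintSet opens them.
        R("EX_for", {"for": 1}, bounds=(0.0, 0.0), name="formate uptake"),
        R("EX_ac", {"ac": 1}, bounds=(0.0, 0.0), name="acetate uptake"),
        R("EX_meoh", {"meoh": 1}, bounds=(0.0, 0.0), name="methanol uptake"),
        R("EX_co2", {"co2": -1}, reversible=True, bounds=(-INF, INF), name="CO2 exchange"),
        R("EX_nh3", {"nh3": 1}, reversible=True, bounds=(-INF, INF), name="ammonia exchange"),
        # --- C1 activation: module M1 ---------------------------------
        R("FtfL", {"for": -1, "atp": -1, "fthf": 1, "adp": 1},
          atom_map=_amap([("for", 1, "fthf", 1)]), enzyme_label="FtfL",
          name="formate-THF ligase"),
        R("Fch", {"fthf": -1, "methf": 1},
          atom_map=_amap([("fthf", 1, "methf", 1)]), enzyme_label="Fch",
          name="methenyl-THF cyclohydrolase"),
        R("MtdA", {"methf": -1, "nadph": -1, "mlthf": 1, "nadp": 1},
          atom_map=_amap([("methf", 1, "mlthf", 1)]), enzyme_label="MtdA",
          name="methylene-THF dehydrogenase"),
        # --- glycine cleavage system, condensing direction (M2) -------
        R("GcvTHP", {"mlthf": -1, "co2": -1, "nh3": -1, "nadh": -1,
                     "gly": 1, "nad": 1},
          atom_map=_amap([("co2", 1, "gly", 1), ("mlthf", 1, "gly", 2)]),
          enzyme_label="GcvTHP", name="glycine synthase (reverse GCS)"),
        # --- serine / pyruvate: module M3 ------------------------------
        R("GlyA", {"gly": -1, "mlthf": -1, "ser": 1},
          reversible=True, bounds=(-INF, INF),
          atom_map=_amap([("gly", 1, "ser", 1), ("gly", 2, "ser", 2),
                          ("mlthf", 1, "ser", 3)]),
          enzyme_label="GlyA", name="serine hydroxymethyltransferase"),
        R("TdcG", {"ser": -1, "pyr": 1, "nh3": 1},
          atom_map=_amap([("ser", 1, "pyr", 1), ("ser", 2, "pyr", 2),
                          ("ser", 3, "pyr", 3)]),
          enzyme_label="TdcG", name="serine deaminase"),
        # --- C1 oxidation ----------------------------------------------
        R("Fdh", {"for": -1, "nad": -1, "co2": 1, "nadh": 1},
          atom_map=_amap([("for", 1, "co2", 1)]), enzyme_label="Fdh",
          name="formate dehydrogenase (energy module)"),
        R("Mdh", {"meoh": -1, "nad": -1, "fald": 1, "nadh": 1},
          atom_map=_amap([("meoh", 1, "fald", 1)]), enzyme_label="Mdh",
          name="NAD-dependent methanol dehydrogenase"),
        R("FaldDH", {"fald": -1, "nad": -1, "for": 1, "nadh": 1},
          atom_map=_amap([("fald", 1, "for", 1)]), enzyme_label="FaldDH",
          name="formaldehyde oxidation (lumped)"),
        # --- acetate activation ----------------------------------------
        R("Acs", {"ac": -1, "atp": -2, "accoa": 1, "adp": 2},
          atom_map=_amap([("ac", 1, "accoa", 1), ("ac", 2, "accoa", 2)]),
          enzyme_label="Acs", name="acetyl-CoA synthetase (2 ATP equiv.)"),
        # --- pyruvate node ---------------------------------------------
        R("Pdh", {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
          atom_map=_amap([("pyr", 1, "co2", 1), ("pyr", 2, "accoa", 1),
                          ("pyr", 3, "accoa", 2)]),
          enzyme_label="Pdh", name="pyruvate dehydrogenase"),
        R("Pyc", {"pyr": -1, "co2": -1, "atp": -1, "oaa": 1, "adp": 1},
          atom_map=_amap([("pyr", 1, "oaa", 1), ("pyr", 2, "oaa", 2),
                          ("pyr", 3, "oaa", 3), ("co2", 1, "oaa", 4)]),
          enzyme_label="Pyc", name="pyruvate carboxylase (anaplerosis)"),
        # --- TCA cycle --------------------------------------------------
        R("GltA", {"oaa": -1, "accoa": -1, "icit": 1},
          atom_map=_amap([("oaa", 1, "icit", 1), ("oaa", 2, "icit", 2),
                          ("oaa", 3, "icit", 3), ("oaa", 4, "icit", 4),
                          ("accoa", 1, "icit", 5), ("accoa", 2, "icit", 6)]),
          enzyme_label="GltA", name="citrate synthase + aconitase (lumped)"),
        R("Icd", {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1},
          atom_map=_amap([("icit", 1, "co2", 1), ("icit", 4, "akg", 1),
                          ("icit", 3, "akg", 2), ("icit", 2, "akg", 3),
                          ("icit", 6, "akg", 4), ("icit", 5, "akg", 5)]),
          enzyme_label="Icd", name="isocitrate dehydrogenase (NADP)"),
        R("SucAB", {"akg": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1},
          atom_map=_amap([("akg", 1, "co2", 1), ("akg", 2, "succoa", 1),
                          ("akg", 3, "succoa", 2), ("akg", 4, "succoa", 3),
                          ("akg", 5, "succoa", 4)]),
          enzyme_label="SucAB", name="2-ketoglutarate dehydrogenase"),
        R("SucCD", {"succoa": -1, "adp": -1, "succ": 1, "atp": 1},
          atom_map=_amap([("succoa", 1, "succ", 1), ("succoa", 2, "succ", 2),
                          ("succoa", 3, "succ", 3), ("succoa", 4, "succ", 4)]),
          enzyme_label="SucCD", name="succinyl-CoA synthetase"),
        R("Sdh", {"succ": -1, "fad": -1, "fum": 1, "fadh2": 1},
          atom_map=_amap([("succ", 1, "fum", 1), ("succ", 2, "fum", 2),
                          ("succ", 3, "fum", 3), ("succ", 4, "fum", 4)]),
          enzyme_label="Sdh", name="succinate dehydrogenase"),
        R("FumC", {"fum": -1, "mal": 1}, reversible=True, bounds=(-INF, INF),
          atom_map=_amap([("fum", 1, "mal", 1), ("fum", 2, "mal", 2),
                          ("fum", 3, "mal", 3), ("fum", 4, "mal", 4)]),
          enzyme_label="FumC", name="fumarase"),
        R("MaeDH", {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1},
          reversible=True, bounds=(-INF, INF),
          atom_map=_amap([("mal", 1, "oaa", 1), ("mal", 2, "oaa", 2),
                          ("mal", 3, "oaa", 3), ("mal", 4, "oaa", 4)]),
          enzyme_label="MaeDH", name="malate dehydrogenase"),
        R("MaeB", {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1},
          atom_map=_amap([("mal", 1, "pyr", 1), ("mal", 2, "pyr", 2),
                          ("mal", 3, "pyr", 3), ("mal", 4, "co2", 1)]),
          enzyme_label="MaeB", name="malic enzyme"),
        # --- glyoxylate shunt & glycine oxidation ----------------------
        R("AceA", {"icit": -1, "succ": 1, "glx": 1},
          atom_map=_amap([("icit", 1, "succ", 1), ("icit", 2, "succ", 2),
                          ("icit", 6, "succ", 3), ("icit", 5, "succ", 4),
                          ("icit", 4, "glx", 1), ("icit", 3, "glx", 2)]),
          enzyme_label="AceA", name="isocitrate lyase"),
        R("GlcB", {"glx": -1, "accoa": -1, "mal": 1},
          atom_map=_amap([("glx", 1, "mal", 1), ("glx", 2, "mal", 2),
                          ("accoa", 2, "mal", 3), ("accoa", 1, "mal", 4)]),
          enzyme_label="GlcB", name="malate synthase"),
        R("ThiO", {"gly": -1, "glx": 1, "nh3": 1},
          atom_map=_amap([("gly", 1, "glx", 1), ("gly", 2, "glx", 2)]),
          enzyme_label="ThiO", name="glycine oxidase branch (lumped)"),
        # --- canonical serine/glycine biosynthesis (lumped) ------------
        # SerA lumps the phosphoglycerate -> serine route onto the
        # pyruvate node (C1..C3 correspondence preserved).
        R("SerA", {"pyr": -1, "nh3": -1, "nadph": -1, "atp": -1,
                   "ser": 1, "nadp": 1, "adp": 1},
          atom_map=_amap([("pyr", 1, "ser", 1), ("pyr", 2, "ser", 2),
                          ("pyr", 3, "ser", 3)]),
          enzyme_label="SerA", name="canonical serine biosynthesis (lumped)"),
        # LtaE lumps threonine synthesis + aldolase cleavage: OAA-derived
        # threonine -> glycine (C1,C2) + acetaldehyde (C3,C4) -> AcCoA.
        R("LtaE", {"oaa": -1, "nadph": -2, "atp": -2, "nh3": -1, "nad": -1,
                   "gly": 1, "accoa": 1, "nadp": 2, "adp": 2, "nadh": 1},
          atom_map=_amap([("oaa", 1, "gly", 1), ("oaa", 2, "gly", 2),
                          ("oaa", 3, "accoa", 1), ("oaa", 4, "accoa", 2)]),
          enzyme_label="LtaE", name="threonine aldolase glycine supply (lumped)"),
        # PurT drains formate + ATP into the (unmodeled) purine pool.
        R("PurT", {"for": -1, "atp": -1, "adp": 1},
          enzyme_label="PurT", name="glycinamide formyltransferase drain"),
        # --- energy metabolism -----------------------------------------
        R("PntAB", {"nadh": -1, "nadp": -1, "nad": 1, "nadph": 1},
          reversible=True, bounds=(-INF, INF),
          enzyme_label="PntAB", name="transhydrogenase"),
        R("OxPhosNADH", {"nadh": -1, "adp": -po_n, "nad": 1, "atp": po_n},
          enzyme_label="OxPhosNADH", name="oxidative phosphorylation (NADH)"),
        R("OxPhosFADH2", {"fadh2": -1, "adp": -po_f, "fad": 1, "atp": po_f},
          enzyme_label="OxPhosFADH2", name="oxidative phosphorylation (FADH2)"),
        R("NGAM", {"atp": -1, "adp": 1}, bounds=(ngam, ngam),
          enzyme_label="NGAM", name="non-growth ATP maintenance"),
        R("ATPsink", {"atp": -1, "adp": 1}, bounds=(0.0, INF),
          enzyme_label="ATPsink", name="excess ATP hydrolysis"),
        # --- biomass ----------------------------------------------------
        R("biomass", biomass_stoich, bounds=(0.0, INF),
          enzyme_label="biomass", name="biomass drain (1 flux unit = 1 gCDW/h)"),
    ]
    return rxns


# Reactions gated by strain "additions"; absent modules are closed to 0.
MODULE_REACTIONS: dict[str, tuple[str, ...]] = {
    "M1": ("FtfL", "Fch", "MtdA"),
    "M2-overexpr": ("GcvTHP",),
    "M3": (),  # GlyA/TdcG are endogenous and always present
    "EGM-Fdh": ("Fdh",),
    "Mdh": ("Mdh", "FaldDH"),
}

_RGLYP_KO = frozenset({"SerA", "LtaE", "AceA"})


@dataclass(frozen=True)
class StrainConfig:
    """Genotype as knockouts (enzyme labels) plus enabled modules."""

    name: str
    knockouts: frozenset[str] = frozenset()
    additions: frozenset[str] = frozenset()

    def __post_init__(self):
        if "rG·F" in self.name and "EGM-Fdh" not in self.additions:
            raise ValueError("rG·F strains require the EGM-Fdh addition")
        if "rG·M" in self.name and "Mdh" not in self.additions:
            raise ValueError("rG·M strains require the Mdh addition")


STRAIN_PRESETS: dict[str, StrainConfig] = {
    "KT2440-core": StrainConfig("KT2440-core"),
    "rG1": StrainConfig(
        "rG1", knockouts=_RGLYP_KO,
        additions=frozenset({"M1", "M2-overexpr", "M3"})),
    "rG1-T": StrainConfig(
        "rG1-T", knockouts=_RGLYP_KO | {"ThiO"},
        additions=frozenset({"M1", "M2-overexpr", "M3"})),
    "rG-F": StrainConfig(
        "rG·F", knockouts=_RGLYP_KO | {"PurT"},
        additions=frozenset({"M1", "M2-overexpr", "M3", "EGM-Fdh"})),
    # rG-M keeps a formate-oxidation route (native dehydrogenases stand in
    # for the cured heterologous Fdh); energy conservation no longer
    # depends on it once methanol oxidation supplies NADH.
    "rG-M": StrainConfig(
        "rG·M", knockouts=_RGLYP_KO | {"PurT"},
        additions=frozenset({"M1", "M2-overexpr", "M3", "Mdh", "EGM-Fdh"})),
}
# Accept the typographic middle-dot spellings too.
STRAIN_PRESETS["rG·F"] = STRAIN_PRESETS["rG-F"]
STRAIN_PRESETS["rG·M"] = STRAIN_PRESETS["rG-M"]
STRAIN_PRESETS["rG1·T"] = STRAIN_PRESETS["rG1-T"]


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str = "biomass"
    cofactor_params: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COFACTOR_PARAMS))
    name: str = "core"

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        if self.biomass_reaction_id not in self._rxn_index:
            raise ValueError(f"biomass reaction {self.biomass_reaction_id!r} missing")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    raise ValueError(f"{r.id}: unknown metabolite {m!r}")

    # -- lookups ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reactions_by_enzyme(self, label: str) -> list[Reaction]:
        return [r for r in self.reactions if r.enzyme_label == label]

    @property
    def S(self) -> np.ndarray:
        """Stoichiometric matrix, rows = metabolites, columns = reactions."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[self._met_index[m], j] = float(c)
        return S

    def bounds_array(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([r.bounds[0] for r in self.reactions])
        hi = np.array([r.bounds[1] for r in self.reactions])
        return lo, hi

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "biomass_reaction_id": self.biomass_reaction_id,
            "cofactor_params": self.cofactor_params,
            "metabolites": [
                {"id": m.id, "name": m.name, "n_carbons": m.n_carbons,
                 "compartment": m.compartment, "symmetric": m.symmetric}
                for m in self.metabolites
            ],
            "reactions": [
                {"id": r.id, "name": r.name, "enzyme_label": r.enzyme_label,
                 "reversible": r.reversible,
                 "bounds": [r.bounds[0], r.bounds[1]],
                 "stoichiometry": {m: float(c) for m, c in r.stoichiometry.items()},
                 "atom_map": ([[s, i, p, j] for (s, i), (p, j) in r.atom_map.items()]
                              if r.atom_map else None)}
                for r in self.reactions
            ],
        }

    def to_json(self, path) -> None:
        def _clean(x):
            if isinstance(x, float) and x == INF:
                return "inf"
            if isinstance(x, float) and x == -INF:
                return "-inf"
            return x

        d = self.to_dict()
        for r in d["reactions"]:
            r["bounds"] = [_clean(b) for b in r["bounds"]]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        def _num(x):
            if x == "inf":
                return INF
            if x == "-inf":
                return -INF
            return float(x)

        mets = [Metabolite(**m) for m in d["metabolites"]]
        rxns = []
        for r in d["reactions"]:
            amap = None
            if r.get("atom_map"):
                amap = {(s, int(i)): (p, int(j)) for s, i, p, j in r["atom_map"]}
            rxns.append(Reaction(
                id=r["id"], name=r.get("name", ""),
                enzyme_label=r.get("enzyme_label", ""),
                reversible=r["reversible"],
                bounds=(_num(r["bounds"][0]), _num(r["bounds"][1])),
                stoichiometry={m: Fraction(c).limit_denominator(10**6)
                               for m, c in r["stoichiometry"].items()},
                atom_map=amap))
        return cls(metabolites=mets, reactions=rxns,
                   biomass_reaction_id=d["biomass_reaction_id"],
                   cofactor_params=dict(d.get("cofactor_params", DEFAULT_COFACTOR_PARAMS)),
                   name=d.get("name", "core"))

    @classmethod
    def from_json(cls, path) -> "MetabolicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_summary_tsv(self, path) -> None:
        """One-line-per-reaction overview (id, enzyme, equation, bounds)."""
        import pandas as pd

        def _eq(r: Reaction) -> str:
            lhs = " + ".join(f"{float(-c):g} {m}" for m, c in r.stoichiometry.items() if c < 0)
            rhs = " + ".join(f"{float(c):g} {m}" for m, c in r.stoichiometry.items() if c > 0)
            arrow = "<=>" if r.reversible else "-->"
            return f"{lhs} {arrow} {rhs}"

        rows = [{"reaction": r.id, "enzyme": r.enzyme_label, "equation": _eq(r),
                 "lb": r.bounds[0], "ub": r.bounds[1],
                 "atom_mapped": r.atom_map is not None}
                for r in self.reactions]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_core_model(
    config: StrainConfig | str,
    cofactor_params: Mapping[str, float] | None = None,
    biomass_drains: Mapping[str, float] | None = None,
) -> MetabolicModel:
    """Assemble the core model for a strain configuration.

    Knockouts and disabled modules are applied by fixing the affected
    reaction bounds to ``[0, 0]`` (the column stays in S so that knockout
    invariants are checkable on flux solutions).
    """
    if isinstance(config, str):
        try:
            config = STRAIN_PRESETS[config]
        except KeyError:
            raise KeyError(f"unknown strain name {config!r}; "
                           f"known: {sorted(set(STRAIN_PRESETS))}") from None

    params = dict(DEFAULT_COFACTOR_PARAMS)
    if cofactor_params:
        params.update(cofactor_params)
    drains = dict(DEFAULT_BIOMASS_DRAINS)
    if biomass_drains:
        drains.update(biomass_drains)

    mets = _metabolites()
    rxns = _reaction_library(params, drains)
    by_enzyme: dict[str, list[Reaction]] = {}
    for r in rxns:
        by_enzyme.setdefault(r.enzyme_label, []).append(r)

    for mod in config.additions:
        if mod not in MODULE_REACTIONS:
            raise KeyError(f"unknown module {mod!r}")
    gated = {rid for mod, rids in MODULE_REACTIONS.items() for rid in rids}
    enabled = {rid for mod in config.additions for rid in MODULE_REACTIONS[mod]}
    for r in rxns:
        if r.id in gated and r.id not in enabled:
            r.bounds = (0.0, 0.0)

    for label in config.knockouts:
        targets = by_enzyme.get(label)
        if not targets:
            raise KeyError(f"knockout target {label!r} not in the base library")
        for r in targets:
            r.bounds = (0.0, 0.0)

    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           cofactor_params=params, name=config.name)
    violations = validate_atom_maps(model)
    if violations:
        raise ValueError("atom-map violations at build time: "
                         + "; ".join(str(v) for v in violations))
    return model


def validate_atom_maps(model: MetabolicModel) -> list[AtomMapViolation]:
    """Check carbon conservation and bijectivity of every atom map.

    Returns an empty list iff every atom-mapped reaction maps each
    substrate carbon to exactly one product carbon and vice versa.
    Reports problems instead of raising.
    """
    out: list[AtomMapViolation] = []
    for r in model.reactions:
        if r.atom_map is None:
            continue
        sub_carbons: set[tuple[str, int]] = set()
        prod_carbons: set[tuple[str, int]] = set()
        for mid, coeff in r.stoichiometry.items():
            met = model.metabolite(mid)
            if met.n_carbons == 0:
                continue
            if abs(float(coeff)) != 1:
                out.append(AtomMapViolation(
                    r.id, f"atom-mapped carbon metabolite {mid} has |coeff| != 1"))
                continue
            slots = {(mid, i) for i in range(1, met.n_carbons + 1)}
            (sub_carbons if coeff < 0 else prod_carbons).update(slots)

        n_sub = len(sub_carbons)
        n_prod = len(prod_carbons)
        if n_sub != n_prod:
            out.append(AtomMapViolation(
                r.id, f"carbon imbalance: {n_sub} substrate vs {n_prod} product carbons"))

        seen_targets: set[tuple[str, int]] = set()
        for src, dst in r.atom_map.items():
            if src not in sub_carbons:
                out.append(AtomMapViolation(
                    r.id, f"mapped source {src} is not a substrate carbon"))
            if dst not in prod_carbons:
                out.append(AtomMapViolation(
                    r.id, f"mapped target {dst} is not a product carbon"))
            if dst in seen_targets:
                out.append(AtomMapViolation(
                    r.id, f"product carbon {dst} mapped twice"))
            seen_targets.add(dst)
        for src in sub_carbons - set(r.atom_map):
            out.append(AtomMapViolation(r.id, f"substrate carbon {src} unmapped"))
        for dst in prod_carbons - seen_targets:
            out.append(AtomMapViolation(r.id, f"product carbon {dst} not produced"))
    return out
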