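"""Genome-scale model extension for full-model flux predictions.

Loads an SBML Level-3 FBC reconstruction (e.g. the P. putida
reconstruction iJN1463 from the BiGG collection), removes the native
serine/glycine/glyoxylate-shunt entry reactions, appends the
heterologous C1-activation reactions (FtfL/Fch/MtdA, plus Fdh and/or
Mdh) and runs biomass-maximizing FBA under measured uptake constraints.

Requires cobrapy (optional dependency); everything here degrades with a
clear ImportError when it is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GemEdits", "extend_genome_scale_model", "gem_growth_rate"]

# BiGG identifiers of the native reactions the engineered strains lack.
DEFAULT_REMOVALS: dict[str, tuple[str, ...]] = {
    # enzyme label -> candidate reaction ids (first match is used)
    "SerA": ("PGCD",),          # 3-phosphoglycerate dehydrogenase
    "LtaE": ("THRA", "THRA2", "LTAA"),  # threonine aldolase
    "AceA": ("ICL",),           # isocitrate lyase
}


@dataclass
class GemEdits:
    """Strain edits expressed against genome-scale reaction identifiers."""

    knockouts: tuple[str, ...] = ("SerA", "LtaE", "AceA")
    add_fdh: bool = True
    add_mdh: bool = False
    extra_knockout_reactions: tuple[str, ...] = ()
    removal_map: dict = field(default_factory=lambda: dict(DEFAULT_REMOVALS))


def _require_cobra():
    try:
        import cobra  # noqa: F401
        return cobra
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "genome-scale modeling requires the optional dependency cobrapy "
            "(pip install 'c1flux[sbml]')") from exc


def extend_genome_scale_model(sbml_path, edits: GemEdits | None = None):
    """Return a cobra model with strain edits applied.

    Knockouts are applied by closing reaction bounds; the heterologous
    THF-route reactions are appended using metabolite identifiers of the
    BiGG namespace.
    """
    cobra = _require_cobra()
    from cobra import Reaction as CobraReaction

    edits = edits or GemEdits()
    model = cobra.io.read_sbml_model(str(sbml_path))

    for label in edits.knockouts:
        candidates = edits.removal_map.get(label, (label,))
        hit = next((rid for rid in candidates if rid in model.reactions), None)
        if hit is None:
            raise KeyError(
                f"no reaction for knockout {label!r} (tried {candidates})")
        rxn = model.reactions.get_by_id(hit)
        rxn.lower_bound = rxn.upper_bound = 0.0
    for rid in edits.extra_knockout_reactions:
        rxn = model.reactions.get_by_id(rid)
        rxn.lower_bound = rxn.upper_bound = 0.0

    def met(mid):
        return model.metabolites.get_by_id(mid)

    def add(rid, name, stoich, lb=0.0, ub=1000.0):
        if rid in model.reactions:
            return
        r = CobraReaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        model.add_reactions([r])
        r.add_metabolites({met(m): c for m, c in stoich.items()})

    # Module M1 (formate -> methylene-THF), BiGG metabolite ids.
    add("FTHFLi_het", "formate-THF ligase (FtfL)",
        {"for_c": -1, "thf_c": -1, "atp_c": -1,
         "10fthf_c": 1, "adp_c": 1, "pi_c": 1})
    add("MTHFC_het", "methenyl-THF cyclohydrolase (Fch)",
        {"10fthf_c": -1, "h_c": -1, "methf_c": 1, "h2o_c": 1},
        lb=-1000.0)
    add("MTHFD_het", "methylene-THF dehydrogenase (MtdA, NADP)",
        {"methf_c": -1, "nadph_c": -1, "mlthf_c": 1, "nadp_c": 1},
        lb=-1000.0)
    if edits.add_fdh:
        add("FDH_het", "NAD-dependent formate dehydrogenase",
            {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1})
    if edits.add_mdh:
        add("MDH_meoh_het", "NAD-dependent methanol dehydrogenase",
            {"meoh_c": -1, "nad_c": -1, "fald_c": 1, "nadh_c": 1, "h_c": 1})
    return model


def gem_growth_rate(model, substrate_exchange: str, uptake: float,
                    co2_open: bool = True) -> tuple[float, dict]:
    """Biomass-maximizing FBA at a fixed substrate uptake rate.

    Returns ``(mu, fluxes)`` with uptake expressed as a positive number
    (mmol gCDW^-1 h^-1).
    """
    _require_cobra()
    ex = model.reactions.get_by_id(substrate_exchange)
    ex.lower_bound = -abs(uptake)
    ex.upper_bound = -abs(uptake)
    if co2_open and "EX_co2_e" in model.reactions:
        model.reactions.EX_co2_e.lower_bound = -1000.0
    sol = model.optimize()
    if sol.status != "optimal":
        raise RuntimeError(f"genome-scale FBA not optimal: {sol.status}")
    return float(sol.objective_value), dict(sol.fluxes)
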