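"""Flux balance analysis on :class:`~c1flux.network.MetabolicModel`.

Solves max-objective LPs with scipy's HiGHS backend, resolves alternate
optima by a parsimonious secondary LP (minimize total |v| at the fixed
optimum), and provides yield and flux-normalization helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicModel

__all__ = [
    "FluxConstraintSet",
    "FluxDistribution",
    "solve_fba",
    "theoretical_yield",
    "normalize_fluxes",
]

FEAS_TOL = 1e-9


@dataclass
class FluxConstraintSet:
    """Uptake / exchange constraints applied on top of model bounds.

    ``substrate_uptakes`` maps an uptake reaction id (or substrate
    metabolite id with an ``EX_<id>`` uptake reaction) to either a fixed
    rate or a ``(lo, hi)`` pair, in mmol gCDW^-1 h^-1.
    """

    substrate_uptakes: dict[str, float | tuple[float, float]] = field(default_factory=dict)
    gas_phase: tuple[float, float] | None = None  # CO2 exchange bounds
    maintenance: float | None = None  # NGAM override, mmol gCDW^-1 h^-1

    def resolve(self, model: MetabolicModel) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for key, val in self.substrate_uptakes.items():
            rid = key if model.has_reaction(key) else f"EX_{key}"
            if not model.has_reaction(rid):
                raise KeyError(f"no uptake reaction for {key!r}")
            if isinstance(val, (tuple, list)):
                lo, hi = float(val[0]), float(val[1])
            else:
                lo = hi = float(val)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{key}: uptake bounds must be finite")
            out[rid] = (lo, hi)
        if self.gas_phase is not None:
            out["EX_co2"] = (float(self.gas_phase[0]), float(self.gas_phase[1]))
        if self.maintenance is not None:
            out["NGAM"] = (float(self.maintenance), float(self.maintenance))
        return out


@dataclass
class FluxDistribution:
    v: dict[str, float]
    mu: float
    status: str  # optimal | infeasible | unbounded | failed
    objective_id: str = "biomass"
    normalized: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> float:
        return self.v[rid]


def _apply_constraints(model: MetabolicModel,
                       constraints: FluxConstraintSet | None) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = model.bounds_array()
    if constraints is not None:
        rids = [r.id for r in model.reactions]
        idx = {rid: j for j, rid in enumerate(rids)}
        for rid, (a, b) in constraints.resolve(model).items():
            j = idx[rid]
            rlo, rhi = model.reactions[j].bounds
            if (rlo == rhi == 0.0 and (a != 0.0 or b != 0.0)
                    and not rid.startswith(("EX_", "NGAM"))):
                raise ValueError(f"{rid}: fixed uptake outside knocked-out bounds")
            lo[j], hi[j] = a, b
        for j in range(len(rids)):
            if lo[j] > hi[j]:
                raise ValueError(f"{rids[j]}: constraint bounds inverted")
    return lo, hi


def solve_fba(model: MetabolicModel,
              constraints: FluxConstraintSet | None = None,
              objective: str | None = None,
              parsimonious: bool = True) -> FluxDistribution:
    """Maximize ``objective`` (default: model biomass) subject to S v = 0.

    With ``parsimonious=True`` a secondary LP minimizes the total
    absolute flux at the fixed optimal objective so that reported flux
    maps are deterministic across alternate optima.
    """
    objective = objective or model.biomass_reaction_id
    if not model.has_reaction(objective):
        raise KeyError(f"objective reaction {objective!r} not in model")
    S = model.S
    lo, hi = _apply_constraints(model, constraints)
    n = S.shape[1]
    rids = [r.id for r in model.reactions]
    j_obj = rids.index(objective)

    c = np.zeros(n)
    c[j_obj] = -1.0  # linprog minimizes
    bounds = list(zip(lo, hi))
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 2:
        return FluxDistribution(v={}, mu=float("nan"), status="infeasible",
                                objective_id=objective)
    if res.status == 3:
        return FluxDistribution(v={}, mu=float("inf"), status="unbounded",
                                objective_id=objective)
    if res.status != 0:
        return FluxDistribution(v={}, mu=float("nan"), status="failed",
                                objective_id=objective)

    opt = -res.fun
    x = res.x
    if parsimonious:
        # min sum t_j  s.t.  t_j >= v_j, t_j >= -v_j, v_obj = opt, S v = 0
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
        lo2 = lo.copy()
        hi2 = hi.copy()
        lo2[j_obj] = hi2[j_obj] = opt
        A_ub = np.vstack([
            np.hstack([np.eye(n), -np.eye(n)]),
            np.hstack([-np.eye(n), -np.eye(n)]),
        ])
        b_ub = np.zeros(2 * n)
        bounds2 = list(zip(lo2, hi2)) + [(0.0, None)] * n
        res2 = linprog(c2, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                       A_ub=A_ub, b_ub=b_ub, bounds=bounds2, method="highs")
        if res2.status == 0:
            x = res2.x[:n]

    v = {rid: float(x[j]) for j, rid in enumerate(rids)}
    mu = float(v[model.biomass_reaction_id]) if model.has_reaction(
        model.biomass_reaction_id) else float("nan")
    resid = float(np.max(np.abs(S @ x))) if n else 0.0
    scale = max(1.0, float(np.max(np.abs(x))) if n else 1.0)
    if resid / scale > 1e-8:
        return FluxDistribution(v=v, mu=mu, status="failed", objective_id=objective)
    return FluxDistribution(v=v, mu=mu, status="optimal", objective_id=objective)


def _uptake_reaction(model: MetabolicModel, substrate: str) -> str:
    rid = substrate if model.has_reaction(substrate) else f"EX_{substrate}"
    if not model.has_reaction(rid):
        raise KeyError(f"substrate {substrate!r} is not exchangeable in this model")
    return rid


def theoretical_yield(model: MetabolicModel, substrate: str,
                      uptake: float = 10.0,
                      constraints: FluxConstraintSet | None = None) -> float:
    """Maximal biomass yield in gCDW per mol substrate.

    The biomass drain is scaled so that one flux unit corresponds to one
    gCDW per hour; the yield is therefore mu_max / q_S * 1000.
    """
    if uptake <= 0:
        raise ValueError("substrate uptake must be positive for a yield")
    rid = _uptake_reaction(model, substrate)
    cs = FluxConstraintSet(substrate_uptakes=dict(constraints.substrate_uptakes)
                           if constraints else {},
                           gas_phase=constraints.gas_phase if constraints else None,
                           maintenance=constraints.maintenance if constraints else None)
    cs.substrate_uptakes[rid] = float(uptake)
    fd = solve_fba(model, cs, parsimonious=False)
    if fd.status != "optimal":
        raise ValueError(f"yield LP not optimal: {fd.status}")
    return max(0.0, fd.mu / uptake * 1000.0)


def normalize_fluxes(fd: FluxDistribution, model: MetabolicModel,
                     substrate: str) -> FluxDistribution:
    """Express every flux as a percentage of the substrate uptake flux."""
    rid = _uptake_reaction(model, substrate)
    uptake = fd.v.get(rid, 0.0)
    if uptake <= 0:
        raise ValueError(f"uptake flux through {rid} is not positive")
    fd.normalized = {r: 100.0 * val / uptake for r, val in fd.v.items()}
    return fd


def flux_report(fd: FluxDistribution, model: MetabolicModel,
                sig_figs: int = 3) -> "pd.DataFrame":  # noqa: F821
    """Tabular flux map (flux + normalized percentage, 3 sig figs)."""
    import pandas as pd

    def _round(x: float) -> float:
        if x == 0 or not np.isfinite(x):
            return x
        from math import floor, log10
        return round(x, -int(floor(log10(abs(x)))) + (sig_figs - 1))

    rows = []
    for r in model.reactions:
        val = fd.v.get(r.id, 0.0)
        rows.append({
            "reaction": r.id,
            "enzyme": r.enzyme_label,
            "flux": _round(val),
            "percent_of_uptake": _round(fd.normalized.get(r.id, float("nan")))
            if fd.normalized else float("nan"),
        })
    return pd.DataFrame(rows)
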