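"""Synthetic data generation for every pipeline stage.

Growth runs follow lag -> exponential -> stationary dynamics with the
stationary onset set by substrate exhaustion through the biomass yield;
substrate decline mirrors biomass formation exactly before noise.  MID
datasets convolve simulated tracer MIDs with the natural-abundance
correction matrix of each fragment and add multiplicative noise.

All randomness flows through one explicitly seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .isotopes import (
    HYPOTHESES,
    FluxHypothesis,
    LabelingScenario,
    hypothesis_fluxes,
    simulate_labeling,
)
from .midcorr import DEFAULT_FRAGMENTS, FragmentSpec, build_correction_matrix, convolve_mid
from .network import MetabolicModel

__all__ = [
    "SimulationRecipe",
    "REGIME_DEFAULTS",
    "generate_growth_run",
    "generate_mid_dataset",
]

# Parameter scales for the three growth regimes (mM substrate, h^-1).
REGIME_DEFAULTS: dict[str, dict] = {
    "mixotroph": {
        "mu": 0.060, "od0": 0.05, "lag_h": 24.0, "od_to_cdw": 0.4,
        "substrates": {"formate": {"S0": 60.0, "Y_XS": 2.2},
                       "acetate": {"S0": 20.0, "Y_XS": 6.5}},
        "t_end": 120.0, "dt": 2.0,
    },
    "formatotroph": {
        "mu": 0.0248, "od0": 0.05, "lag_h": 20.0, "od_to_cdw": 0.4,
        "substrates": {"formate": {"S0": 80.0, "Y_XS": 1.38}},
        "t_end": 200.0, "dt": 2.0,
    },
    "methylotroph": {
        "mu": 0.0288, "od0": 0.05, "lag_h": 30.0, "od_to_cdw": 0.4,
        "substrates": {"methanol": {"S0": 300.0, "Y_XS": 4.49}},
        "t_end": 250.0, "dt": 2.0,
    },
}


@dataclass
class SimulationRecipe:
    """Everything needed to generate one reproducible growth run."""

    regime: str = "formatotroph"
    mu: float = 0.0248  # h^-1
    od0: float = 0.05
    lag_h: float = 20.0
    od_to_cdw: float = 0.4  # gCDW/L per OD unit
    substrates: dict[str, dict] = field(default_factory=dict)  # id -> {S0, Y_XS}
    t_end: float = 200.0
    dt: float = 2.0
    od_noise_sigma: float = 0.02  # multiplicative (log-normal)
    substrate_noise_sigma: float = 0.5  # additive, mM
    mid_noise_sigma: float = 0.02  # multiplicative
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if min(self.od_noise_sigma, self.substrate_noise_sigma,
               self.mid_noise_sigma) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not self.substrates:
            self.substrates = {
                k: dict(v)
                for k, v in REGIME_DEFAULTS[self.regime]["substrates"].items()}

    @classmethod
    def for_regime(cls, regime: str, seed: int = 0, **overrides) -> "SimulationRecipe":
        if regime not in REGIME_DEFAULTS:
            raise KeyError(f"unknown regime {regime!r}")
        d = REGIME_DEFAULTS[regime]
        kw = dict(regime=regime, mu=d["mu"], od0=d["od0"], lag_h=d["lag_h"],
                  od_to_cdw=d["od_to_cdw"],
                  substrates={k: dict(v) for k, v in d["substrates"].items()},
                  t_end=d["t_end"], dt=d["dt"], seed=seed)
        kw.update(overrides)
        return cls(**kw)

    def q_S(self, substrate: str) -> float:
        """Implied specific uptake rate, mmol gCDW^-1 h^-1."""
        return self.mu / self.substrates[substrate]["Y_XS"] * 1000.0


def generate_growth_run(recipe: SimulationRecipe) -> dict[str, pd.DataFrame]:
    """Simulate one growth run.

    Returns ``{"od": DataFrame(time_h, od600), "<substrate>":
    DataFrame(time_h, substrate_mM), ..., "truth": DataFrame}``.  The
    noiseless trajectories satisfy dX = Y_XS * dS exactly; noise is
    applied last.
    """
    t = np.arange(0.0, recipe.t_end + recipe.dt / 2, recipe.dt)
    X0 = recipe.od0 * recipe.od_to_cdw  # gCDW/L

    # Stationary onset: the first substrate to run out caps growth.
    t_stat = np.inf
    for sub, p in recipe.substrates.items():
        if p["S0"] <= 0:
            raise ValueError(f"{sub}: non-positive initial concentration")
        X_max = X0 + p["Y_XS"] * p["S0"] / 1000.0
        t_exhaust = recipe.lag_h + np.log(X_max / X0) / recipe.mu
        t_stat = min(t_stat, t_exhaust)

    t_growth = np.clip(t, recipe.lag_h, t_stat) - recipe.lag_h
    X = X0 * np.exp(recipe.mu * np.clip(t_growth, 0.0, None))

    rng = np.random.default_rng(recipe.seed)
    od_true = X / recipe.od_to_cdw
    od_noisy = od_true * np.exp(rng.normal(0.0, recipe.od_noise_sigma, size=t.shape))

    out: dict[str, pd.DataFrame] = {
        "od": pd.DataFrame({"time_h": t, "od600": od_noisy}),
    }
    truth_rows = [{"parameter": "mu", "value": recipe.mu},
                  {"parameter": "DT", "value": float(np.log(2) / recipe.mu)},
                  {"parameter": "lag_h", "value": recipe.lag_h},
                  {"parameter": "od_to_cdw", "value": recipe.od_to_cdw},
                  {"parameter": "t_stationary", "value": float(t_stat)}]
    for sub, p in recipe.substrates.items():
        S_true = p["S0"] - (X - X0) / p["Y_XS"] * 1000.0
        if np.any(S_true < -1e-9):
            S_true = np.clip(S_true, 0.0, None)
        S_noisy = S_true + rng.normal(0.0, recipe.substrate_noise_sigma,
                                      size=t.shape)
        S_noisy = np.clip(S_noisy, 0.0, None)
        out[sub] = pd.DataFrame({"time_h": t, "substrate_mM": S_noisy})
        truth_rows += [
            {"parameter": f"S0_{sub}", "value": p["S0"]},
            {"parameter": f"Y_XS_{sub}", "value": p["Y_XS"]},
            {"parameter": f"q_{sub}", "value": recipe.q_S(sub)},
        ]
    out["truth"] = pd.DataFrame(truth_rows)
    return out


def generate_mid_dataset(
    model: MetabolicModel,
    scenario: LabelingScenario,
    hypothesis: FluxHypothesis | str,
    fragments: Mapping[str, FragmentSpec] | None = None,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Emulate a raw (uncorrected) fragment-MID measurement.

    raw = natural-abundance convolution of the simulated tracer MID,
    perturbed multiplicatively and renormalized.  Ground truth MIDs are
    returned alongside for round-trip tests.
    """
    hyp = HYPOTHESES[hypothesis] if isinstance(hypothesis, str) else hypothesis
    fragments = dict(fragments or DEFAULT_FRAGMENTS)
    state = simulate_labeling(model, hypothesis_fluxes(model, scenario, hyp),
                              scenario)
    rng = np.random.default_rng(seed)

    raw_rows: list[dict] = []
    truth_rows: list[dict] = []
    for aa, spec in fragments.items():
        mid = state.mid(aa)
        C = build_correction_matrix(spec)
        raw = convolve_mid(mid, C)
        if noise_sigma > 0:
            raw = raw * np.exp(rng.normal(0.0, noise_sigma, size=raw.shape))
            raw = raw / raw.sum()
        raw_rows.append({"fragment": aa,
                         **{f"M{k}": raw[k] for k in range(len(raw))}})
        truth_rows.append({"fragment": aa,
                           **{f"M{k}": mid[k] for k in range(len(mid))}})
    return {"raw": pd.DataFrame(raw_rows), "truth": pd.DataFrame(truth_rows),
            "hypothesis": hyp.name}
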