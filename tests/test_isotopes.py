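import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c1flux.isotopes import (
    HYPOTHESES,
    SCENARIOS,
    IsotopomerState,
    LabelingScenario,
    discriminate_hypotheses,
    dominant_isotopomer,
    hypothesis_fluxes,
    mid_from_positional,
    predict_fingerprints,
    reverse_distribution,
    simulate_labeling,
)


# ---------------------------------------------------------------------------
# Brute-force oracle: dict-of-tuples fixed point, written independently of
# the numpy implementation (no shared helpers).
# ---------------------------------------------------------------------------

def oracle_fixed_point(model, fluxes, substrate_patterns, n_iter=2000):
    """Iterate the isotopomer balance map on explicit label tuples.

    ``substrate_patterns`` maps source metabolites to {tuple: prob}.
    Returns {metabolite: {tuple: prob}}.
    """
    ncarb = {m.id: m.n_carbons for m in model.metabolites if m.n_carbons}
    sym = {m.id for m in model.metabolites if m.symmetric}
    dists = {}
    for mid, n in ncarb.items():
        if mid in substrate_patterns:
            dists[mid] = dict(substrate_patterns[mid])
        else:
            dists[mid] = {tuple([0] * n): 1.0}

    active = []
    for r in model.reactions:
        f = fluxes.get(r.id, 0.0)
        if abs(f) < 1e-12 or r.atom_map is None:
            continue
        amap = r.atom_map if f > 0 else {d: s for s, d in r.atom_map.items()}
        active.append((abs(f), amap))

    for _ in range(n_iter):
        prod = {}
        wsum = {}
        for f, amap in active:
            subs = sorted({s for s, _ in amap})
            prods = sorted({p for _, (p, _) in amap.items()})
            for combo in itertools.product(*[dists[s].items() for s in subs]):
                w = f
                pat_by_sub = {}
                for s, (pat, pr) in zip(subs, combo):
                    w *= pr
                    pat_by_sub[s] = pat
                if w == 0:
                    continue
                out = {p: [0] * ncarb[p] for p in prods}
                for (s, i), (p, j) in amap.items():
                    out[p][j - 1] = pat_by_sub[s][i - 1]
                for p in prods:
                    key = tuple(out[p])
                    prod.setdefault(p, {}).setdefault(key, 0.0)
                    prod[p][key] += w
            for p in prods:
                wsum[p] = wsum.get(p, 0.0) + f
        new = {m: dict(d) for m, d in dists.items()}
        for p, d in prod.items():
            if p in substrate_patterns:
                continue
            total = wsum[p]
            mixed = {k: v / total for k, v in d.items()}
            if p in sym:
                rev = {}
                for k, v in mixed.items():
                    rev[tuple(reversed(k))] = rev.get(tuple(reversed(k)), 0.0) + v
                mixed = {k: 0.5 * (mixed.get(k, 0.0) + rev.get(k, 0.0))
                         for k in set(mixed) | set(rev)}
            new[p] = mixed
        dists = new
    return dists


def oracle_mid(dist, n):
    mid = [0.0] * (n + 1)
    for pat, p in dist.items():
        mid[sum(pat)] += p
    return np.array(mid)


def _bernoulli_patterns(fracs):
    n = len(fracs)
    out = {}
    for pat in itertools.product([0, 1], repeat=n):
        p = 1.0
        for bit, f in zip(pat, fracs):
            p *= f if bit else 1 - f
        out[pat] = p
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("hyp", sorted(HYPOTHESES))
    @pytest.mark.parametrize("scen_name", ["formatotrophic_12CO2",
                                           "formatotrophic_13CO2",
                                           "mixotrophic_13C"])
    def test_fixed_point_matches_bruteforce(self, formatotroph_model,
                                            scen_name, hyp):
        scen = SCENARIOS[scen_name]
        fluxes = hypothesis_fluxes(formatotroph_model, scen, HYPOTHESES[hyp])
        state = simulate_labeling(formatotroph_model, fluxes, scen)
        patterns = {sid: _bernoulli_patterns(fr)
                    for sid, fr in scen.substrate_labels.items()}
        oracle = oracle_fixed_point(formatotroph_model, fluxes, patterns,
                                    n_iter=1500)
        for met in ("gly", "ser", "pyr", "accoa", "oaa", "akg"):
            n = state.n_carbons[met]
            got = state.mid(met)
            want = oracle_mid(oracle[met], n)
            assert np.max(np.abs(got - want)) < 1e-8, (met, got, want)

    def test_cyclic_tca_with_labeled_accoa_converges_to_fully_labeled(
            self, formatotroph_model):
        # Independent expectation: with fully labeled acetyl-CoA input the
        # 4-carbon pool's only fixed point is the all-labeled isotopomer
        # (enumerated over all 2^4 OAA patterns by the oracle).
        scen = LabelingScenario("ac_only", {"ac": (1.0, 1.0), "for": (0.0,),
                                            "co2": (0.0,)})
        fluxes = hypothesis_fluxes(formatotroph_model, scen,
                                   HYPOTHESES["cyclic_TCA"])
        state = simulate_labeling(formatotroph_model, fluxes, scen)
        oaa = state.mid("oaa")
        assert oaa[4] == pytest.approx(1.0, abs=1e-7)


class TestSimulateLabeling:
    def test_all_unlabeled_in_gives_unlabeled_out(self, formatotroph_model):
        state = simulate_labeling(
            formatotroph_model,
            hypothesis_fluxes(formatotroph_model, SCENARIOS["unlabeled"],
                              HYPOTHESES["anaplerosis"]),
            SCENARIOS["unlabeled"])
        for aa in ("Gly", "Ser", "Ala", "Asp", "Glu"):
            mid = state.mid(aa)
            assert mid[0] == pytest.approx(1.0, abs=1e-9)

    def test_pure_tracer_rglyp_positional_pattern(self, formatotroph_model):
        # 13C-formate (purity 1) + 12CO2: glycine C1 unlabeled / C2 labeled
        # with probability 1, serine M+2, pyruvate (alanine) M+2.
        scen = LabelingScenario("pure", {"for": (1.0,), "co2": (0.0,)})
        fluxes = hypothesis_fluxes(formatotroph_model, scen,
                                   HYPOTHESES["anaplerosis"])
        state = simulate_labeling(formatotroph_model, fluxes, scen)
        gly = state.positional["gly"]
        assert gly[0b10] == pytest.approx(1.0, abs=1e-9)  # C2 labeled only
        assert state.mid("Ser")[2] == pytest.approx(1.0, abs=1e-9)
        assert state.mid("Ala")[2] == pytest.approx(1.0, abs=1e-9)

    def test_distributions_are_normalized_and_mid_consistent(
            self, formatotroph_model):
        scen = SCENARIOS["formatotrophic_13CO2"]
        state = simulate_labeling(
            formatotroph_model,
            hypothesis_fluxes(formatotroph_model, scen, HYPOTHESES["cyclic_TCA"]),
            scen)
        for met, dist in state.positional.items():
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)
            # brute-force marginalization
            n = state.n_carbons[met]
            mid = np.zeros(n + 1)
            for pat in range(2 ** n):
                mid[bin(pat).count("1")] += dist[pat]
            assert np.allclose(mid, state.mid(met), atol=1e-12)

    def test_symmetry_of_succinate(self, formatotroph_model):
        scen = SCENARIOS["mixotrophic_13C"]
        state = simulate_labeling(
            formatotroph_model,
            hypothesis_fluxes(formatotroph_model, scen, HYPOTHESES["cyclic_TCA"]),
            scen)
        for met in ("succ", "fum"):
            d = state.positional[met]
            assert np.allclose(d, reverse_distribution(d, 4), atol=1e-9)

    def test_missing_atom_map_on_flux_carrying_reaction(self, formatotroph_model):
        fluxes = {"PurT": 1.0}  # carbon reaction without an atom map
        with pytest.raises(ValueError, match="atom map"):
            simulate_labeling(formatotroph_model, fluxes,
                              SCENARIOS["formatotrophic_12CO2"])

    def test_co2_monotonicity_for_aspartate(self, formatotroph_model):
        # Raising the CO2-pool 13C fraction never lowers the expected
        # label count of aspartate.
        prev = -1.0
        for f in np.linspace(0.0, 1.0, 6):
            scen = LabelingScenario("sweep", {"for": (0.99,), "co2": (float(f),)})
            state = simulate_labeling(
                formatotroph_model,
                hypothesis_fluxes(formatotroph_model, scen,
                                  HYPOTHESES["anaplerosis"]),
                scen)
            mid = state.mid("Asp")
            expected = float(np.dot(np.arange(len(mid)), mid))
            assert expected >= prev - 1e-9
            prev = expected

    def test_co2_reassimilation_enriches_glycine(self, formatotroph_model):
        base = LabelingScenario("r0", {"for": (1.0,), "co2": (0.0,)})
        rec = LabelingScenario("r03", {"for": (1.0,), "co2": (0.0,)},
                               co2_reassimilation=0.3)
        hyp = HYPOTHESES["anaplerosis"]
        f0 = hypothesis_fluxes(formatotroph_model, base, hyp)
        s0 = simulate_labeling(formatotroph_model, f0, base)
        s1 = simulate_labeling(formatotroph_model, f0, rec)
        # Recycled 13CO2 (from Fdh/decarboxylations) makes doubly labeled
        # glycine appear.
        assert s1.mid("Gly")[2] > s0.mid("Gly")[2] + 0.01

    def test_scenario_validation(self, formatotroph_model):
        bad = LabelingScenario("bad", {"for": (0.5, 0.5)})  # 1-carbon substrate
        with pytest.raises(ValueError, match="label fractions"):
            simulate_labeling(formatotroph_model, {"FtfL": 1.0}, bad)
        with pytest.raises(ValueError):
            LabelingScenario("bad2", {"for": (1.5,)})
        with pytest.raises(ValueError):
            LabelingScenario("bad3", {"for": (0.5,)}, co2_reassimilation=2.0)


class TestDominantIsotopomer:
    def test_unlabeled_is_zero(self, formatotroph_model):
        state = simulate_labeling(
            formatotroph_model,
            hypothesis_fluxes(formatotroph_model, SCENARIOS["unlabeled"],
                              HYPOTHESES["anaplerosis"]),
            SCENARIOS["unlabeled"])
        assert dominant_isotopomer(state, "Asp") == 0

    def test_fully_labeled_scenario_asp4_glu5(self, formatotroph_model):
        scen = SCENARIOS["formatotrophic_13CO2"]
        state = simulate_labeling(
            formatotroph_model,
            hypothesis_fluxes(formatotroph_model, scen, HYPOTHESES["anaplerosis"]),
            scen)
        assert dominant_isotopomer(state, "Asp") == 4
        assert dominant_isotopomer(state, "Glu") == 5

    def test_malate_synthase_route_gives_asp3(self, formatotroph_model):
        scen = SCENARIOS["mixotrophic_13C"]
        state = simulate_labeling(
            formatotroph_model,
            hypothesis_fluxes(formatotroph_model, scen,
                              HYPOTHESES["glyoxylate_malate_synthase"]),
            scen)
        assert dominant_isotopomer(state, "Asp") == 3

    def test_tie_breaks_toward_lower_count(self):
        state = IsotopomerState(
            positional={"x": np.array([0.5, 0.0, 0.0, 0.5])},
            n_carbons={"x": 2})
        assert dominant_isotopomer(state, "x") == 0

    def test_absent_metabolite_raises(self, formatotroph_model):
        state = IsotopomerState(positional={}, n_carbons={})
        with pytest.raises(KeyError):
            dominant_isotopomer(state, "Asp")


class TestPredictAndDiscriminate:
    def test_all_hypotheses_identical_without_tracer(self, formatotroph_model):
        pred = predict_fingerprints(formatotroph_model, SCENARIOS["unlabeled"],
                                    list(HYPOTHESES))
        mids = list(pred.values())
        for other in mids[1:]:
            for aa in mids[0]:
                assert np.allclose(mids[0][aa], other[aa], atol=1e-9)

    def test_cyclic_tca_mixotrophic_asp_m4(self, formatotroph_model):
        pred = predict_fingerprints(formatotroph_model,
                                    SCENARIOS["mixotrophic_13C"], ["cyclic_TCA"])
        mid = pred["cyclic_TCA"]["Asp"]
        assert int(np.argmax(mid)) == 4
        assert mid[4] > 0.6  # reported: ca. 70 % four-times labeled

    def test_self_match_scores_zero_and_ranks_first(self, formatotroph_model):
        scen = SCENARIOS["formatotrophic_12CO2"]
        pred = predict_fingerprints(formatotroph_model, scen, list(HYPOTHESES))
        ranking = discriminate_hypotheses(pred["anaplerosis"], pred)
        assert ranking[0][0] == "anaplerosis"
        assert ranking[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_observed_m2_dominated_asp_prefers_anaplerosis(
            self, formatotroph_model):
        # Reported aspartate pattern: dominant doubly labeled isotopomer.
        scen = SCENARIOS["formatotrophic_12CO2"]
        pred = predict_fingerprints(formatotroph_model, scen, list(HYPOTHESES))
        observed = {"Asp": np.array([0.10, 0.18, 0.62, 0.06, 0.04])}
        ranking = dict(discriminate_hypotheses(observed, pred))
        assert ranking["anaplerosis"] < ranking["cyclic_TCA"]

    def test_symmetric_tie_reported_with_equal_scores(self):
        a = {"h1": {"Asp": np.array([1.0, 0.0])}}
        b = {"h2": {"Asp": np.array([0.0, 1.0])}}
        observed = {"Asp": np.array([0.5, 0.5])}
        ranking = discriminate_hypotheses(observed, {**a, **b})
        assert ranking[0][1] == pytest.approx(ranking[1][1])

    def test_length_mismatch_raises(self, formatotroph_model):
        scen = SCENARIOS["formatotrophic_12CO2"]
        pred = predict_fingerprints(formatotroph_model, scen, ["anaplerosis"])
        with pytest.raises(ValueError, match="length"):
            discriminate_hypotheses({"Asp": np.array([1.0, 0.0])}, pred)

    def test_purity_does_not_flip_dominant_species(self, formatotroph_model):
        for scen_name in ("formatotrophic_12CO2", "formatotrophic_13CO2",
                          "mixotrophic_13C"):
            for hyp in HYPOTHESES:
                lo = SCENARIOS[scen_name]  # purity 0.99
                hi = LabelingScenario(
                    scen_name + "_pure",
                    {k: tuple(1.0 if f > 0 else 0.0 for f in v)
                     for k, v in lo.substrate_labels.items()})
                p_lo = predict_fingerprints(formatotroph_model, lo, [hyp])[hyp]
                p_hi = predict_fingerprints(formatotroph_model, hi, [hyp])[hyp]
                for aa in p_lo:
                    assert int(np.argmax(p_lo[aa])) == int(np.argmax(p_hi[aa]))


@settings(max_examples=25, deadline=None)
@given(f_for=st.floats(0.0, 1.0), f_co2=st.floats(0.0, 1.0))
def test_property_distributions_normalized(f_for, f_co2):
    from c1flux import build_core_model

    model = build_core_model("rG-F")
    scen = LabelingScenario("prop", {"for": (f_for,), "co2": (f_co2,)})
    fluxes = hypothesis_fluxes(model, scen, HYPOTHESES["anaplerosis"])
    state = simulate_labeling(model, fluxes, scen)
    for dist in state.positional.values():
        assert abs(dist.sum() - 1.0) < 1e-9
        assert np.all(dist >= -1e-12)
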