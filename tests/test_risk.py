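"""Risk index arithmetic, ranking, tier separation, pattern classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oxhotspot.errors import OxhotspotError
from oxhotspot.fixtures import generate_helix_structure, generate_synthetic_profile
from oxhotspot.profile import map_profile_to_structure, parse_hssp
from oxhotspot.risk import (
    DEFAULT_SCALE,
    RiskWeights,
    SusceptibilityScale,
    classify_pattern,
    lookup_susceptibility,
    oxidation_risk_index,
    rank_and_tier,
    risk_from_value,
    score_all,
    upper_tier,
)
from oxhotspot.structure import compute_features, parse_structure

# the published per-residue risk profile of the serpin benchmark
# (position, residue, printed index value), used as replay input
SERPIN_TABLE = [
    (358, "M", 0.95), (351, "M", 0.89), (226, "M", 0.73), (374, "M", 0.50),
    (242, "M", 0.46), (385, "M", 0.46), (63, "M", 0.40), (221, "M", 0.35),
    (220, "M", 0.35), (238, "W", 0.34), (160, "Y", 0.23), (194, "W", 0.21),
    (187, "Y", 0.21), (297, "Y", 0.20), (38, "Y", 0.19), (244, "Y", 0.18),
    (138, "Y", 0.18),
]

# the four peroxidase methionines with comparable printed values
PEROXIDASE_VALUES = [(247, "M", 0.69), (152, "M", 0.66), (265, "M", 0.63), (262, "M", 0.62)]


def unit_floats():
    return hst.floats(0.0, 1.0, allow_nan=False)


class TestSusceptibility:
    def test_default_scale_values(self):
        assert lookup_susceptibility("M") == 0.95
        assert lookup_susceptibility("C") == 1.00
        assert lookup_susceptibility("A") == 0.05  # baseline

    def test_custom_scale_override(self):
        scale = SusceptibilityScale(table={"M": 1.0}, prone_set=frozenset("M"), baseline=0.0)
        assert lookup_susceptibility("M", scale) == 1.0
        assert lookup_susceptibility("Y", scale) == 0.0

    def test_unknown_residue_rejected(self):
        with pytest.raises(OxhotspotError):
            lookup_susceptibility("X")

    def test_prone_set_must_dominate(self):
        with pytest.raises(ValueError):
            SusceptibilityScale(table={"M": 0.1, "L": 0.5})


class TestOxidationRiskIndex:
    def test_maximal_case(self):
        w = RiskWeights(0.25, 0.25, 0.25, 0.25)
        assert oxidation_risk_index(1, 1, 0, 1, w) == pytest.approx(1.0)

    def test_minimal_case(self):
        assert oxidation_risk_index(0, 0, 1, 0) == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        # independent arithmetic: 0.30·0.8 + 0.30·0.95 + 0.15·(1−0.26) + 0.25·1
        #                       = 0.24 + 0.285 + 0.111 + 0.25 = 0.886
        w = RiskWeights(0.30, 0.30, 0.15, 0.25)
        assert oxidation_risk_index(0.8, 0.95, 0.26, 1.0, w) == pytest.approx(0.886, abs=1e-12)

    def test_factor_domain_enforced(self):
        with pytest.raises(OxhotspotError):
            oxidation_risk_index(1.2, 0, 0, 0)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            RiskWeights(-0.1, 0.5, 0.3, 0.3)
        with pytest.raises(ValueError):
            RiskWeights(0, 0, 0, 0)
        assert RiskWeights(1, 1, 1, 1).normalized().is_normalized

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(E=unit_floats(), C=unit_floats(), K=unit_floats(), S=unit_floats(),
           raw=hst.lists(hst.floats(0.01, 10.0), min_size=4, max_size=4))
    def test_bounded_for_normalized_weights(self, E, C, K, S, raw):
        w = RiskWeights(*raw).normalized()
        assert 0.0 <= oxidation_risk_index(E, C, K, S, w) <= 1.0 + 1e-12

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(E=unit_floats(), C=unit_floats(), K=unit_floats(), S=unit_floats())
    def test_monotonicities(self, E, C, K, S):
        w = RiskWeights(0.3, 0.3, 0.15, 0.25)
        base = oxidation_risk_index(E, C, K, S, w)
        eps = 1e-3
        if E <= 1 - eps:
            assert oxidation_risk_index(E + eps, C, K, S, w) > base
        if C <= 1 - eps:
            assert oxidation_risk_index(E, C + eps, K, S, w) > base
        if S <= 1 - eps:
            assert oxidation_risk_index(E, C, K, S + eps, w) > base
        if K <= 1 - eps:
            assert oxidation_risk_index(E, C, K + eps, S, w) < base


class TestScoreAll:
    def pipeline_inputs(self, seq, conservation, sites=(), seed=0):
        residues = parse_structure(generate_helix_structure(seq), "A")
        features = compute_features(residues, {("A", p, "") for p in sites})
        text, _ = generate_synthetic_profile(seq, conservation, seed=seed)
        profile = parse_hssp(text)
        mapping = map_profile_to_structure(profile, residues)
        return features, profile, mapping

    def test_scores_reproduce_index_equation(self, scenario):
        from oxhotspot.risk import DEFAULT_WEIGHTS

        residues = parse_structure(scenario.structure_text, "A")
        features = compute_features(residues, {("A", 7, "")})
        profile = parse_hssp(scenario.profile_text)
        mapping = map_profile_to_structure(profile, residues)
        for r in score_all(features, profile, mapping):
            assert r.ori == pytest.approx(
                oxidation_risk_index(r.E, r.C, r.K, r.S, DEFAULT_WEIGHTS), abs=1e-12
            )

    def test_all_ala_prone_only_is_empty(self):
        features, profile, mapping = self.pipeline_inputs("AAAAAA", [0.8] * 6)
        assert score_all(features, profile, mapping) == []

    def test_prone_only_flag_controls_selection(self):
        features, profile, mapping = self.pipeline_inputs("AAMAAY", [0.8] * 6)
        prone = score_all(features, profile, mapping, prone_only=True)
        assert {r.aa for r in prone} == {"M", "Y"}
        everything = score_all(features, profile, mapping, prone_only=False)
        assert len(everything) == 6

    def test_hand_tabulated_toy(self):
        # 5-residue toy; expected values computed by hand from the stored
        # factors with default weights (0.30, 0.30, 0.15, 0.25)
        from oxhotspot.structure import StructuralFeatures
        from oxhotspot.profile import EvolutionaryProfile, ProfilePosition, SeqStructMapping

        rows = [
            # (resnum, aa, E, K, S); C comes from the default scale
            (1, "M", 0.80, 0.10, 1.00),
            (2, "C", 0.10, 0.90, 0.00),
            (3, "Y", 0.50, 0.50, 0.50),
            (4, "W", 0.00, 1.00, 0.20),
            (5, "M", 1.00, 0.00, 0.00),
        ]
        features = {
            ("A", n, ""): StructuralFeatures(("A", n, ""), aa, 0.0, E, "C", None, S)
            for n, aa, E, K, S in rows
        }
        profile = EvolutionaryProfile(
            [ProfilePosition(n, aa, {aa: K}) for n, aa, E, K, S in rows]
        )
        mapping = SeqStructMapping({n: ("A", n, "") for n, *_ in rows}, 1.0, 0)
        got = {r.residue[1]: r.ori for r in score_all(features, profile, mapping)}
        expected = {
            1: 0.30 * 0.80 + 0.30 * 0.95 + 0.15 * 0.90 + 0.25 * 1.00,  # 0.9100
            2: 0.30 * 0.10 + 0.30 * 1.00 + 0.15 * 0.10 + 0.25 * 0.00,  # 0.3450
            3: 0.30 * 0.50 + 0.30 * 0.60 + 0.15 * 0.50 + 0.25 * 0.50,  # 0.5300
            4: 0.30 * 0.00 + 0.30 * 0.70 + 0.15 * 0.00 + 0.25 * 0.20,  # 0.2600
            5: 0.30 * 1.00 + 0.30 * 0.95 + 0.15 * 1.00 + 0.25 * 0.00,  # 0.7350
        }
        for n, ori in expected.items():
            assert got[n] == pytest.approx(ori, abs=1e-12)

    def test_missing_profile_position_gets_conservative_k(self):
        features, profile, mapping = self.pipeline_inputs("AAMAAM", [0.8] * 6)
        del mapping.pairs[3]
        scored = {r.residue[1]: r for r in score_all(features, profile, mapping)}
        assert scored[3].k_missing and scored[3].K == 1.0
        assert not scored[6].k_missing


class TestRankAndTier:
    def test_serpin_replay_order_and_tier(self):
        risks = [risk_from_value(p, aa, ori) for p, aa, ori in SERPIN_TABLE]
        ranked = rank_and_tier(risks, gap_delta=0.15)
        assert [r.residue[1] for r in ranked[:3]] == [358, 351, 226]
        assert [r.residue[1] for r in upper_tier(ranked)] == [358, 351]
        assert all(r.tier == "lower" for r in ranked[2:])

    def test_tie_breaks_by_lower_resnum(self):
        risks = [risk_from_value(p, aa, ori) for p, aa, ori in SERPIN_TABLE]
        ranked = rank_and_tier(risks)
        order = [r.residue[1] for r in ranked]
        assert order.index(242) < order.index(385)  # equal 0.46

    def test_tie_breaks_by_susceptibility_first(self):
        risks = [risk_from_value(10, "Y", 0.5), risk_from_value(5, "W", 0.5)]
        ranked = rank_and_tier(risks)
        assert ranked[0].aa == "W"  # C(W)=0.70 > C(Y)=0.60 despite higher resnum

    def test_single_residue_has_no_upper_tier(self):
        ranked = rank_and_tier([risk_from_value(1, "M", 0.9)])
        assert ranked[0].rank == 1
        assert ranked[0].tier is None

    def test_ranks_are_permutation(self):
        risks = [risk_from_value(p, aa, ori) for p, aa, ori in SERPIN_TABLE]
        ranked = rank_and_tier(risks)
        assert sorted(r.rank for r in ranked) == list(range(1, len(risks) + 1))

    def test_empty_input_rejected(self):
        with pytest.raises(OxhotspotError):
            rank_and_tier([])

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(oris=hst.lists(hst.floats(0, 1), min_size=2, max_size=12),
           delta=hst.floats(0.01, 0.5))
    def test_tier_is_prefix_and_cut_moves_down_with_delta(self, oris, delta):
        # The upper tier is always a prefix of the ranking. Raising the gap
        # threshold disqualifies gaps, so the first qualifying gap (the tier
        # cut) can only move further down the ranking or disappear.
        risks = [risk_from_value(i + 1, "M", o) for i, o in enumerate(oris)]
        ranked = rank_and_tier(risks, delta)
        tiers = [r.tier for r in ranked]
        if "upper" in tiers:
            k = tiers.index("lower") if "lower" in tiers else len(tiers)
            assert all(t == "upper" for t in tiers[:k])
            assert all(t == "lower" for t in tiers[k:])
        wider = upper_tier(rank_and_tier(risks, min(1.0, delta + 0.1)))
        narrow = upper_tier(ranked)
        if wider and narrow:
            assert len(wider) >= len(narrow)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(scalefac=hst.floats(0.1, 10.0),
           rows=hst.lists(hst.tuples(unit_floats(), unit_floats(), unit_floats(), unit_floats()),
                          min_size=2, max_size=8))
    def test_rank_invariant_under_weight_rescaling(self, scalefac, rows):
        w = RiskWeights(0.3, 0.3, 0.15, 0.25)
        ws = RiskWeights(*(x * scalefac for x in w.as_tuple()))
        def ranked_ids(weights):
            risks = [
                risk_from_value(i + 1, "M", oxidation_risk_index(E, C, K, S, weights))
                for i, (E, C, K, S) in enumerate(rows)
            ]
            return [r.residue for r in rank_and_tier(risks)]
        assert ranked_ids(w) == ranked_ids(ws)


class TestClassifyPattern:
    def test_narrow_range_is_distributed(self):
        risks = [risk_from_value(p, aa, ori) for p, aa, ori in PEROXIDASE_VALUES]
        assert classify_pattern(risks, gap_delta=0.15) == "distributed"

    def test_separated_pair_is_dominant(self):
        risks = [risk_from_value(p, aa, ori) for p, aa, ori in SERPIN_TABLE]
        assert classify_pattern(risks, gap_delta=0.15) == "dominant"

    def test_maximal_gap_is_dominant(self):
        risks = [risk_from_value(1, "M", 1.0), risk_from_value(2, "M", 0.0)]
        assert classify_pattern(risks) == "dominant"

    def test_large_upper_tier_is_distributed(self):
        oris = [0.9, 0.88, 0.86, 0.4]
        risks = [risk_from_value(i + 1, "M", o) for i, o in enumerate(oris)]
        assert classify_pattern(risks, gap_delta=0.15, max_dominant=2) == "distributed"

    def test_single_residue_undefined(self):
        assert classify_pattern([risk_from_value(1, "M", 0.9)]) == "undefined"


def test_planted_hotspot_wins_for_all_positive_weights(scenario):
    """The planted hotspot beats the protected residue on every factor, so
    its rank-1 position must be independent of the (positive) weights."""
    residues = parse_structure(scenario.structure_text, "A")
    features = compute_features(residues, {("A", 7, "")})
    profile = parse_hssp(scenario.profile_text)
    mapping = map_profile_to_structure(profile, residues)
    rng = np.random.default_rng(123)
    for _ in range(100):
        w = RiskWeights(*rng.uniform(0.05, 1.0, size=4)).normalized()
        ranked = rank_and_tier(
            score_all(features, profile, mapping, DEFAULT_SCALE, w)
        )
        assert ranked[0].residue == scenario.hotspot
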