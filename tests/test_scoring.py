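"""Feature weights, multiplicity/positional/combined scores, baselines."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from archsim.graph import LayerPath, ResolvedArchitecture
from archsim.model import FeatureCountTable, ScoringParams
from archsim.scoring import (
    compute_weights,
    fas_score,
    multiplicity_score,
    positional_score,
    resolve_by_evalue,
    score_resolved_pair,
    score_unresolved,
)
from archsim.synthetic import random_pair
from _oracles import literal_ms, literal_ps, literal_weights
from conftest import make_architecture, make_instance


def resolved(protein_id, length, instances):
    """Wrap instances as a single-realization architecture (no conflicts assumed)."""
    paths = {}
    for inst in instances:
        paths.setdefault(inst.layer_id, []).append(inst)
    return ResolvedArchitecture(
        protein_id,
        length,
        {
            lid: LayerPath(lid, sorted(v, key=lambda i: (i.start, i.end)))
            for lid, v in paths.items()
        },
    )


class TestWeights:
    def test_uniform(self):
        w = compute_weights({"A", "B", "C", "D"}, None, ScoringParams())
        assert all(v == pytest.approx(0.25) for v in w.weights.values())

    def test_ln_symmetry(self):
        counts = FeatureCountTable({"A": 1, "B": 1})
        w = compute_weights({"A", "B"}, counts, ScoringParams(weighting="ln"))
        assert w["A"] == pytest.approx(0.5)
        assert w["B"] == pytest.approx(0.5)

    def test_ln_rare_vs_common(self):
        """Literal-formula check: o=(1, 100) under the ln transform."""
        counts = FeatureCountTable({"A": 1, "B": 100})
        w = compute_weights({"A", "B"}, counts, ScoringParams(weighting="ln"))
        assert w["A"] == pytest.approx(0.8486, abs=1e-4)
        assert w["B"] == pytest.approx(0.1514, abs=1e-4)
        lit = literal_weights({"A": 1, "B": 100}, "ln")
        assert w["A"] == pytest.approx(lit["A"], abs=1e-12)
        assert w["B"] == pytest.approx(lit["B"], abs=1e-12)

    @pytest.mark.parametrize("scheme", ["ln", "linear", "log10", "root4", "root8"])
    def test_all_schemes_match_literal_formula(self, scheme):
        abundances = {"A": 3, "B": 250, "C": 17, "D": 9999}
        counts = FeatureCountTable(abundances)
        w = compute_weights(
            set(abundances), counts, ScoringParams(weighting=scheme)
        )
        lit = literal_weights(abundances, scheme)
        for t in abundances:
            assert w[t] == pytest.approx(lit[t], abs=1e-12)

    @pytest.mark.parametrize("scheme", ["ln", "linear", "log10", "root4", "root8"])
    def test_rarer_types_weigh_more(self, scheme):
        counts = FeatureCountTable({"rare": 2, "mid": 200, "common": 20000})
        w = compute_weights(
            {"rare", "mid", "common"}, counts, ScoringParams(weighting=scheme)
        )
        assert w["rare"] > w["mid"] > w["common"]

    def test_linear_punishes_abundance_hardest(self):
        """The linear transform gives abundant features the lowest relative
        weight and root8 the highest."""
        counts = FeatureCountTable({"rare": 1, "common": 10000})
        by_scheme = {
            s: compute_weights(
                {"rare", "common"}, counts, ScoringParams(weighting=s)
            )["common"]
            for s in ("linear", "log10", "ln", "root4", "root8")
        }
        others = {s: v for s, v in by_scheme.items() if s not in ("linear", "root8")}
        assert by_scheme["linear"] < min(others.values())
        assert by_scheme["root8"] > max(others.values())

    def test_min_weight_floor_applied_and_sum_kept(self):
        counts = FeatureCountTable({"tm": 50000, "A": 5, "B": 7})
        params = ScoringParams(weighting="ln", min_weights={"tm": 0.3})
        w = compute_weights({"tm", "A", "B"}, counts, params)
        assert w["tm"] >= 0.3
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)
        # unfloored types keep their relative proportions
        unconstrained = compute_weights(
            {"tm", "A", "B"}, counts, ScoringParams(weighting="ln")
        )
        ratio = unconstrained["A"] / unconstrained["B"]
        assert w["A"] / w["B"] == pytest.approx(ratio, rel=1e-9)

    def test_min_weights_summing_to_one_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(min_weights={"a": 0.6, "b": 0.4})

    def test_empty_type_set_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(set(), None, ScoringParams())

    def test_missing_count_falls_back_to_one(self, caplog):
        counts = FeatureCountTable({"A": 100})
        with caplog.at_level("WARNING"):
            w = compute_weights({"A", "B"}, counts, ScoringParams(weighting="ln"))
        assert w["B"] > w["A"]  # missing type gets the maximal (count-1) weight

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(list("ABCDEFG")),
            st.integers(min_value=1, max_value=10**6),
            min_size=1,
        ),
        st.sampled_from(["uniform", "ln", "linear", "log10", "root4", "root8"]),
    )
    def test_weights_always_sum_to_one(self, abundances, scheme):
        counts = FeatureCountTable(abundances)
        w = compute_weights(
            set(abundances), counts, ScoringParams(weighting=scheme)
        )
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v > 0 for v in w.weights.values())


def _unit_weight(type_ids):
    return compute_weights(set(type_ids), None, ScoringParams())


class TestMultiplicityScore:
    def test_identical_architectures_score_one(self):
        ref = resolved("r", 100, [make_instance("A", 10, 30), make_instance("B", 50, 70)])
        assert multiplicity_score(ref, ref, _unit_weight(["A", "B"])) == pytest.approx(1.0)

    def test_reference_duplication_halves_the_term(self):
        ref = resolved("r", 100, [make_instance("A", 10, 30), make_instance("A", 50, 70)])
        tgt = resolved("t", 100, [make_instance("A", 10, 30)])
        # N_S=2, N_O=1: min(2*1/4, 1) = 0.5
        assert multiplicity_score(ref, tgt, _unit_weight(["A"])) == pytest.approx(0.5)

    def test_target_surplus_saturates_at_one(self):
        ref = resolved("r", 100, [make_instance("A", 10, 30)])
        tgt = resolved(
            "t", 100, [make_instance("A", s, s + 20) for s in (10, 40, 70)]
        )
        assert multiplicity_score(ref, tgt, _unit_weight(["A"])) == pytest.approx(1.0)

    def test_matches_literal_formula(self):
        ref = resolved(
            "r",
            200,
            [make_instance("A", 10, 30), make_instance("A", 60, 80),
             make_instance("B", 100, 140), make_instance("C", 150, 170)],
        )
        tgt = resolved(
            "t", 200, [make_instance("A", 12, 32), make_instance("B", 90, 130)]
        )
        w = _unit_weight(["A", "B", "C"])
        expected = literal_ms({"A": 2, "B": 1, "C": 1}, {"A": 1, "B": 1}, w.weights)
        assert multiplicity_score(ref, tgt, w) == pytest.approx(expected, abs=1e-12)


class TestPositionalScore:
    def test_identical_positions_score_one(self):
        ref = resolved("r", 100, [make_instance("A", 10, 30)])
        tgt = resolved("t", 100, [make_instance("A", 10, 30)])
        assert positional_score(ref, tgt, _unit_weight(["A"])) == pytest.approx(1.0)

    def test_nearest_instance_matching(self):
        # ref midpoint 0.30; targets at 0.50 and 0.95 -> nearest distance 0.20
        ref = resolved("r", 100, [make_instance("A", 25, 35)])
        tgt = resolved(
            "t", 100, [make_instance("A", 45, 55), make_instance("A", 90, 100)]
        )
        assert positional_score(ref, tgt, _unit_weight(["A"])) == pytest.approx(0.8)

    def test_type_absent_from_target_contributes_zero(self):
        ref = resolved("r", 100, [make_instance("A", 25, 35)])
        tgt = resolved("t", 100, [make_instance("B", 25, 35)])
        assert positional_score(ref, tgt, _unit_weight(["A"])) == 0.0

    def test_half_integer_midpoints_kept_exact(self):
        # (10+29)/2 = 19.5: no rounding before dividing by length
        ref = resolved("r", 100, [make_instance("A", 10, 29)])
        tgt = resolved("t", 100, [make_instance("A", 11, 30)])
        assert positional_score(ref, tgt, _unit_weight(["A"])) == pytest.approx(
            1.0 - 1.0 / 100
        )

    def test_matches_literal_formula(self):
        ref = resolved(
            "r", 200,
            [make_instance("A", 10, 30), make_instance("A", 150, 190),
             make_instance("B", 90, 110)],
        )
        tgt = resolved(
            "t", 250,
            [make_instance("A", 30, 60), make_instance("B", 200, 240)],
        )
        w = _unit_weight(["A", "B"])
        expected = literal_ps(
            {"A": [20 / 200, 170 / 200], "B": [100 / 200]},
            {"A": [45 / 250], "B": [220 / 250]},
            w.weights,
        )
        assert positional_score(ref, tgt, w) == pytest.approx(expected, abs=1e-12)


class TestCombinedScore:
    def test_perfect_pair(self, simple_pair):
        ref, tgt = simple_pair
        res = fas_score(
            resolved("r", 200, ref.instances()), resolved("t", 200, tgt.instances())
        )
        assert res.fas == pytest.approx(1.0)

    def test_linear_combination(self):
        # MS = 0.5 (A duplicated in ref), PS = 0.8 via a second type
        ref = resolved("r", 100, [make_instance("A", 10, 30), make_instance("A", 50, 70)])
        tgt = resolved("t", 100, [make_instance("A", 10, 30)])
        res = fas_score(ref, tgt, params=ScoringParams(alpha=0.7))
        assert res.ms == pytest.approx(0.5)
        assert res.fas == pytest.approx(0.7 * res.ms + 0.3 * res.ps, abs=1e-9)

    def test_disjoint_type_sets_score_zero(self):
        ref = resolved("r", 100, [make_instance("A", 10, 30)])
        tgt = resolved("t", 100, [make_instance("B", 10, 30)])
        res = fas_score(ref, tgt)
        assert res.fas == 0.0

    def test_empty_reference_flagged_not_raised(self):
        ref = ResolvedArchitecture("r", 100, {})
        tgt = resolved("t", 100, [make_instance("A", 10, 30)])
        res = fas_score(ref, tgt)
        assert res.fas == 0.0 and res.empty_reference

    def test_sub_architecture_scores_one_and_asymmetric(self):
        """S strictly contained in O with aligned relative midpoints:
        FAS(S, O) = 1 but FAS(O, S) < 1."""
        sub = resolved("s", 100, [make_instance("A", 20, 40)])
        sup = resolved(
            "o", 100,
            [make_instance("A", 20, 40), make_instance("B", 60, 90)],
        )
        assert fas_score(sub, sup).fas == pytest.approx(1.0)
        assert fas_score(sup, sub).fas < 1.0

    def test_losing_a_shared_type_never_helps(self):
        ref = resolved(
            "r", 100, [make_instance("A", 10, 30), make_instance("B", 50, 70)]
        )
        tgt_full = resolved(
            "t", 100, [make_instance("A", 10, 30), make_instance("B", 50, 70)]
        )
        tgt_lost = resolved("t", 100, [make_instance("A", 10, 30)])
        w = _unit_weight(["A", "B"])
        assert multiplicity_score(ref, tgt_lost, w) <= multiplicity_score(
            ref, tgt_full, w
        )
        assert fas_score(ref, tgt_lost).fas <= fas_score(ref, tgt_full).fas

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_scores_always_within_unit_interval(self, seed):
        ref_arch, tgt_arch = random_pair(seed)
        res = score_unresolved(ref_arch, tgt_arch)
        assert 0.0 <= res.ms <= 1.0 + 1e-12
        assert 0.0 <= res.ps <= 1.0 + 1e-12
        assert 0.0 <= res.fas <= 1.0 + 1e-12
        assert res.fas == pytest.approx(0.7 * res.ms + 0.3 * res.ps, abs=1e-9)


class TestEvalueResolution:
    def test_lowest_evalue_wins(self):
        arch = make_architecture(
            "p",
            100,
            [
                make_instance("A", 10, 60, evalue=1e-10),
                make_instance("B", 15, 65, evalue=1e-3),
            ],
        )
        res = resolve_by_evalue(arch, 0)
        assert res.type_ids() == {"A"}

    def test_non_overlapping_all_kept(self):
        arch = make_architecture(
            "p",
            100,
            [make_instance("A", 1, 40, evalue=1e-2), make_instance("B", 50, 90, evalue=1e-9)],
        )
        assert resolve_by_evalue(arch, 0).n_instances == 2

    def test_instances_without_evalue_rank_last(self):
        arch = make_architecture(
            "p",
            100,
            [make_instance("A", 10, 60, evalue=1e-5), make_instance("B", 15, 65)],
        )
        assert resolve_by_evalue(arch, 0).type_ids() == {"A"}

    def test_result_is_a_maximal_path(self):
        for seed in range(20):
            arch, _ = random_pair(seed)
            res = resolve_by_evalue(arch, 0)
            from archsim.graph import build_layer_graph, enumerate_layer_paths

            for lid, path in res.paths.items():
                g = build_layer_graph(arch, lid, 0)
                sigs = [
                    tuple((i.start, i.end, i.type_id) for i in p.selected)
                    for p in enumerate_layer_paths(g)
                ]
                assert tuple(
                    (i.start, i.end, i.type_id) for i in path.selected
                ) in sigs


class TestUnresolvedScoring:
    def test_non_redundant_equals_fixed_scoring(self, simple_pair):
        ref, tgt = simple_pair
        direct = fas_score(
            resolved("ref", 200, ref.instances()), resolved("tgt", 200, tgt.instances())
        )
        un = score_unresolved(ref, tgt)
        assert un.fas == pytest.approx(direct.fas, abs=1e-12)

    def test_redundant_triple_annotation_dilutes_ms(self):
        # three overlapping copies of A in ref, one in tgt: min(3*1/9, 1) = 1/3
        ref = make_architecture(
            "p", 100, [make_instance("A", 10 + k, 60 + k, evalue=1e-5) for k in range(3)]
        )
        tgt = make_architecture("q", 100, [make_instance("A", 10, 60, evalue=1e-5)])
        res = score_unresolved(ref, tgt)
        assert res.ms == pytest.approx(1 / 3)

    def test_empty_target_scores_zero(self):
        ref = make_architecture("p", 100, [make_instance("A", 10, 60)])
        tgt = make_architecture("q", 100, [])
        assert score_unresolved(ref, tgt).fas == 0.0
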