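import itertools
import math

import pytest

from decidiff.enrichment import EnrichmentTerm, propagate_annotations
from decidiff.errors import DomainError
from decidiff.formats import Annotation
from decidiff.reduction import (FunctionGroupMap, call_specificity,
                                classify_groups, default_function_groups,
                                information_content, reduce_terms,
                                term_similarity)


def _term(term_id, p):
    return EnrichmentTerm(term_id, p, 1, 1, 1, 1, frozenset())


class TestInformationContent:
    def test_full_coverage_term_has_zero_ic(self, diamond_ontology,
                                            diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        assert ic.ic["R"] == pytest.approx(0.0)

    def test_half_coverage_is_log_two(self, diamond_ontology):
        direct = {f"g{i}": frozenset({"E" if i < 5 else "A"})
                  for i in range(10)}
        ann = Annotation(direct, frozenset(direct))
        ic = information_content(diamond_ontology, ann)
        assert ic.ic["E"] == pytest.approx(math.log(2))

    def test_matches_counting_oracle(self, diamond_ontology,
                                     diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        prop = propagate_annotations(diamond_ontology, diamond_annotation)
        n = len(diamond_annotation.population)
        for term in diamond_ontology.terms:
            count = sum(term in terms for terms in prop.direct.values())
            if count:
                assert ic.ic[term] == pytest.approx(-math.log(count / n))
            else:
                assert term not in ic

    def test_parent_ic_never_exceeds_child(self, diamond_ontology,
                                           diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        for child, parent in diamond_ontology.graph.edges:
            if child in ic and parent in ic:
                assert ic.ic[parent] <= ic.ic[child] + 1e-12

    def test_empty_population_rejected(self, diamond_ontology):
        with pytest.raises(DomainError):
            information_content(diamond_ontology,
                                Annotation({}, frozenset()))


class TestSimilarity:
    def test_self_similarity_is_one(self, diamond_ontology,
                                    diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        assert term_similarity("D", "D", ic, diamond_ontology,
                               "lin") == pytest.approx(1.0)

    def test_root_only_common_ancestor_gives_zero(self, diamond_ontology,
                                                  diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        # A and E share only R (IC 0) and B... E is under B, A is not.
        assert term_similarity("A", "E", ic, diamond_ontology,
                               "lin") == pytest.approx(0.0)

    def test_matches_exhaustive_mica_oracle(self, diamond_ontology,
                                            diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        prop = propagate_annotations(diamond_ontology, diamond_annotation)
        n = len(diamond_annotation.population)

        def counts(term):
            return sum(term in terms for terms in prop.direct.values())

        terms = sorted(t for t in diamond_ontology.terms if t in ic)
        for t1, t2 in itertools.combinations_with_replacement(terms, 2):
            anc1 = diamond_ontology.ancestors(t1) | {t1}
            anc2 = diamond_ontology.ancestors(t2) | {t2}
            common = [t for t in anc1 & anc2 if counts(t)]
            denom = ic.ic[t1] + ic.ic[t2]
            if not common or denom == 0:
                expected_lin = 0.0
                expected_simrel = 0.0
            else:
                mica_ic = max(-math.log(counts(t) / n) for t in common)
                mica_freq = math.exp(-mica_ic)
                expected_lin = 2 * mica_ic / denom
                expected_simrel = expected_lin * (1 - mica_freq)
            assert term_similarity(t1, t2, ic, diamond_ontology, "lin") == \
                pytest.approx(expected_lin)
            assert term_similarity(t1, t2, ic, diamond_ontology, "simrel") \
                == pytest.approx(expected_simrel)

    def test_symmetry_and_simrel_below_lin(self, diamond_ontology,
                                           diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        terms = sorted(t for t in diamond_ontology.terms if t in ic)
        for t1, t2 in itertools.combinations(terms, 2):
            lin = term_similarity(t1, t2, ic, diamond_ontology, "lin")
            assert lin == pytest.approx(
                term_similarity(t2, t1, ic, diamond_ontology, "lin"))
            simrel = term_similarity(t1, t2, ic, diamond_ontology, "simrel")
            assert 0.0 <= simrel <= lin + 1e-12 <= 1.0 + 1e-12


class TestReduce:
    def test_dissimilar_terms_all_representatives(self, diamond_ontology,
                                                  diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        terms = [_term("A", 0.001), _term("E", 0.002)]
        reduced = reduce_terms(terms, ic, diamond_ontology, cutoff=0.5)
        assert reduced.representative_ids() == ["A", "E"]

    def test_duplicate_term_assigned_to_first(self, diamond_ontology,
                                              diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        terms = [_term("D", 0.001), _term("D", 0.002)]
        reduced = reduce_terms(terms, ic, diamond_ontology, cutoff=0.5)
        assert reduced.representative_ids() == ["D"]
        assert reduced.assigned_to == {"D": "D"}

    def test_matches_reference_greedy_sweep(self, diamond_ontology,
                                            diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        terms = [_term(t, p) for t, p in
                 [("D", 0.001), ("C", 0.002), ("A", 0.003), ("B", 0.004),
                  ("E", 0.005), ("R", 0.006)]]
        cutoff = 0.3
        reduced = reduce_terms(terms, ic, diamond_ontology, cutoff)
        # independent straightforward re-implementation of the sweep
        order = sorted(terms, key=lambda t: (t.p_value, -ic.ic[t.term_id],
                                             t.term_id))
        reps, assigned = [], {}
        for t in order:
            sims = [(term_similarity(t.term_id, r, ic, diamond_ontology,
                                     "simrel"), -i)
                    for i, r in enumerate(reps)]
            if sims and max(sims)[0] > cutoff:
                best = max(sims)
                assigned[t.term_id] = reps[-best[1]]
            else:
                reps.append(t.term_id)
        assert reduced.representative_ids() == reps
        assert reduced.assigned_to == assigned

    def test_deterministic_under_input_permutation(self, diamond_ontology,
                                                   diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        terms = [_term(t, 0.001) for t in ("E", "D", "B", "A")]
        a = reduce_terms(terms, ic, diamond_ontology, 0.4)
        b = reduce_terms(list(reversed(terms)), ic, diamond_ontology, 0.4)
        assert a.representative_ids() == b.representative_ids()

    def test_representatives_pairwise_below_cutoff(self, diamond_ontology,
                                                   diamond_annotation):
        ic = information_content(diamond_ontology, diamond_annotation)
        terms = [_term(t, p / 1000) for p, t in
                 enumerate(sorted(t for t in diamond_ontology.terms
                                  if t in ic), 1)]
        reduced = reduce_terms(terms, ic, diamond_ontology, 0.5)
        for r1, r2 in itertools.combinations(
                reduced.representative_ids(), 2):
            assert term_similarity(r1, r2, ic, diamond_ontology,
                                   "simrel") <= 0.5


class TestClassify:
    def test_substring_rule(self, diamond_ontology, diamond_annotation):
        import networkx as nx
        from decidiff.formats import Ontology
        g = nx.DiGraph()
        g.add_node("T:1", name="sprouting angiogenesis",
                   namespace="biological_process")
        onto = Ontology(g)
        groups = FunctionGroupMap(
            {"angiogenesis": {"ids": set(), "substrings": ["angiogenesis"]},
             "metabolism": {"ids": set(), "substrings": ["metabol"]}})
        from decidiff.reduction import ReducedTerms
        reduced = ReducedTerms([_term("T:1", 0.001)], {}, 0.5)
        out = classify_groups(reduced, groups, onto)
        assert [t.term_id for t in out["angiogenesis"]] == ["T:1"]
        assert out["metabolism"] == [] and out["unclassified"] == []

    def test_unmatched_term_unclassified(self, diamond_ontology):
        from decidiff.reduction import ReducedTerms
        groups = FunctionGroupMap(
            {"angiogenesis": {"ids": set(), "substrings": ["angiogenesis"]}})
        reduced = ReducedTerms([_term("D", 0.001)], {}, 0.5)
        out = classify_groups(reduced, groups, diamond_ontology)
        assert [t.term_id for t in out["unclassified"]] == ["D"]

    def test_first_matching_group_wins(self, diamond_ontology):
        import networkx as nx
        from decidiff.formats import Ontology
        from decidiff.reduction import ReducedTerms
        g = nx.DiGraph()
        g.add_node("T:1", name="insulin receptor signaling pathway",
                   namespace="biological_process")
        onto = Ontology(g)
        groups = FunctionGroupMap({
            "insulin signaling": {"ids": set(), "substrings": ["insulin"]},
            "signal transduction": {"ids": set(),
                                    "substrings": ["signaling pathway"]}})
        out = classify_groups(ReducedTerms([_term("T:1", 0.01)], {}, 0.5),
                              groups, onto)
        assert [t.term_id for t in out["insulin signaling"]] == ["T:1"]


class TestSpecificity:
    @staticmethod
    def _flags(up=(), down=()):
        return {s: {"up": s in up, "down": s in down}
                for s in ("cAMP", "cAMP+MPA", "MPA", "E2+MPA")}

    def test_insulin_pattern_is_mpa_specific(self):
        det = {"insulin signaling": self._flags(
            up=("MPA", "E2+MPA", "cAMP+MPA"))}
        assert call_specificity(det).labels["insulin signaling"] == \
            "MPA_specific"

    def test_angiogenesis_pattern_is_camp_specific(self):
        det = {"angiogenesis": self._flags(up=("cAMP", "cAMP+MPA"))}
        assert call_specificity(det).labels["angiogenesis"] == \
            "cAMP_specific"

    def test_all_four_detected_is_common(self):
        det = {"metabolism": self._flags(
            up=("cAMP", "cAMP+MPA"), down=("MPA", "E2+MPA"))}
        assert call_specificity(det).labels["metabolism"] == "common"

    def test_common_precedes_camp_specific(self):
        # detected everywhere, up under the cAMP pair: common wins
        det = {"g": self._flags(up=("cAMP", "cAMP+MPA", "MPA", "E2+MPA"))}
        assert call_specificity(det).labels["g"] == "common"

    def test_unmatched_pattern_is_other(self):
        det = {"g": self._flags(up=("cAMP",))}
        assert call_specificity(det).labels["g"] == "other"

    def test_missing_stimulus_rejected(self):
        with pytest.raises(DomainError):
            call_specificity({"g": {"cAMP": {"up": True, "down": False}}})

    def test_both_direction_mode_is_stricter(self):
        det = {"g": self._flags(up=("cAMP", "cAMP+MPA", "MPA", "E2+MPA"))}
        strict = call_specificity(det, common_mode="both")
        assert strict.labels["g"] != "common"


def test_default_group_map_covers_ten_groups():
    groups = default_function_groups()
    assert len(groups.names) == 10
    assert "insulin signaling" in groups.names
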