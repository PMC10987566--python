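"""Redundancy reduction of enriched terms and function-group classification.

Enriched GO terms are highly redundant; following the approach popularised
by the REVIGO service, terms are greedily clustered by information-content
based semantic similarity (SimRel by default, Lin selectable) with an
"allowed similarity" cutoff of 0.5: sweeping terms in ascending p-value
order, a term more similar than the cutoff to an already-kept
representative is assigned to it, otherwise it becomes a representative.

Representatives are then classified into named cellular-function groups
(angiogenesis, insulin signaling, ...) by a configurable rule map, and the
per-stimulus, per-direction detection pattern of each group is summarised
into a specificity label: a function detected under all four stimuli is
"common"; one detected in the up-regulated genes of both cAMP-using
stimuli (cAMP, cAMP+MPA) and in neither non-cAMP stimulus is
"cAMP_specific"; one detected in the up-regulated genes of all three
MPA-using stimuli (MPA, E2+MPA, cAMP+MPA) but not under cAMP alone is
"MPA_specific"; anything else is "other".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enrichment import EnrichmentTerm, propagate_annotations
from .errors import DomainError
from .formats import Annotation, Ontology

#: Canonical stimulus names, in reporting order.
STIMULI = ("cAMP", "cAMP+MPA", "MPA", "E2+MPA")
CAMP_STIMULI = ("cAMP", "cAMP+MPA")
MPA_STIMULI = ("MPA", "E2+MPA", "cAMP+MPA")

SPECIFICITY_LABELS = ("common", "cAMP_specific", "MPA_specific", "other")


# ---------------------------------------------------------------------------
# information content and semantic similarity
# ---------------------------------------------------------------------------

@dataclass
class TermIC:
    """Information content IC(t) = -ln(annotation frequency of t)."""

    ic: dict[str, float]
    freq: dict[str, float]
    population_size: int

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def information_content(ontology: Ontology, annotation: Annotation,
                        *, propagated: bool = False) -> TermIC:
    """Compute IC per term from a (propagated) annotation corpus.

    IC(t) = -ln(n_t / N) with n_t the number of population genes annotated
    to t after ancestry propagation and N the population size.  Terms with
    no annotated gene get no IC and are excluded from similarity
    computations.  IC is non-decreasing from parent to child, and a term
    annotating the whole population (typically the root) has IC 0.
    """
    if len(annotation.population) == 0:
        raise DomainError("empty population")
    if not propagated:
        annotation = propagate_annotations(ontology, annotation)
    counts: dict[str, int] = {}
    for terms in annotation.direct.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n = len(annotation.population)
    freq = {t: c / n for t, c in counts.items()}
    ic = {t: -math.log(f) for t, f in freq.items()}
    return TermIC(ic=ic, freq=freq, population_size=n)


def _mica(t1: str, t2: str, ic: TermIC, ontology: Ontology) -> str | None:
    """Common ancestor (terms included) with maximal IC, or None."""
    anc1 = ontology.ancestors(t1) | {t1}
    anc2 = ontology.ancestors(t2) | {t2}
    common = [t for t in anc1 & anc2 if t in ic]
    if not common:
        return None
    return max(common, key=lambda t: (ic.ic[t], t))


def term_similarity(
    t1: str,
    t2: str,
    ic: TermIC,
    ontology: Ontology,
    measure: str = "simrel",
) -> float:
    """Lin or SimRel similarity of two terms.

    Lin(t1, t2) = 2 IC(MICA) / (IC(t1) + IC(t2)) where MICA is the common
    ancestor with maximal IC; SimRel additionally down-weights generic
    ancestors: SimRel = Lin x (1 - p(MICA)) with p the annotation
    frequency.  Cross-namespace pairs have similarity 0, as does any pair
    whose ICs sum to 0.
    """
    if measure not in ("lin", "simrel"):
        raise DomainError(f"unknown similarity measure {measure!r}")
    for t in (t1, t2):
        if t not in ic:
            raise DomainError(f"term {t!r} has no information content")
    if ontology.namespace(t1) != ontology.namespace(t2):
        return 0.0
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0:
        return 0.0
    mica = _mica(t1, t2, ic, ontology)
    if mica is None:
        return 0.0
    lin = 2.0 * ic.ic[mica] / denom
    if measure == "lin":
        return lin
    return lin * (1.0 - ic.freq[mica])


# ---------------------------------------------------------------------------
# greedy reduction
# ---------------------------------------------------------------------------

@dataclass
class ReducedTerms:
    """Representatives plus the redundant -> representative assignment."""

    representatives: list[EnrichmentTerm]
    assigned_to: dict[str, str]
    cutoff: float

    def representative_ids(self) -> list[str]:
        return [t.term_id for t in self.representatives]


def reduce_terms(
    terms: Sequence[EnrichmentTerm],
    ic: TermIC,
    ontology: Ontology,
    cutoff: float = 0.5,
    measure: str = "simrel",
) -> ReducedTerms:
    """Greedy redundancy sweep in ascending p-value order.

    Ties in p-value are broken by larger IC, then lexicographic term id, so
    the output is deterministic regardless of input order.  A term whose
    similarity to any kept representative exceeds ``cutoff`` is assigned to
    the most similar one (earliest kept wins similarity ties); otherwise it
    becomes a representative itself.
    """
    ordered = sorted(
        terms,
        key=lambda t: (t.p_value, -ic.ic.get(t.term_id, 0.0), t.term_id),
    )
    representatives: list[EnrichmentTerm] = []
    assigned: dict[str, str] = {}
    for term in ordered:
        best_rep = None
        best_sim = -1.0
        for rep in representatives:
            sim = term_similarity(term.term_id, rep.term_id, ic, ontology,
                                  measure)
            if sim > best_sim:
                best_sim = sim
                best_rep = rep
        if best_rep is not None and best_sim > cutoff:
            assigned[term.term_id] = best_rep.term_id
        else:
            representatives.append(term)
    return ReducedTerms(representatives, assigned, cutoff)


# ---------------------------------------------------------------------------
# function groups
# ---------------------------------------------------------------------------

@dataclass
class FunctionGroupMap:
    """Ordered group -> matching rules (explicit ids, name substrings).

    A term matches a group if its id is listed or its lower-cased name
    contains any of the group's substrings; the first matching group in
    config order wins.
    """

    groups: dict[str, dict]  # name -> {"ids": set[str], "substrings": [str]}

    def __post_init__(self) -> None:
        for name, rules in self.groups.items():
            ids = rules.get("ids", set())
            subs = rules.get("substrings", [])
            if not ids and not subs:
                raise DomainError(f"group {name!r} has no rules")

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def match(self, term_id: str, term_name: str) -> str | None:
        lowered = term_name.lower()
        for group, rules in self.groups.items():
            if term_id in rules.get("ids", set()):
                return group
            if any(sub in lowered for sub in rules.get("substrings", [])):
                return group
        return None


def default_function_groups() -> FunctionGroupMap:
    """Ten cellular-function groups as name-substring rules.

    This is an editorial reconstruction of a manual classification: the
    original grouping of GO terms into cellular functions was curated by
    hand, so these keyword rules approximate it and can be replaced by a
    user-supplied config.
    """
    subs = {
        "cell morphology": ["morpholog", "cytoskeleton", "cell shape",
                            "adhesion", "extracellular matrix"],
        "signal transduction": ["signal transduction", "signaling pathway",
                                "signalling", "second messenger"],
        "cell proliferation": ["proliferation", "cell cycle", "cell division",
                               "mitotic"],
        "metabolism": ["metabol", "biosynthe", "catabol", "glycolys"],
        "differentiation": ["differentiation", "cell fate", "development"],
        "angiogenesis": ["angiogenesis", "vasculature", "blood vessel",
                         "vascular"],
        "inflammation": ["inflammat", "cytokine", "interleukin",
                         "prostaglandin"],
        "immune system": ["immune", "immunity", "leukocyte", "lymphocyte",
                          "defense response"],
        "embryo implantation": ["implantation", "embryo", "decidua"],
        "insulin signaling": ["insulin"],
    }
    return FunctionGroupMap(
        {name: {"ids": set(), "substrings": s} for name, s in subs.items()}
    )


def load_function_groups(path) -> FunctionGroupMap:
    """Load a group map from YAML: group -> list of substrings, or
    group -> {ids: [...], substrings: [...]}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups: dict[str, dict] = {}
    for name, rules in raw.items():
        if isinstance(rules, list):
            groups[name] = {"ids": set(), "substrings": [str(s) for s in rules]}
        else:
            groups[name] = {
                "ids": set(rules.get("ids", [])),
                "substrings": [str(s) for s in rules.get("substrings", [])],
            }
    return FunctionGroupMap(groups)


def save_function_groups(groups: FunctionGroupMap, path) -> None:
    import yaml

    raw = {
        name: {"ids": sorted(r.get("ids", set())),
               "substrings": list(r.get("substrings", []))}
        for name, r in groups.groups.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def classify_groups(
    reduced: ReducedTerms,
    groups: FunctionGroupMap,
    ontology: Ontology,
) -> dict[str, list[EnrichmentTerm]]:
    """Partition the representatives into function groups.

    Every representative lands in exactly one group, or under
    "unclassified" when no rule matches.
    """
    out: dict[str, list[EnrichmentTerm]] = {g: [] for g in groups.names}
    out["unclassified"] = []
    for term in reduced.representatives:
        group = groups.match(term.term_id, ontology.name(term.term_id))
        out[group if group is not None else "unclassified"].append(term)
    return out


# ---------------------------------------------------------------------------
# specificity calls
# ---------------------------------------------------------------------------

@dataclass
class SpecificityCall:
    """Per-group specificity label plus the evidence flags behind it."""

    labels: dict[str, str]
    evidence: dict[str, dict[str, dict[str, bool]]]


def detections_from_classifications(
    classified: Mapping[str, Mapping[str, Mapping[str, list]]],
    groups: FunctionGroupMap,
) -> dict[str, dict[str, dict[str, bool]]]:
    """Flatten stimulus -> direction -> group classifications into flags.

    ``classified[stimulus][direction]`` is the output of
    :func:`classify_groups` for that contrast's enriched terms.
    """
    detections: dict[str, dict[str, dict[str, bool]]] = {}
    for group in groups.names:
        detections[group] = {}
        for stimulus, by_direction in classified.items():
            detections[group][stimulus] = {
                direction: bool(by_direction.get(direction, {}).get(group))
                for direction in ("up", "down")
            }
    return detections


def call_specificity(
    detections: Mapping[str, Mapping[str, Mapping[str, bool]]],
    *,
    common_mode: str = "either",
) -> SpecificityCall:
    """Label each function group common / cAMP_specific / MPA_specific / other.

    ``detections[group][stimulus]`` holds {"up": bool, "down": bool} flags.
    Rules are applied in order:

    * common — detected (either direction by default; both with
      ``common_mode="both"``) under all four stimuli;
    * cAMP_specific — detected in the up-regulated genes of both cAMP-using
      stimuli and not at all under either non-cAMP stimulus;
    * MPA_specific — detected in the up-regulated genes of all three
      MPA-using stimuli and not at all under cAMP;
    * other — anything else.
    """
    if common_mode not in ("either", "both"):
        raise DomainError(f"unknown common_mode {common_mode!r}")
    labels: dict[str, str] = {}
    for group, flags in detections.items():
        missing = [s for s in STIMULI if s not in flags]
        if missing:
            raise DomainError(
                f"group {group!r} lacks flags for stimulus {missing[0]!r}"
            )

        def detected(stimulus: str) -> bool:
            f = flags[stimulus]
            if common_mode == "both":
                return bool(f.get("up")) and bool(f.get("down"))
            return bool(f.get("up")) or bool(f.get("down"))

        def detected_any(stimulus: str) -> bool:
            f = flags[stimulus]
            return bool(f.get("up")) or bool(f.get("down"))

        if all(detected(s) for s in STIMULI):
            labels[group] = "common"
        elif (all(flags[s].get("up") for s in CAMP_STIMULI)
              and not any(detected_any(s) for s in ("MPA", "E2+MPA"))):
            labels[group] = "cAMP_specific"
        elif (all(flags[s].get("up") for s in MPA_STIMULI)
              and not detected_any("cAMP")):
            labels[group] = "MPA_specific"
        else:
            labels[group] = "other"
    return SpecificityCall(
        labels=labels,
        evidence={g: {s: dict(d) for s, d in f.items()}
                  for g, f in detections.items()},
    )
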