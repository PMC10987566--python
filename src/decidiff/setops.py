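"""Multi-way set comparison of DEG lists.

Three operations mirror the comparative figures of a stimulus-comparison
study: an N-way Venn partition of DEG sets, pairwise up/down overlap
counts between stimuli, and the direction-matched concordance of an
in vitro DEG set with the in vivo DEG set, reported as a percentage of
the in vitro total.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .deg import DEGSet
from .errors import DomainError


@dataclass
class VennPartition:
    """Disjoint membership compartments of up to six named gene sets.

    Each gene of the union is assigned the N-tuple of booleans recording
    which input sets contain it.  Compartment labels (a, b, c, ...) follow
    a canonical order: signatures sorted lexicographically with membership
    (True) before non-membership, so label "a" is always the
    all-sets compartment.
    """

    set_names: tuple[str, ...]
    compartments: dict[tuple[bool, ...], frozenset[str]]

    def labelled_compartments(self):
        """Yield (label, signature, genes) in canonical label order."""
        n = len(self.set_names)
        signatures = [
            sig for sig in itertools.product((True, False), repeat=n)
            if any(sig)
        ]
        labels = string.ascii_lowercase
        for label, sig in zip(labels, signatures):
            yield label, sig, self.compartments.get(sig, frozenset())

    def sizes(self) -> dict[str, int]:
        return {
            label: len(genes)
            for label, _, genes in self.labelled_compartments()
        }


@dataclass
class ConcordanceResult:
    """Direction-matched overlap of one in vitro DEG set with in vivo DEGs."""

    stimulus: str
    shared_up: frozenset[str]
    shared_down: frozenset[str]
    invitro_total: int
    ratio_percent: float

    @property
    def shared_total(self) -> int:
        return len(self.shared_up) + len(self.shared_down)


def venn_partition(
    named_sets: Sequence[tuple[str, Iterable[str]]],
) -> VennPartition:
    """Partition the union of 2..6 named gene sets by membership signature."""
    names = tuple(n for n, _ in named_sets)
    if not 2 <= len(names) <= 6:
        raise DomainError("venn_partition requires between 2 and 6 sets")
    if len(set(names)) != len(names):
        raise DomainError("duplicate set names")
    sets = [frozenset(s) for _, s in named_sets]
    compartments: dict[tuple[bool, ...], set[str]] = {}
    for gene in frozenset().union(*sets):
        sig = tuple(gene in s for s in sets)
        compartments.setdefault(sig, set()).add(gene)
    return VennPartition(
        names, {sig: frozenset(g) for sig, g in compartments.items()}
    )


def pairwise_overlap(a: DEGSet, b: DEGSet) -> pd.DataFrame:
    """Per-direction counts of genes specific to each set and common to both.

    Returns a frame indexed by direction (up, down) with columns
    ``a_only``, ``common``, ``b_only``.
    """
    rows = {}
    for direction in ("up", "down"):
        sa = getattr(a, direction + "_genes")
        sb = getattr(b, direction + "_genes")
        rows[direction] = {
            "a_only": len(sa - sb),
            "common": len(sa & sb),
            "b_only": len(sb - sa),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "direction"
    df.attrs["a"] = a.contrast_name
    df.attrs["b"] = b.contrast_name
    return df


def shared_with_invivo(invitro: DEGSet, invivo: DEGSet) -> ConcordanceResult:
    """Concordance of an in vitro DEG set with the in vivo DEG set.

    Shared DEGs are direction-matched: up with up, down with down; a gene
    regulated in opposite directions contributes to neither shared set.
    The concordance ratio is 100 x shared / in vitro total, rounded to one
    decimal place (e.g. 762 shared of 3821 in vitro DEGs -> 19.9).
    """
    invitro_total = len(invitro)
    if invitro_total == 0:
        raise DomainError(
            f"in vitro DEG set {invitro.contrast_name!r} is empty; "
            "concordance ratio undefined"
        )
    shared_up = frozenset(invitro.up_genes & invivo.up_genes)
    shared_down = frozenset(invitro.down_genes & invivo.down_genes)
    ratio = round(100.0 * (len(shared_up) + len(shared_down)) / invitro_total, 1)
    return ConcordanceResult(
        stimulus=invitro.contrast_name,
        shared_up=shared_up,
        shared_down=shared_down,
        invitro_total=invitro_total,
        ratio_percent=ratio,
    )
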