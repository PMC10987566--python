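"""Threshold-based differential-expression calling.

A gene is called differentially expressed when its pseudocount-adjusted
fold change versus the matched control exceeds ``up_fold`` (default 2.0)
or falls below ``down_fold`` (default 0.5):

    fold = (treated + pseudocount) / (control + pseudocount)

with pseudocount 1 by default.  "More than 2.0-fold or 0.5-fold" is read
as strict inequality, so a fold of exactly 2.0 or 0.5 is not a DEG; the
thresholds are configurable.  The same rule is applied to bulk stimulus
vs control contrasts and to the single-cell pseudobulk contrast of
late-secretory versus late-proliferative stromal cells, where per-phase
mean TPM is computed over cells *before* the pseudocount is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, EmptySelectionError
from .formats import CellMatrix, ExpressionMatrix, StudyDesign


@dataclass(frozen=True)
class DEGThresholds:
    """Pseudocount and fold-change cutoffs for DEG calling."""

    pseudocount: float = 1.0
    up_fold: float = 2.0
    down_fold: float = 0.5

    def __post_init__(self) -> None:
        if not self.pseudocount > 0:
            raise DomainError("pseudocount must be > 0")
        if not self.up_fold > 1:
            raise DomainError("up_fold must be > 1")
        if not 0 < self.down_fold < 1:
            raise DomainError("down_fold must be in (0, 1)")


@dataclass
class DEGSet:
    """Direction-labelled DEG calls for one contrast, with fold changes."""

    contrast_name: str
    up: dict[str, float] = field(default_factory=dict)
    down: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        both = set(self.up) & set(self.down)
        if both:
            raise DomainError(
                f"gene(s) in both up and down sets: {sorted(both)[:3]}"
            )

    @property
    def up_genes(self) -> set[str]:
        return set(self.up)

    @property
    def down_genes(self) -> set[str]:
        return set(self.down)

    @property
    def all_genes(self) -> set[str]:
        return set(self.up) | set(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class PseudobulkProfile:
    """Per-gene mean TPM over the cells of one phase."""

    phase: str
    mean_tpm: pd.Series
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise DomainError("n_cells must be >= 1")


def fold_change(treated, control, thresholds: DEGThresholds = DEGThresholds()):
    """Pseudocount-adjusted fold change (treated + pc) / (control + pc).

    Accepts scalars or aligned numpy arrays / pandas Series.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if (treated < 0).any() or (control < 0).any():
        raise DomainError("expression values must be >= 0")
    if not (np.isfinite(treated).all() and np.isfinite(control).all()):
        raise DomainError("expression values must be finite")
    out = (treated + thresholds.pseudocount) / (control + thresholds.pseudocount)
    return float(out) if out.ndim == 0 else out


def _call_from_folds(
    contrast: str, genes, folds: np.ndarray, thresholds: DEGThresholds
) -> DEGSet:
    genes = np.asarray(genes)
    up_mask = folds > thresholds.up_fold
    down_mask = folds < thresholds.down_fold
    up = dict(zip(genes[up_mask], folds[up_mask]))
    down = dict(zip(genes[down_mask], folds[down_mask]))
    return DEGSet(contrast, up, down)


def call_degs_bulk(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    thresholds: DEGThresholds = DEGThresholds(),
) -> dict[str, DEGSet]:
    """Call up/down DEGs for every stimulus against its matched control."""
    samples = set(matrix.sample_ids)
    out: dict[str, DEGSet] = {}
    for stimulus in design.stimuli:
        if stimulus not in samples:
            raise DesignError(f"stimulus sample {stimulus!r} missing from matrix")
        control = design.control_of[stimulus]
        if control not in samples:
            raise DesignError(f"control sample {control!r} missing from matrix")
        folds = fold_change(
            matrix.data[stimulus].to_numpy(),
            matrix.data[control].to_numpy(),
            thresholds,
        )
        out[stimulus] = _call_from_folds(stimulus, matrix.gene_ids, folds,
                                         thresholds)
    return out


def pseudobulk_means(
    cells: CellMatrix,
    phase: str,
    marker_filter: tuple[str, float] | None = None,
) -> PseudobulkProfile:
    """Mean expression per gene over the cells of one phase.

    ``marker_filter=(gene, min_value)`` keeps only cells whose expression of
    ``gene`` is strictly greater than ``min_value`` — used to restrict
    late-secretory cells to those expressing the decidualization marker
    FOXO1 (min_value 0 means "any positive expression").  Means are raw
    (no pseudocount); the pseudocount enters only at fold-change time.
    """
    selected = [c for c in cells.cell_ids if cells.phase_of[c] == phase]
    if marker_filter is not None:
        gene, min_value = marker_filter
        if gene not in cells.data.index:
            raise DomainError(f"marker gene {gene!r} not in cell matrix")
        marker = cells.data.loc[gene]
        selected = [c for c in selected if marker[c] > min_value]
    if not selected:
        raise EmptySelectionError(
            f"no cells with phase {phase!r} pass the filters"
        )
    means = cells.data[selected].mean(axis=1)
    return PseudobulkProfile(phase, means, len(selected))


def call_degs_invivo(
    proliferative: PseudobulkProfile,
    secretory: PseudobulkProfile,
    thresholds: DEGThresholds = DEGThresholds(),
    contrast_name: str = "in_vivo",
) -> DEGSet:
    """DEGs of in vivo decidualization: secretory vs proliferative pseudobulk.

    The late-secretory profile is the "treated" side.  Both profiles must
    share the same gene universe.
    """
    if not proliferative.mean_tpm.index.equals(secretory.mean_tpm.index):
        raise DomainError(
            "pseudobulk profiles must share the same gene universe"
        )
    folds = fold_change(
        secretory.mean_tpm.to_numpy(),
        proliferative.mean_tpm.to_numpy(),
        thresholds,
    )
    return _call_from_folds(contrast_name, proliferative.mean_tpm.index,
                            folds, thresholds)
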