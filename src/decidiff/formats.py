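"""Readers, writers and validated containers for every external representation.

The pipeline touches five kinds of external data:

* bulk expression matrices — tab-separated TPM tables, genes in rows,
  samples in columns (:func:`read_expression_tsv`);
* single-cell expression — MatrixMarket coordinate triplets with plain-text
  sidecars for gene symbols and cell phase labels (:func:`read_cell_matrix`);
* a Gene Ontology style DAG in a restricted OBO subset where only ``id``,
  ``name``, ``namespace`` and ``is_a`` are interpreted (:func:`read_obo_subset`);
* gene-to-term annotation tables (:func:`read_annotation_tsv`);
* pipeline products — DEG tables, Venn partitions, enrichment tables,
  Newick dendrograms and a JSON run summary (:func:`write_outputs`).

All containers validate their invariants at construction time, so a parsed
object is always internally consistent.  Gene identifiers are matched
case-sensitively and exactly throughout; no alias resolution is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DesignError, FormatError

#: Menstrual-cycle phases accepted as cell labels.  The late proliferative
#: phase (~day 9-11) is the pre-decidualization state, the late secretory
#: phase (~day 24-27) the in vivo decidualized state.
PHASES = ("late_proliferative", "late_secretory")

#: Serialisation precision for fold changes and p-values (significant digits).
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Bulk TPM values, genes in rows and samples in columns.

    Wraps a :class:`pandas.DataFrame` and enforces: unique gene and sample
    identifiers, every cell populated, all values finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            coerced = df.apply(pd.to_numeric, errors="coerce")
            bad = coerced.isna() & df.notna()
            gene, sample = _first_true_cell(bad | df.isna())
            raise FormatError(
                f"non-numeric expression value at gene {gene!r}, sample {sample!r}"
            )
        if np.isnan(values).any():
            gene, sample = _first_true_cell(df.isna())
            raise FormatError(f"missing value at gene {gene!r}, sample {sample!r}")
        if not np.isfinite(values).all():
            gene, sample = _first_true_cell(~np.isfinite(df))
            raise FormatError(f"non-finite value at gene {gene!r}, sample {sample!r}")
        if (values < 0).any():
            gene, sample = _first_true_cell(df < 0)
            raise FormatError(
                f"negative expression value at gene {gene!r}, sample {sample!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:  # value equality, used in tests
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class StudyDesign:
    """Maps each stimulus to its unstimulated control sample.

    The in vitro protocol uses two controls: cells cultured without
    stimulation for 4 days (control for cAMP-containing stimuli) or for
    14 days (control for the progestin-only stimuli).  ``protocol_days``
    records the culture duration per stimulus; stimuli sharing a control
    must share a duration.
    """

    stimuli: tuple[str, ...]
    control_of: Mapping[str, str]
    protocol_days: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.stimuli)) != len(self.stimuli):
            raise DesignError("duplicate stimulus names")
        missing = set(self.stimuli) - set(self.control_of)
        if missing:
            raise DesignError(f"stimuli without a control: {sorted(missing)}")
        missing = set(self.stimuli) - set(self.protocol_days)
        if missing:
            raise DesignError(f"stimuli without protocol_days: {sorted(missing)}")
        by_control: dict[str, set[int]] = {}
        for s in self.stimuli:
            by_control.setdefault(self.control_of[s], set()).add(
                self.protocol_days[s]
            )
        for ctrl, days in by_control.items():
            if len(days) > 1:
                raise DesignError(
                    f"control {ctrl!r} shared by stimuli with different "
                    f"protocol durations {sorted(days)}"
                )

    @property
    def controls(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.stimuli:
            c = self.control_of[s]
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def default_design() -> StudyDesign:
    """The six-sample in vitro design: two controls plus four stimuli.

    cAMP-containing stimuli (cAMP, cAMP+MPA) follow the 4-day protocol and
    are compared to the 4-day control; MPA and E2+MPA follow the 14-day
    protocol and are compared to the 14-day control.
    """
    return StudyDesign(
        stimuli=("cAMP", "cAMP+MPA", "MPA", "E2+MPA"),
        control_of={
            "cAMP": "control_4d",
            "cAMP+MPA": "control_4d",
            "MPA": "control_14d",
            "E2+MPA": "control_14d",
        },
        protocol_days={"cAMP": 4, "cAMP+MPA": 4, "MPA": 14, "E2+MPA": 14},
    )


@dataclass
class CellMatrix:
    """Per-cell expression with a menstrual-cycle phase label per cell."""

    data: pd.DataFrame  # genes x cells
    phase_of: Mapping[str, str]

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise FormatError(
                f"duplicate gene identifier: {df.index[df.index.duplicated()][0]!r}"
            )
        if df.columns.duplicated().any():
            raise FormatError(
                f"duplicate cell barcode: {df.columns[df.columns.duplicated()][0]!r}"
            )
        missing = [c for c in df.columns if c not in self.phase_of]
        if missing:
            raise FormatError(
                f"{len(missing)} cell(s) present in matrix but absent from "
                f"metadata, e.g. {missing[0]!r}"
            )
        for cell, phase in self.phase_of.items():
            if phase not in PHASES:
                raise FormatError(
                    f"unknown phase label {phase!r} for cell {cell!r}; "
                    f"allowed labels: {list(PHASES)}"
                )
        values = df.to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise FormatError("cell matrix values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class Ontology:
    """An is_a DAG of terms.

    ``graph`` is a :class:`networkx.DiGraph` with edges pointing child ->
    parent, node attributes ``name`` and ``namespace``.  Roots are terms
    with no outgoing is_a link.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        g = self.graph
        undeclared = [n for n, d in g.nodes(data=True) if "name" not in d]
        if undeclared:
            raise FormatError(
                f"is_a reference to undeclared term {undeclared[0]!r}"
            )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"cycle in is_a links involving term {cycle[0][0]!r}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def name(self, term: str) -> str:
        return self.graph.nodes[term]["name"]

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (not including itself)."""
        return nx.descendants(self.graph, term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))


@dataclass
class Annotation:
    """Direct gene -> term assignments over a background population."""

    direct: dict[str, frozenset[str]]
    population: frozenset[str]

    def __post_init__(self) -> None:
        extra = set(self.direct) - set(self.population)
        if extra:
            raise FormatError(
                f"annotated gene outside the population: {sorted(extra)[0]!r}"
            )

    def validate_against(self, ontology: Ontology) -> None:
        known = ontology.terms
        for gene, terms in self.direct.items():
            unknown = terms - known
            if unknown:
                raise FormatError(
                    f"gene {gene!r} annotated to unknown term {sorted(unknown)[0]!r}"
                )


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated TPM table (first column gene ids, header samples).

    Input gene order is preserved.  Duplicate identifiers, non-numeric or
    negative values raise :class:`FormatError` naming the offending cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for i, s in enumerate(samples) if s in samples[:i])
        raise FormatError(f"duplicate sample identifier in header: {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                       index_label="gene")


# ---------------------------------------------------------------------------
# single-cell matrix I/O (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------

def read_cell_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CellMatrix:
    """Read a sparse genes x cells matrix with its two sidecar tables.

    ``genes_path`` lists one gene symbol per line, in matrix row order.
    ``cells_path`` is a two-column TSV ``cell_id<TAB>phase`` with a header,
    in matrix column order.  Coordinates absent from the triplet file are
    zeros.  MatrixMarket indices are 1-based on disk; in-memory coordinates
    are 0-based.
    """
    sparse = scipy.io.mmread(str(mtx_path))
    dense = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse,
                       dtype=float)
    genes = Path(genes_path).read_text().splitlines()
    genes = [g.strip() for g in genes if g.strip()]
    if len(genes) != dense.shape[0]:
        raise FormatError(
            f"gene sidecar lists {len(genes)} genes but matrix has "
            f"{dense.shape[0]} rows"
        )
    meta = pd.read_csv(cells_path, sep="\t", dtype=str)
    if list(meta.columns[:2]) != ["cell_id", "phase"]:
        raise FormatError(
            "cell sidecar must have header columns 'cell_id' and 'phase'"
        )
    if len(meta) < dense.shape[1]:
        raise FormatError(
            f"{dense.shape[1] - len(meta)} cell(s) present in matrix but "
            "absent from metadata"
        )
    if len(meta) > dense.shape[1]:
        raise FormatError(
            f"metadata lists {len(meta)} cells but matrix has "
            f"{dense.shape[1]} columns"
        )
    cells = list(meta["cell_id"])
    phase_of = dict(zip(cells, meta["phase"]))
    df = pd.DataFrame(dense, index=genes, columns=cells)
    return CellMatrix(df, phase_of)


def write_cell_matrix(
    cells: CellMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(cells.data.to_numpy())
    scipy.io.mmwrite(str(mtx_path), sparse, precision=10)
    Path(genes_path).write_text("\n".join(cells.gene_ids) + "\n")
    meta = pd.DataFrame(
        {"cell_id": cells.cell_ids,
         "phase": [cells.phase_of[c] for c in cells.cell_ids]}
    )
    meta.to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ontology / annotation I/O
# ---------------------------------------------------------------------------

def read_obo_subset(path: str | Path) -> Ontology:
    """Parse an OBO file interpreting only id, name, namespace and is_a.

    Obsolete terms are skipped; relationship types other than is_a are
    ignored.  A cycle or an is_a reference to an undeclared term raises
    :class:`FormatError`.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    for node, attrs in multi.nodes(data=True):
        g.add_node(node, **{k: attrs[k] for k in ("name", "namespace")
                            if k in attrs})
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_node(child, **multi.nodes[child])
            if parent not in multi.nodes or "name" not in multi.nodes[parent]:
                g.add_node(parent)  # undeclared; Ontology validation reports it
            g.add_edge(child, parent)
    return Ontology(g)


def write_obo_subset(ontology: Ontology, path: str | Path) -> None:
    """Serialise an ontology in the restricted OBO subset the reader accepts."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(ontology.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.name(term)}")
        ns = ontology.namespace(term)
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(ontology.parents(term)):
            lines.append(f"is_a: {parent} ! {ontology.name(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_annotation_tsv(
    path: str | Path,
    ontology: Ontology,
    population: Iterable[str] | None = None,
) -> Annotation:
    """Read a two-column gene<TAB>term table into an :class:`Annotation`.

    Duplicate lines are deduplicated (set semantics).  The background
    population defaults to all genes appearing in the file; pass
    ``population`` to widen it.  Terms absent from ``ontology`` raise
    :class:`FormatError`.
    """
    direct: dict[str, set[str]] = {}
    known = ontology.terms
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected gene<TAB>term, got {line!r}"
                )
            gene, term = parts
            if term not in known:
                raise FormatError(
                    f"{path}:{lineno}: term {term!r} not in ontology"
                )
            direct.setdefault(gene, set()).add(term)
    pop = frozenset(population) if population is not None else frozenset(direct)
    ann = Annotation({g: frozenset(t) for g, t in direct.items()}, pop)
    ann.validate_against(ontology)
    return ann


def write_annotation_tsv(annotation: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation.direct):
            for term in sorted(annotation.direct[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# pipeline-product writers
# ---------------------------------------------------------------------------

DEG_TABLE_COLUMNS = ("contrast", "gene", "direction", "fold_change")


def write_deg_table(deg_sets, path: str | Path) -> None:
    """Write one or more DEG sets as a tab-separated table.

    Columns: contrast, gene, direction (up/down), fold_change (6 significant
    digits).  An empty DEG set produces a header-only table.
    """
    from .deg import DEGSet  # local import to avoid a cycle

    if isinstance(deg_sets, DEGSet):
        deg_sets = [deg_sets]
    rows = []
    for ds in deg_sets:
        for direction, folds in (("up", ds.up), ("down", ds.down)):
            for gene in sorted(folds):
                rows.append((ds.contrast_name, gene, direction,
                             FLOAT_FORMAT % folds[gene]))
    with open(path, "w") as fh:
        fh.write("\t".join(DEG_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_deg_table(path: str | Path):
    """Read a DEG table back into a mapping contrast -> DEGSet."""
    from .deg import DEGSet

    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if list(df.columns) != list(DEG_TABLE_COLUMNS):
        raise FormatError(
            f"DEG table must have columns {list(DEG_TABLE_COLUMNS)}"
        )
    out: dict[str, DEGSet] = {}
    for contrast, sub in df.groupby("contrast", sort=False):
        up = dict(zip(sub.loc[sub.direction == "up", "gene"],
                      sub.loc[sub.direction == "up", "fold_change"]))
        down = dict(zip(sub.loc[sub.direction == "down", "gene"],
                        sub.loc[sub.direction == "down", "fold_change"]))
        out[contrast] = DEGSet(contrast, up, down)
    return out


def write_venn_table(partition, path: str | Path) -> None:
    """Write a Venn partition as (label, signature, gene) rows."""
    with open(path, "w") as fh:
        fh.write("label\tsignature\tsets\tgene\n")
        for label, signature, genes in partition.labelled_compartments():
            sets = ",".join(
                n for n, flag in zip(partition.set_names, signature) if flag
            )
            sig = "".join("1" if f else "0" for f in signature)
            for gene in sorted(genes):
                fh.write(f"{label}\t{sig}\t{sets}\t{gene}\n")


ENRICHMENT_COLUMNS = (
    "term_id", "name", "namespace", "p_value", "study_hits", "study_size",
    "term_population_count", "population_size", "gene_ratio", "hit_genes",
)


def write_enrichment_table(report, path: str | Path, ontology=None) -> None:
    """Write an enrichment report; one row per term, sorted by p-value."""
    with open(path, "w") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for t in report.terms:
            name = ontology.name(t.term_id) if ontology is not None else ""
            ns = ontology.namespace(t.term_id) if ontology is not None else ""
            fh.write(
                f"{t.term_id}\t{name}\t{ns}\t{FLOAT_FORMAT % t.p_value}\t"
                f"{t.study_hits}\t{t.study_size}\t{t.term_population_count}\t"
                f"{t.population_size}\t{FLOAT_FORMAT % t.gene_ratio}\t"
                f"{','.join(sorted(t.hit_genes))}\n"
            )


def read_enrichment_table(path: str | Path, *, contrast_name: str = "",
                          direction: str = "", alpha: float = 1.0):
    """Read an enrichment table back into an EnrichmentReport."""
    from .enrichment import EnrichmentReport, EnrichmentTerm

    df = pd.read_csv(path, sep="\t", dtype={"term_id": str},
                     keep_default_na=False)
    missing = set(ENRICHMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"enrichment table missing columns {sorted(missing)}")
    terms = [
        EnrichmentTerm(
            term_id=row.term_id,
            p_value=float(row.p_value),
            study_hits=int(row.study_hits),
            study_size=int(row.study_size),
            term_population_count=int(row.term_population_count),
            population_size=int(row.population_size),
            hit_genes=frozenset(
                g for g in str(row.hit_genes).split(",") if g),
        )
        for row in df.itertuples()
    ]
    return EnrichmentReport(contrast_name, direction, alpha, terms)


def write_reduced_table(reduced, report_terms, path: str | Path,
                        ontology=None) -> None:
    """Write a reduction result: every input term with its representative."""
    rep_ids = set(reduced.representative_ids())
    by_id = {t.term_id: t for t in report_terms}
    with open(path, "w") as fh:
        fh.write("term_id\tname\trepresentative\tis_representative\t"
                 "p_value\n")
        for t in report_terms:
            rep = t.term_id if t.term_id in rep_ids \
                else reduced.assigned_to.get(t.term_id, t.term_id)
            name = ontology.name(t.term_id) if ontology is not None else ""
            fh.write(f"{t.term_id}\t{name}\t{rep}\t"
                     f"{int(t.term_id in rep_ids)}\t"
                     f"{FLOAT_FORMAT % t.p_value}\n")


def write_newick(dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def write_outputs(result, path: str | Path) -> None:
    """Duck-typed dispatcher writing any pipeline product to ``path``.

    Accepts a DEGSet (or list of them), a VennPartition, an
    EnrichmentReport, a Dendrogram, or a plain mapping (run summary).
    """
    if hasattr(result, "compartments"):
        write_venn_table(result, path)
    elif hasattr(result, "terms") and hasattr(result, "alpha"):
        write_enrichment_table(result, path)
    elif hasattr(result, "merges"):
        write_newick(result, path)
    elif hasattr(result, "up") and hasattr(result, "down"):
        write_deg_table(result, path)
    elif isinstance(result, Mapping):
        write_run_summary(result, path)
    elif isinstance(result, (list, tuple)):
        write_deg_table(result, path)
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")


def _first_true_cell(mask: pd.DataFrame) -> tuple[str, str]:
    """Index labels of the first True cell of a boolean frame (row-major)."""
    arr = mask.to_numpy()
    i, j = np.argwhere(arr)[0]
    return str(mask.index[i]), str(mask.columns[j])
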