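"""Coupled synthetic fixtures with known ground truth.

Three generators emulate the shapes of the real study inputs so every
pipeline stage can be exercised end-to-end without downloads:

* :func:`simulate_bulk` — a six-sample bulk TPM matrix (two unstimulated
  controls plus four decidualization stimuli) with planted per-stimulus
  up/down DEG signatures whose default sizes mirror the reported counts
  (cAMP 1442/2109, cAMP+MPA 1378/2443, MPA 956/1058, E2+MPA 913/1087);
* :func:`simulate_cells` — a two-phase single-cell matrix (189 late
  proliferative, 137 late secretory cells) whose planted secretory fold
  changes overlap one designated stimulus's DEG set at a configured
  direction-matched concordance (default 0.199 for cAMP+MPA), constructed
  exactly by explicit shared-set selection;
* :func:`simulate_ontology` — a small is_a DAG with one branch per
  cellular-function group, annotated so each stimulus's planted DEGs are
  over-represented in the branches matching its planted specific
  functions (cAMP-pair genes fill the angiogenesis / inflammation /
  immune / implantation branches; genes up under all MPA-using stimuli
  fill the insulin-signaling branch; four-way common genes fill the
  common branches).

Planted fold changes are realised on the pseudocount scale —
treated = f*(control+1) - 1 — so threshold calling recovers the drawn
fold exactly under zero noise.  All randomness flows from the single
``seed``; each generator derives an independent stream from it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats import (
    Annotation,
    CellMatrix,
    ExpressionMatrix,
    Ontology,
    StudyDesign,
    default_design,
    write_annotation_tsv,
    write_cell_matrix,
    write_expression_tsv,
    write_obo_subset,
)
from .reduction import FunctionGroupMap, STIMULI, default_function_groups

#: Function groups detected under all four stimuli in the planted design.
COMMON_GROUPS = ("cell morphology", "signal transduction",
                 "cell proliferation", "metabolism", "differentiation")
#: Groups planted as specific to the cAMP-using stimuli (up-regulated).
CAMP_GROUPS = ("angiogenesis", "inflammation", "immune system",
               "embryo implantation")
#: Groups planted as specific to the MPA-using stimuli (up-regulated).
MPA_GROUPS = ("insulin signaling",)


@dataclass
class SimulationConfig:
    """All knobs of the three coupled generators.

    Defaults encode the study conditions: the reported per-stimulus DEG
    counts, the 189/137 cell split, and the 0.199 concordance of cAMP+MPA
    with in vivo decidualization.  Signature-overlap pool sizes (how many
    planted genes are shared between stimuli) are free parameters chosen
    to reproduce the qualitative structure — a large shared signature
    between the two progestin-only stimuli, a shared cAMP component, and
    a three-way MPA-response pool — while keeping every per-stimulus
    total exact.
    """

    n_genes: int = 10000
    planted_up: dict[str, int] = field(default_factory=lambda: {
        "cAMP": 1442, "cAMP+MPA": 1378, "MPA": 956, "E2+MPA": 913})
    planted_down: dict[str, int] = field(default_factory=lambda: {
        "cAMP": 2109, "cAMP+MPA": 2443, "MPA": 1058, "E2+MPA": 1087})
    # signature-overlap pool sizes
    common_up: int = 150            # up in all four stimuli
    common_down: int = 250          # down in all four stimuli
    camp_pair_up: int = 300         # up in cAMP and cAMP+MPA only
    camp_pair_down: int = 500
    mpa_triple_up: int = 150        # up in MPA, E2+MPA and cAMP+MPA
    mpa_pair_up: int = 450          # up in MPA and E2+MPA only
    mpa_pair_down: int = 600
    # planted fold-change ranges (drawn uniformly)
    up_fold_range: tuple[float, float] = (2.5, 8.0)
    down_fold_range: tuple[float, float] = (0.05, 0.4)
    noise_sd: float = 0.0           # log-scale multiplicative noise, bulk
    renormalize_tpm: bool = False   # rescale each sample to 1e6 (perturbs folds)
    # single-cell design
    n_cells_proliferative: int = 189
    n_cells_secretory: int = 137
    dispersion: float = 0.0         # gamma-Poisson dispersion; 0 = exact means
    invivo_up: int = 2579
    invivo_down: int = 3768
    concordance_target: float = 0.199
    concordance_stimulus: str = "cAMP+MPA"
    marker_gene: str = "FOXO1"
    marker_zero_fraction: float = 0.0
    # ontology
    branch_groups: tuple[str, ...] = tuple(
        COMMON_GROUPS + CAMP_GROUPS + MPA_GROUPS)
    leaves_per_branch: int = 3
    genes_per_term: int = 20
    background_per_term: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.planted_up) != set(STIMULI) or \
                set(self.planted_down) != set(STIMULI):
            raise ConfigError(f"planted counts must cover stimuli {STIMULI}")
        for s in STIMULI:
            if self.unique_up(s) < 0 or self.unique_down(s) < 0:
                raise ConfigError(
                    f"overlap pools exceed planted counts for {s!r}"
                )
        if not 0 <= self.concordance_target <= 1:
            raise ConfigError("concordance_target must be in [0, 1]")
        if self.concordance_stimulus not in STIMULI:
            raise ConfigError(
                f"concordance_stimulus must be one of {STIMULI}"
            )
        if not 0 <= self.marker_zero_fraction <= 1:
            raise ConfigError("marker_zero_fraction must be in [0, 1]")
        if self.n_planted_distinct() > self.n_genes - 1:
            raise ConfigError(
                f"planted signatures need {self.n_planted_distinct()} distinct "
                f"genes but only {self.n_genes - 1} are available"
            )

    # pool membership per stimulus -------------------------------------
    def up_pools(self, stimulus: str) -> tuple[str, ...]:
        pools = {"cAMP": ("common_up", "camp_pair_up"),
                 "cAMP+MPA": ("common_up", "camp_pair_up", "mpa_triple_up"),
                 "MPA": ("common_up", "mpa_triple_up", "mpa_pair_up"),
                 "E2+MPA": ("common_up", "mpa_triple_up", "mpa_pair_up")}
        return pools[stimulus]

    def down_pools(self, stimulus: str) -> tuple[str, ...]:
        pools = {"cAMP": ("common_down", "camp_pair_down"),
                 "cAMP+MPA": ("common_down", "camp_pair_down"),
                 "MPA": ("common_down", "mpa_pair_down"),
                 "E2+MPA": ("common_down", "mpa_pair_down")}
        return pools[stimulus]

    def unique_up(self, stimulus: str) -> int:
        return self.planted_up[stimulus] - sum(
            getattr(self, p) for p in self.up_pools(stimulus))

    def unique_down(self, stimulus: str) -> int:
        return self.planted_down[stimulus] - sum(
            getattr(self, p) for p in self.down_pools(stimulus))

    def n_planted_distinct(self) -> int:
        pools = (self.common_up + self.common_down + self.camp_pair_up
                 + self.camp_pair_down + self.mpa_triple_up
                 + self.mpa_pair_up + self.mpa_pair_down)
        uniques = sum(self.unique_up(s) + self.unique_down(s) for s in STIMULI)
        return pools + uniques

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        ids = [f"G{i:0{width}d}" for i in range(1, self.n_genes)]
        return [self.marker_gene] + ids


@dataclass
class TruthTable:
    """Per-gene planted direction per contrast plus function-branch label.

    ``table`` is indexed by gene; stimulus columns and the ``in_vivo``
    column hold "up", "down" or ""; ``branch`` holds the function group a
    gene was planted into (signal genes only).
    """

    table: pd.DataFrame

    def up_genes(self, contrast: str) -> set[str]:
        col = self.table[contrast]
        return set(col.index[col == "up"])

    def down_genes(self, contrast: str) -> set[str]:
        col = self.table[contrast]
        return set(col.index[col == "down"])

    def branch_genes(self, group: str) -> set[str]:
        col = self.table["branch"]
        return set(col.index[col == group])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([stage, config.seed & 0x7FFFFFFF]))


def _draw_folds(rng, low_high, n):
    return rng.uniform(low_high[0], low_high[1], size=n)


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------

def simulate_bulk(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, StudyDesign, TruthTable]:
    """Six-sample bulk matrix with planted per-stimulus DEG signatures.

    Baseline abundances are log-normal; both control samples share the
    baseline.  For a planted gene the treated value is f*(control+1) - 1
    with f drawn from the configured fold range, so the pseudocount fold
    change equals f exactly; baselines of down-planted genes are raised
    where needed so treated values stay non-negative.  Optional log-normal
    noise multiplies every entry; optional renormalization rescales each
    sample to a million (off by default because it perturbs planted folds).
    """
    rng = _rng(config, 1)
    genes = config.gene_ids()
    n = config.n_genes
    plantable = list(np.array(genes[1:])[rng.permutation(n - 1)])

    # consume the shuffled gene list block by block
    pools: dict[str, list[str]] = {}
    for name in ("common_up", "common_down", "camp_pair_up", "camp_pair_down",
                 "mpa_triple_up", "mpa_pair_up", "mpa_pair_down"):
        k = getattr(config, name)
        pools[name], plantable = plantable[:k], plantable[k:]
    unique_up: dict[str, list[str]] = {}
    unique_down: dict[str, list[str]] = {}
    for s in STIMULI:
        k = config.unique_up(s)
        unique_up[s], plantable = plantable[:k], plantable[k:]
        k = config.unique_down(s)
        unique_down[s], plantable = plantable[:k], plantable[k:]

    up_sets = {s: [g for p in config.up_pools(s) for g in pools[p]]
               + unique_up[s] for s in STIMULI}
    down_sets = {s: [g for p in config.down_pools(s) for g in pools[p]]
                 + unique_down[s] for s in STIMULI}

    # planted folds per (gene, stimulus)
    gene_index = {g: i for i, g in enumerate(genes)}
    folds = {s: {} for s in STIMULI}
    for s in STIMULI:
        for g, f in zip(up_sets[s],
                        _draw_folds(rng, config.up_fold_range,
                                    len(up_sets[s]))):
            folds[s][g] = f
        for g, f in zip(down_sets[s],
                        _draw_folds(rng, config.down_fold_range,
                                    len(down_sets[s]))):
            folds[s][g] = f

    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=n)
    # keep treated = f*(c+1)-1 non-negative for down-planted genes
    min_fold = np.full(n, np.inf)
    for s in STIMULI:
        for g in down_sets[s]:
            i = gene_index[g]
            min_fold[i] = min(min_fold[i], folds[s][g])
    needs = np.isfinite(min_fold)
    baseline[needs] = np.maximum(baseline[needs],
                                 1.0 / min_fold[needs] - 1.0 + 0.5)

    design = default_design()
    columns = {"control_4d": baseline.copy(), "control_14d": baseline.copy()}
    for s in STIMULI:
        col = baseline.copy()
        for g, f in folds[s].items():
            i = gene_index[g]
            col[i] = f * (baseline[i] + 1.0) - 1.0
        columns[s] = col

    order = ["control_4d", "cAMP", "cAMP+MPA", "control_14d", "MPA", "E2+MPA"]
    values = np.column_stack([columns[c] for c in order])
    if config.noise_sd > 0:
        values = values * rng.lognormal(0.0, config.noise_sd, size=values.shape)
    if config.renormalize_tpm:
        values = values / values.sum(axis=0, keepdims=True) * 1e6
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=order))

    truth = pd.DataFrame("", index=pd.Index(genes, name="gene"),
                         columns=list(STIMULI) + ["in_vivo", "branch"])
    for s in STIMULI:
        truth.loc[up_sets[s], s] = "up"
        truth.loc[down_sets[s], s] = "down"
    return matrix, design, TruthTable(truth)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def simulate_cells(
    config: SimulationConfig, truth: TruthTable
) -> tuple[CellMatrix, TruthTable]:
    """Two-phase cell matrix with an exactly-planted in vivo DEG overlap.

    The planted in vivo set shares ceil(target * count) direction-matched
    genes with the designated stimulus's planted set, per direction, so
    the pipeline's concordance ratio equals the configured target by
    construction.  Remaining in vivo genes are drawn from genes the
    designated stimulus did not regulate.  With dispersion 0 each cell
    carries its phase's mean profile exactly; otherwise counts are
    gamma-Poisson around the means and rescaled to per-cell TPM.  All
    cells express the marker gene positively unless ``marker_zero_fraction``
    zeroes it in a leading fraction of secretory cells.
    """
    rng = _rng(config, 2)
    genes = config.gene_ids()
    n = config.n_genes
    gene_index = {g: i for i, g in enumerate(genes)}
    s_star = config.concordance_stimulus

    star_up = sorted(truth.up_genes(s_star))
    star_down = sorted(truth.down_genes(s_star))
    n_shared_up = math.ceil(config.concordance_target * len(star_up))
    n_shared_down = math.ceil(config.concordance_target * len(star_down))
    if n_shared_up > config.invivo_up or n_shared_down > config.invivo_down:
        raise ConfigError(
            "concordance target requires more shared genes than the in vivo "
            "set sizes allow"
        )
    shared_up = list(rng.choice(star_up, size=n_shared_up, replace=False)) \
        if n_shared_up else []
    shared_down = list(rng.choice(star_down, size=n_shared_down,
                                  replace=False)) if n_shared_down else []

    excluded = set(star_up) | set(star_down) | {config.marker_gene}
    free = sorted(set(genes) - excluded)
    free = list(np.array(free)[rng.permutation(len(free))])
    n_extra_up = config.invivo_up - n_shared_up
    n_extra_down = config.invivo_down - n_shared_down
    if n_extra_up + n_extra_down > len(free):
        raise ConfigError(
            f"in vivo sets need {n_extra_up + n_extra_down} unshared genes "
            f"but only {len(free)} genes are unused by {s_star!r}"
        )
    invivo_up = shared_up + free[:n_extra_up]
    invivo_down = shared_down + free[n_extra_up:n_extra_up + n_extra_down]

    prolif = rng.lognormal(mean=1.0, sigma=1.0, size=n)
    prolif[gene_index[config.marker_gene]] = 5.0
    up_folds = _draw_folds(rng, config.up_fold_range, len(invivo_up))
    down_folds = _draw_folds(rng, config.down_fold_range, len(invivo_down))
    for g, f in zip(invivo_down, down_folds):
        i = gene_index[g]
        prolif[i] = max(prolif[i], 1.0 / f - 1.0 + 0.5)
    secretory = prolif.copy()
    for g, f in zip(invivo_up, up_folds):
        i = gene_index[g]
        secretory[i] = f * (prolif[i] + 1.0) - 1.0
    for g, f in zip(invivo_down, down_folds):
        i = gene_index[g]
        secretory[i] = f * (prolif[i] + 1.0) - 1.0

    def sample_cells(means: np.ndarray, count: int) -> np.ndarray:
        if config.dispersion == 0:
            return np.tile(means[:, None], (1, count))
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, np.maximum(means, 1e-12)[:, None] / shape,
                        size=(n, count))
        counts = rng.poisson(lam).astype(float)
        totals = counts.sum(axis=0, keepdims=True)
        totals[totals == 0] = 1.0
        return counts / totals * 1e6

    p_cells = sample_cells(prolif, config.n_cells_proliferative)
    s_cells = sample_cells(secretory, config.n_cells_secretory)
    n_zero = int(config.marker_zero_fraction * config.n_cells_secretory)
    if n_zero:
        s_cells[gene_index[config.marker_gene], :n_zero] = 0.0

    p_ids = [f"P{i:04d}" for i in range(config.n_cells_proliferative)]
    s_ids = [f"S{i:04d}" for i in range(config.n_cells_secretory)]
    data = pd.DataFrame(np.hstack([p_cells, s_cells]), index=genes,
                        columns=p_ids + s_ids)
    phase_of = {c: "late_proliferative" for c in p_ids}
    phase_of.update({c: "late_secretory" for c in s_ids})

    table = truth.table.copy()
    table.loc[invivo_up, "in_vivo"] = "up"
    table.loc[invivo_down, "in_vivo"] = "down"
    return CellMatrix(data, phase_of), TruthTable(table)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def simulate_ontology(
    config: SimulationConfig, truth: TruthTable
) -> tuple[Ontology, Annotation, FunctionGroupMap, TruthTable]:
    """Branch-per-function-group DAG with planted annotation enrichment.

    Each branch hangs off a single root and carries ``leaves_per_branch``
    leaf terms.  Leaves of the cAMP-specific branches annotate genes from
    the cAMP/cAMP+MPA shared up-signature; the insulin-signaling leaves
    annotate genes up under all three MPA-using stimuli; leaves of the
    common branches annotate four-way common genes (first leaf from the
    up pool, the rest from the down pool).  Every leaf adds
    ``background_per_term`` random genes, and every gene is annotated to
    the root so the background population spans the whole gene universe.
    """
    rng = _rng(config, 3)
    groups = list(config.branch_groups)
    genes = config.gene_ids()

    # signal pools derived from the planted truth
    common4_up = sorted(set.intersection(*[truth.up_genes(s) for s in STIMULI]))
    common4_down = sorted(set.intersection(
        *[truth.down_genes(s) for s in STIMULI]))
    camp_up = sorted((truth.up_genes("cAMP") & truth.up_genes("cAMP+MPA"))
                     - truth.up_genes("MPA") - truth.up_genes("E2+MPA"))
    mpa_up = sorted((truth.up_genes("MPA") & truth.up_genes("E2+MPA")
                     & truth.up_genes("cAMP+MPA")) - truth.up_genes("cAMP"))

    def shuffled(pool: list[str]) -> list[str]:
        return list(np.array(pool)[rng.permutation(len(pool))])

    common_up_pool = shuffled(common4_up)
    common_down_pool = shuffled(common4_down)
    camp_pool = shuffled(camp_up)
    mpa_pool = shuffled(mpa_up)

    root = "SYN:0000001"
    g = nx.DiGraph()
    g.add_node(root, name="biological process root",
               namespace="biological_process")
    annotation: dict[str, set[str]] = {gene: {root} for gene in genes}
    branch_label: dict[str, str] = {}

    term_counter = 1

    def new_term(name: str, parent: str) -> str:
        nonlocal term_counter
        term_counter += 1
        tid = f"SYN:{term_counter:07d}"
        g.add_node(tid, name=name, namespace="biological_process")
        g.add_edge(tid, parent)
        return tid

    def draw_signal(pool: list[str], k: int, group: str) -> list[str]:
        if len(pool) < k:
            raise ConfigError(
                f"signal pool for group {group!r} exhausted: needs {k}, "
                f"has {len(pool)}"
            )
        block, pool[:k] = pool[:k], []
        return block

    for group in groups:
        branch = new_term(f"{group} module", root)
        for leaf_i in range(config.leaves_per_branch):
            leaf = new_term(f"{group} process {leaf_i + 1}", branch)
            if group in CAMP_GROUPS:
                signal = draw_signal(camp_pool, config.genes_per_term, group)
            elif group in MPA_GROUPS:
                signal = draw_signal(mpa_pool, config.genes_per_term, group)
            elif group in COMMON_GROUPS:
                pool = common_up_pool if leaf_i == 0 else common_down_pool
                signal = draw_signal(pool, config.genes_per_term, group)
            else:  # extra user-configured group: unplanted random genes
                signal = list(rng.choice(genes, size=config.genes_per_term,
                                         replace=False))
            background = list(rng.choice(genes,
                                         size=config.background_per_term,
                                         replace=False))
            for gene in signal + background:
                annotation[gene].add(leaf)
            for gene in signal:
                branch_label[gene] = group

    ontology = Ontology(g)
    ann = Annotation({gene: frozenset(t) for gene, t in annotation.items()},
                     frozenset(genes))
    group_map = FunctionGroupMap({
        name: rules for name, rules in default_function_groups().groups.items()
        if name in groups
    }) if set(groups) <= set(default_function_groups().groups) else \
        FunctionGroupMap({name: {"ids": set(), "substrings": [name.lower()]}
                          for name in groups})

    table = truth.table.copy()
    for gene, group in branch_label.items():
        table.loc[gene, "branch"] = group
    return ontology, ann, group_map, TruthTable(table)


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run all three generators and write every fixture file to ``outdir``.

    Emits the formats the pipeline readers consume (expression TSV, MTX +
    sidecars, OBO subset, annotation TSV, group-map YAML) plus the truth
    table and the generating config; returns a manifest of paths.
    """
    from .reduction import save_function_groups

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, design, truth = simulate_bulk(config)
    cells, truth = simulate_cells(config, truth)
    ontology, annotation, groups, truth = simulate_ontology(config, truth)

    paths = {
        "bulk_tsv": outdir / "bulk_tpm.tsv",
        "design_json": outdir / "design.json",
        "mtx": outdir / "cells.mtx",
        "genes": outdir / "cells_genes.txt",
        "cells_meta": outdir / "cells_meta.tsv",
        "obo": outdir / "ontology.obo",
        "annotation": outdir / "annotation.tsv",
        "groups_yaml": outdir / "function_groups.yaml",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.json",
    }
    write_expression_tsv(matrix, paths["bulk_tsv"])
    Path(paths["design_json"]).write_text(json.dumps({
        "stimuli": list(design.stimuli),
        "control_of": dict(design.control_of),
        "protocol_days": dict(design.protocol_days),
    }, indent=2))
    write_cell_matrix(cells, paths["mtx"], paths["genes"], paths["cells_meta"])
    write_obo_subset(ontology, paths["obo"])
    write_annotation_tsv(annotation, paths["annotation"])
    save_function_groups(groups, paths["groups_yaml"])
    truth.write(paths["truth"])
    cfg = asdict(config)
    cfg["branch_groups"] = list(cfg["branch_groups"])
    cfg["up_fold_range"] = list(cfg["up_fold_range"])
    cfg["down_fold_range"] = list(cfg["down_fold_range"])
    Path(paths["config"]).write_text(json.dumps(cfg, indent=2))
    return {k: str(v) for k, v in paths.items()}
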