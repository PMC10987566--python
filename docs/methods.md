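# Methods

## Scientific setting

Decidualization is the differentiation of endometrial stromal cells
(ESCs) into decidual cells in preparation for embryo implantation. In
culture it is induced with cAMP and/or the synthetic progestin MPA,
optionally with estradiol (E2); in vivo it happens between the late
proliferative (~cycle day 9–11) and late secretory (~day 24–27) phases of
the menstrual cycle. `decidiff` implements the comparative analysis that
asks which in vitro stimulus — cAMP, cAMP+MPA, MPA, or E2+MPA — most
closely recapitulates the in vivo transcriptome change, and which
cellular functions each stimulus engages.

## DEG calling

For a gene with treated expression *t* and control expression *c* (TPM),
the fold change is

    FC = (t + ψ) / (c + ψ),   ψ = 1 (pseudocount)

A gene is up-regulated when FC > 2.0 and down-regulated when FC < 0.5.
"More than" is read as strict inequality, so FC exactly 2.0 or 0.5 is not
a DEG; both the reading and the cutoffs are configurable
(`DEGThresholds`). Bulk contrasts compare each stimulus sample with its
matched control: cAMP-containing protocols run 4 days and use the 4-day
unstimulated control, progestin-only protocols run 14 days and use the
14-day control.

The in vivo contrast is a pseudobulk comparison: per-gene mean TPM over
all late-proliferative ESCs versus mean TPM over late-secretory ESCs that
express the decidualization marker FOXO1 (strictly positive expression;
the marker and cutoff are parameters, and the filter is applied only to
the secretory side because that is where the marker is informative).
Means are computed over raw cell values *before* the pseudocount is
added. Cells are pooled across donors — the unweighted mean over cells,
not a mean of per-donor means.

Genes absent from one dataset are excluded from cross-dataset
comparisons rather than imputed as zero, to avoid manufacturing DEGs
from annotation differences.

## Set comparison and concordance

`venn_partition` assigns every gene of the union of up to six DEG sets to
its exact membership signature; compartment labels a, b, c, … follow a
canonical order (signatures sorted with membership before
non-membership, so "a" is always the all-sets compartment). The
stimulus-level Venn pools up- and down-regulated genes per stimulus by
default; per-direction partitions are also computed and persisted.

The concordance of an in vitro DEG set with the in vivo set is
direction-matched — up with up, down with down; a gene regulated in
opposite directions counts for neither — and reported as

    concordance % = 100 × (|up∩up| + |down∩down|) / (|up| + |down|)_in vitro

rounded to one decimal. The denominator is the in vitro total: e.g. 762
shared genes over 1378+2443 in vitro DEGs give 19.9%.

## GO over-representation

Annotations are closed under the is_a true-path rule, then every term
with at least one study hit is tested with the one-sided hypergeometric
(Fisher exact upper tail): population *N* annotated background genes,
*n_t* of them on term *t*, study size *m*, hits *k*, p = P(X ≥ k). Terms
with raw p < α (default 0.01) are reported with their gene ratio
k / n_t. Choices a user can change:

* `method="ease"` subtracts one from the hit count (the more
  conservative score reported by the DAVID service); plain Fisher is the
  default since the analysis criterion is simply a raw p-value cutoff.
* Benjamini–Hochberg adjustment is available (`correction="bh"`) but off
  by default, matching the raw-p criterion.
* The background population defaults to the genes appearing in the
  annotation table and can be overridden.
* Terms with zero study hits are not tested — they cannot be enriched
  and would only inflate the test count.

## Redundancy reduction and function groups

Term information content is IC(t) = −ln(n_t / N) computed from the
user-supplied annotation corpus itself (not an external release), so runs
are self-contained. Similarity between terms uses the most informative
common ancestor (MICA):

    Lin(t1,t2)    = 2·IC(MICA) / (IC(t1)+IC(t2))
    SimRel(t1,t2) = Lin(t1,t2) × (1 − p(MICA))

with p(MICA) the MICA's annotation frequency. SimRel (which down-weights
similarity through generic ancestors) is the default, matching the
REVIGO service's default; the "allowed similarity" cutoff defaults to
0.5 ("small"). Reduction is a greedy sweep in ascending p-value order
(ties: larger IC, then lexicographic id): a term more similar than the
cutoff to a kept representative is assigned to the most similar one,
otherwise it becomes a representative. The sweep is deterministic under
input permutation.

Representatives are classified into cellular-function groups by an
ordered rule map (explicit term ids and/or lower-cased name substrings;
first match wins). The shipped ten-group map (cell morphology, signal
transduction, cell proliferation, metabolism, differentiation,
angiogenesis, inflammation, immune system, embryo implantation, insulin
signaling) is an editorial keyword reconstruction of what is, in the
original analyses of this kind, a manual curation — users should supply
their own map for real data.

Specificity labels summarise per-stimulus, per-direction detection
flags, applied in order:

* **common** — detected (either direction by default; "both" mode
  available) under all four stimuli;
* **cAMP_specific** — detected among up-regulated genes of both
  cAMP-using stimuli (cAMP, cAMP+MPA) and not at all under MPA or
  E2+MPA;
* **MPA_specific** — detected among up-regulated genes of all three
  MPA-using stimuli (MPA, E2+MPA, cAMP+MPA) and not at all under cAMP;
* **other** — anything else.

These are a strict-boolean resolution of a qualitative ("mainly
detected") description; the either/both choice for common functions is
configurable.

## Clustering

Samples are clustered on log2(TPM+1) profiles with Euclidean distance
and average linkage by default; correlation distance (1 − Pearson r) and
complete/single linkage are selectable. None of the three choices is
dictated by the analysis being reproduced, so they follow common
transcriptomics practice and are documented as a reconstruction. The
agglomeration recomputes cluster distances from the original pairwise
table at each step (O(n³), exact for the three linkages) and breaks ties
by merging the lexicographically smallest eligible pair, making the
dendrogram invariant to sample order. Newick export uses branch length =
parent merge height − child height (leaves at height 0).

## Synthetic data

The generator produces the study's shapes with known truth:

* **Bulk**: 10,000 genes, six samples. Per-stimulus planted up/down
  counts default to the reported values (cAMP 1442/2109, cAMP+MPA
  1378/2443, MPA 956/1058, E2+MPA 913/1087). Signatures are composed
  from overlap pools — genes shared by all four stimuli (150 up/250
  down), by the cAMP pair (300/500), by all three MPA-using stimuli
  (150 up), by the MPA/E2+MPA pair (450 up/600 down) — plus per-stimulus
  unique genes chosen so every total is exact. The pool sizes are free
  parameters set so that (i) the planted dendrogram structure emerges
  (controls together; MPA and E2+MPA co-clustered; cAMP+MPA, carrying
  the most DEGs, farthest out) and (ii) each function-group branch has a
  large enough signal pool; they are not themselves reported quantities.
  Planted folds are drawn uniformly (up: 2.5–8; down: 0.05–0.4) and
  realised on the pseudocount scale, treated = f·(control+1) − 1, so
  threshold calling recovers f exactly at zero noise; baselines
  (log-normal, meanlog 1, sdlog 1) are raised where needed to keep
  down-regulated treated values non-negative. Optional multiplicative
  log-normal noise and optional per-sample TPM renormalization are off
  by default because both perturb planted folds.
* **Cells**: 189 proliferative and 137 secretory cells. The planted
  in vivo sets (2579 up/3768 down) share exactly ⌈0.199·count⌉
  direction-matched genes per direction with the designated stimulus
  (cAMP+MPA), i.e. 275+487 = 762 of 3821 → 19.9% by construction;
  remaining in vivo genes are drawn from genes that stimulus did not
  regulate. At dispersion 0 every cell carries its phase's exact mean
  profile (an exactness mode); with dispersion > 0, counts are
  gamma-Poisson around the means and rescaled to per-cell TPM. All
  cells express the marker positively unless a configured fraction of
  secretory cells is zeroed to exercise the filter.
* **Ontology**: one root, one branch per function group, three leaf
  terms per branch, 20 signal + 10 background genes per leaf. Signal
  genes come from the pool matching the group's planted specificity
  (cAMP-pair genes → angiogenesis/inflammation/immune/implantation;
  triple-MPA genes → insulin signaling; four-way common genes → the five
  common groups, first leaf from the up pool, the rest from the down
  pool). Every gene is annotated to the root, so the background
  population is the whole gene universe. Branch and leaf names embed the
  group keywords so the shipped rule map recovers the planted grouping.

All randomness flows from one seed; each generator derives an
independent stream from it, and identical configs produce byte-identical
fixture files.

### What the generator does not emulate

No dropout curves fitted to real data, ambient RNA, doublets, donor
batch structure, gene-length or GC effects, and no realistic GO topology
(the synthetic DAG is shallow and balanced). Passing the zero-noise
recovery tests therefore demonstrates correctness of the pipeline's
logic and arithmetic, not robustness to real single-cell noise; the
moderate-noise recall property (log-sd 0.1, planted folds ≥ 4, recall
≥ 0.95 over 10 seeds) probes robustness only in a mild, idealised noise
regime.

## Numerical choices and degenerate inputs

* Fold changes and p-values serialize with 6 significant digits;
  round-trip tests compare at that precision.
* MatrixMarket files are 1-based on disk, 0-based in memory; unlisted
  coordinates are zeros.
* Similarity returns 0 for cross-namespace pairs and when IC(t1)+IC(t2)
  = 0; terms with no annotated gene are excluded from similarity.
* Empty study sets yield empty enrichment reports (with a logged
  warning); an empty in vitro DEG set makes the concordance ratio
  undefined and raises.
* Distance tables must be symmetric with a zero diagonal; clustering of
  a single sample is rejected.
* Statistical calibration of the enrichment test is asserted against the
  exact attainable level of the discrete hypergeometric just below α
  (the test is conservative by discreteness), not against α itself.

## Problem sizes

The default synthetic study (10,000 genes, 6 samples, 326 cells, a
31-term ontology) runs the full pipeline in a few seconds; the test
suite's statistical simulations use 1000 enrichment replicates on a
2000-gene population and ten 2000-gene bulk simulations, sizes chosen to
make the binomial tolerances tight while keeping the suite quick to run.

## Known limitations

* The function-group keyword map cannot be validated against the
  original manual curation; it is validated only on synthetic
  ontologies whose names embed the keywords.
* Gene identifiers are matched case-sensitively by symbol with no alias
  resolution; cross-dataset comparisons of real data need harmonised
  annotations upstream.
* Only is_a links are interpreted in OBO input; part_of and other
  relationships are ignored.
* Threshold DEG calling uses no replication or count model; it is the
  method being reproduced, not a recommendation.
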