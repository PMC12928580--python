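# Methods

## Model and assumptions

The pipeline treats a tumor cohort as a pair of per-sample binary feature
sets: an intrinsic vector (which curated driver genes carry an event in the
patient, encoded 0/1) and an extrinsic vector (which frequent communication
subnetworks the sample's multi-cell-type communication network contains).
The core statistical object is the association between one intrinsic column
and one extrinsic column, assessed by a one-sided Fisher's exact test over
pseudo-samples. This presumes:

* driver annotations are correct and binary — no allele dosage, no
  continuous copy-number variation;
* communication is adequately summarized by an unweighted labeled graph on
  (gene, cell type) nodes with intracellular/intercellular edge types;
* a pattern's relevance is captured by presence/absence, not by strength.

### Pseudo-sampling

Cohorts of 10–30 patients are too small for contingency testing, so each
eligible patient (≥ `min_cells` = 20 cells in **every** focal cell type) is
expanded into `repeats` = 5 bootstrap pseudo-samples, each drawing
round(0.5 · n_t) cells *with replacement* per focal type t. Rounding is
half-to-even. Undersized patients are excluded by default; a policy flag
includes each once, unresampled (replicate index 0), since both behaviors
are legitimate cohort-construction choices. Randomness uses one master seed
plus a per-(patient, replicate) stream keyed by a stable hash of the
patient ID, so adding or removing patients never perturbs other patients'
draws.

Pseudo-samples from one patient are statistically dependent (they share the
driver label and resample the same cells). The Fisher test treats them as
exchangeable units, which anti-conservatively inflates the effective sample
size; this is the method's deliberate power/validity trade-off. Patient
level support counting can be approximated by mining with a support
threshold expressed per patient, and the association family structure is
exposed (`family="per_driver"` vs `"global"`) so users can tighten control.

### Network construction

A `NetworkBackend` yields one network per pseudo-sample. The **external**
backend ingests precomputed per-sample edge lists from any dedicated
signal-transduction inference tool (weights and node prizes are stripped on
read — mining is weight-blind by design). The **lite** backend is a
transparent co-expression rule: an intercellular edge (L@A)–(R@B) is added
when ligand L is expressed (> 0) in at least `expr_frac_threshold`
(default 0.1) of type-A cells and receptor R likewise in type-B cells, both
genes having passed the per-type low-expression filter (expressed in ≥ 5%
of that type's cells, recorded as a per-(gene, type) retention mask rather
than global gene dropping). Intracellular edges from a user-supplied
gene-interaction network are added around the used ligands/receptors up to
`hop_radius` hops (default 1). The lite backend captures co-expression of
annotated ligand–receptor pairs only; it encodes no mutual-information or
pathway evidence, and exists so the pipeline runs self-contained.

Pairwise networks are unioned per sample; an edge claimed both
intracellular and intercellular is an error rather than silently resolved.

### Frequent subnetwork mining

Mining is gSpan over undirected labeled graphs: node labels are
`gene@celltype` strings, edge labels the intra/intercellular kind. Patterns
grow by rightmost-path extension; each candidate DFS code is kept only if
it is the minimum DFS code of its pattern (canonicality check via the
greedy state-set minimal-code construction), which enumerates each
isomorphism class exactly once. Support sets are exact, tracked through
embedding lists; containment is label-preserving subgraph isomorphism —
occurrences need not be induced subgraphs. Single-node patterns are
excluded (signatures are interactions); `max_edges` defaults to 5 since
reported signatures are 1–2 interactions, and caps the exponential search.
Determinism: pattern output is sorted by canonical code, so results are
independent of input graph order.

The support threshold is the user's robustness/sensitivity dial. The
`choose_support` helper suggests ceil(prevalence · n_samples) for a driver
prevalence of interest. The simulation analyses in this repository use
min_support = max(2, ceil(0.15 · n_samples)) — deliberately below typical
driver prevalence so that patterns carried predominantly by driver-positive
samples still clear the mining threshold and reach the association stage.

### Association testing

For each (driver, pattern) pair the 2×2 table over pseudo-samples is tested
with Fisher's exact test, alternative "greater" on the co-occurrence cell:
the target is patterns that appear *together with* the driver, not mutual
exclusivity. The reported odds ratio is the unconditional ad/bc (infinite
when bc = 0 with a > 0). Benjamini–Hochberg correction is applied within
each driver's family of tested patterns; per-driver families match how
per-driver signature counts are reported, and a global family is available
behind a flag. Drivers present in none or all samples carry no contrast and
are skipped with a warning. Significant results (adjusted p < 0.05) are
ranked per driver by adjusted p, then raw p, then higher odds ratio, larger
co-occurrence count, and pattern id — an arbitrary but fully deterministic
tie-break.

### Intrinsic–extrinsic paths

Communication networks are ligand–receptor centered, so the driver gene may
be absent. Expansion proceeds in breadth-first rounds: each round adds the
intracellular first-order neighbors of all current nodes, within the cancer
cell type only (the driver is cancer-cell-intrinsic; a flag expands all
types), stopping at the first round containing the driver node — the
stopping round is therefore minimal by construction. `max_rounds` defaults
to 6 with explicit unreachable flagging. IE paths are unweighted shortest
paths from the driver node to *each* node of a signature
(`mode="all_shortest"` returns every minimal route; `mode="one"` the
lexicographically smallest by node labels); a summary distance-to-signature
is the minimum over signature nodes. Unreachable targets warn and yield
empty paths rather than failing, since signatures may span components.

### Downstream evaluation

* **MHC-I score**: arithmetic mean of HLA-A, HLA-B, HLA-C, TAP1, TAP2,
  NLRC5, PSMB9, PSMB8, B2M per bulk sample; absent genes are dropped with a
  warning.
* **CYT score**: geometric mean of GZMA and PRF1 with pseudocount 0.01
  (the convention of the cytolytic-activity literature; configurable).
* **Survival stratification**: for each signature gene, the single-cell
  cohort defines Hi/Lo cell subtypes by a median split (ties at the median
  go Lo — deterministic); bulk patients are split by the median of the
  Hi-subtype abundance (supplied by an external deconvolution tool, or the
  built-in NNLS fallback normalized to sum to one); the k genes of a
  signature define up to 2^k combinatorial groups; survival differences use
  the multi-group log-rank test (lifelines), with Kaplan–Meier curves
  exported as tidy tables. Abundance medians are computed within the
  analyzed subcohort.
* **CNV driver calling**: per patient and candidate gene, a two-sided
  two-sample KS test compares tumor-cell vs reference-diploid-cell inferred
  CNV values; BH is applied per patient (a global family is available) and
  genes with adjusted p < 0.01 are called. CNV inference itself is consumed
  as input, not performed.

## Synthetic data

The generator plants associations of controlled strength and is the test
harness for every stage. Study conditions (the defaults): 60 samples,
driver prevalence π = 0.4, planted motif presence probabilities 0.9 given
driver⁺ and 0.1 given driver⁻, plus a null motif at 0.3/0.3; a motif is
truly associated iff its conditional probabilities differ.

* The **network path** draws per-sample networks directly (motif edges plus
  background edges over a disjoint gene label space at density 0.004),
  bypassing any backend — this isolates mining + association.
* The **expression path** draws negative-binomial counts (dispersion 2;
  background mean 2 counts, planted genes 8 where "on" and 0.02 elsewhere)
  for 12 patients × 3 cell types × 40 cells, so the lite backend recovers
  planted edges from co-expression; it exercises normalization, filtering,
  pseudo-sampling, network construction and testing end to end.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, cell-type misassignment, realistic gene-gene correlation, or
dependence between motifs. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
generative model, not robustness to real single-cell artifacts.

## Numerical and design choices

* Normalization is counts-per-10k + log1p (natural log), the common
  single-cell default; pre-normalized input is accepted as-is.
* Gene symbols match case-sensitively after whitespace stripping; no alias
  resolution, for deterministic behavior without external databases.
* The low-expression filter is applied once on the full cohort, not
  re-applied per pseudo-sample.
* Non-focal cell types are passed through unresampled; the lite backend
  only consumes focal-type expression.
* Monte-Carlo analyses (type-I error: 200 replicates of 40-sample null
  cohorts; power: 100 replicates of the 60-sample planted condition) use
  sizes chosen to make a ±2 standard-error acceptance band decisive.
* Degenerate inputs fail loudly: zero-cell cell types, constant genes at a
  median split, rank-deficient signature matrices, saturated drivers and
  empty networks all raise typed errors or warnings as documented on each
  function.

## Known limitations

* Pseudo-sample dependence (five correlated replicates per patient) is not
  modeled in the test; p values are calibrated per pseudo-sample, not per
  patient.
* The lite backend is a co-expression heuristic; biological conclusions
  should rest on a dedicated signaling-inference backend via the external
  interface.
* Mining cost grows exponentially in `max_edges` and with dense networks;
  the support threshold is the practical control.
* Functional enrichment of IE-path gene sets is out of scope; the module
  exports gene lists ready for external enrichment tools.
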