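# Methods

## Scope and data model

The package takes a chemotaxonomic study from processed LC–MS/MS exports to
clade-level evolutionary statements. Its inputs are the artifacts a feature
finding tool (e.g. MZmine) exports — MGF spectral summaries and CSV feature
quantification tables, one pair per ionization mode — plus sample metadata
(sample → species → genus → clade, extraction solvent, mode), per-feature
chemical classifications with binary fingerprints, and a rooted, genus-tip
phylogeny with named clades. Feature detection itself, in-silico structure
prediction, and phylogeny inference are upstream of the package: their
outputs are inputs here.

Retention times are minutes internally (`RTINSECONDS` converted on read).
Unknown charge defaults to ±1 by ionization mode. The two ionization modes
are kept as separate tables end to end and only merged at the binary
character stage; features absent from one mode are never zero-padded into
the other.

## Spectral cleaning and modified cosine

Cleaning reproduces the standard molecular-networking preparation:
fragments within ±17 Da of the precursor are removed (residual precursor
ions), then a rolling window filter keeps a peak only if it is among the
top six intensities within ±50 Da of its own m/z. All "within ±W" windows
are closed intervals (≤). Window-filter intensity ties break toward lower
m/z, making both filters deterministic and idempotent.

For scoring, peaks are weighted √intensity and scaled to unit norm —
damping base-peak dominance, the convention that keeps scores comparable
with GNPS-style cosines. Candidate peak pairs match directly or shifted by
the precursor-mass difference (fragment tolerance 0.02 Da, closed); each
peak may be used once. The score is the maximum of Σ wᵢwⱼ over one-to-one
assignments, solved exactly as a maximum-weight bipartite matching
(`scipy.optimize.linear_sum_assignment`); a greedy descending-product
assignment is available as an option for comparison with tools that use
it. Exact assignment makes the score provably symmetric and bounded in
[0, 1], and the test suite checks it against an independent brute-force
enumeration over candidate subsets. Network edges require cosine strictly
above 0.7 **and** at least 4 matched peaks; raising the threshold can only
remove edges.

Library annotation finds, per query, the best-scoring reference spectrum
whose precursor agrees within 0.02 Da and that passes the same thresholds
(ties: more matched peaks, then library order). Blank subtraction is an
optional node filter (a feature is dropped when its mean blank area is at
least a configurable fraction, default 0.5, of its mean sample area):
the underlying criterion in practice is qualitative, so the threshold is a
documented stand-in and off unless blanks are flagged.

## Ordination and significance

Bray–Curtis compares extraction protocols; Canberra (both-zero features
skipped, no renormalization by feature count — the common ecology variant)
compares the per-mode/per-solvent subsets. PCoA eigendecomposes
−½·J·D²·J; axes with non-positive eigenvalues are dropped, negative
eigenvalues are reported but not corrected (no Lingoes/Cailliez), and
proportions explained use the positive-eigenvalue sum. On Euclidean
distances this reproduces PCA scores up to sign.

PERMANOVA is one-way with unrestricted raw-label permutations:
SS_total = Σ_{x<y} D²/N, within-group sums analogous, pseudo-F =
(SS_b/(k−1))/(SS_w/(N−k)), p = (1 + #{F* ≥ F})/(1 + n_perm) with a seeded
generator (999 permutations by default). The permutation loop is
vectorized via group-indicator quadratic forms. The suite verifies exact
equality with classical ANOVA on univariate Euclidean data and calibrates
the type-I error over 500 null resamplings.

The "two chemical profiles" of an ordination are operationalized — the
original judgement was visual — as an exact 2-medoid partition (all medoid
pairs enumerated, O(n³), fine at study scale), label A fixed to the group
containing the lexicographically first sample.

## Class enrichment

Class relative abundances are per-sample area shares (features without a
class label form an unmodeled remainder). Values are arcsine-square-root
transformed, each class tested by one-way ANOVA across clades,
Benjamini–Hochberg adjusted **across classes**, with Tukey HSD pairwise
contrasts on the transformed scale and log₂ fold changes of the
untransformed clade means (±inf when a mean is zero — no pseudocount, so a
planted 2× enrichment yields exactly 1.0). Classes constant across all
samples are untestable and skipped with a note. The heatmap matrix keeps
classes with adjusted p below α = 0.05.

The fingerprint hierarchy clusters binary fingerprint vectors (treated as
0/1, not probabilities) by Euclidean distance with average linkage
(ward/complete selectable); input order is canonicalized so the tree is
reproducible. Pruning to superclass-classified leaves contracts unary
nodes with branch lengths summed, preserving leaf-to-leaf path lengths.

## Character coding

Species presence = class abundance strictly above a floor (default 0) in
at least one sample. Genus state = 1 iff the arithmetic mean of its
species presences strictly exceeds a threshold whose default is 0, i.e.
presence in any sampled species marks the genus — the only reading of a
mean-then-binary rule that needs no extra cutoff; both knobs are exposed.
Ionization modes merge by logical OR with per-character provenance
(pos/neg/both). Matrices round-trip through TSV and a NEXUS characters
block.

## Mk1 ancestral state reconstruction

The model is the symmetric two-state Markov chain: P(same) = ½+½e^(−2qt),
uniform root prior, non-ultrametric trees accepted, zero-length branches
replaced by ε = 1e-8. Likelihoods use Felsenstein pruning, vectorized over
characters with per-node rescaling. The rate is fitted per character by
default (a shared-rate fit over the whole matrix is available): because
the log-likelihood flattens toward high rates, the optimizer first scans a
40-point log-spaced grid over q ∈ [1e-8, 200] to bracket the optimum, then
refines with bounded scalar minimization (xatol 1e-10). Constant
characters are pinned at the lower bound and flagged.

Marginal node probabilities come from the standard up/down two-pass
computation and are reported for every node; MAP ties at exactly 0.5
resolve to state 0 with a flag. For *counting state changes*, a labeling
must be a single consistent history: per-node argmax of marginals is not
(adjacent nodes can each be individually most probable while the implied
edge changes correspond to no scenario), so origin counting uses either

* **fitch** (default): Fitch parsimony with parent-preference resolution —
  the fast-optimization style that favors homoplasies, matching how such
  studies count origins in practice; or
* **ml**: the jointly most probable labeling (max-product analogue of
  pruning, Pupko-style) under the fitted rate.

The default is parsimony because per-character ML rate estimates on
clade-concordant presence patterns are large enough that even the joint-ML
labeling sometimes scatters parallel gains where a single stem gain
exists; in simulations with planted clade markers the parsimony labeling
recovers the stem gain essentially always, the joint-ML labeling in
roughly half to three quarters of cases.

A clade call for a character: let s be the state uniform across the
clade's tips (polymorphic → uninformative). With the clade's MRCA labeled
s and its parent ¬s (a stem change), the call is synapomorphy if s
originates exactly once on the tree (gains for s = 1, losses for s = 0),
homoplasy if more than once; no stem change → uninformative. Characters
present in (or absent from) all genera get no clade calls and are listed
as ubiquitous. The tree is pruned to the sampled genera before analysis;
clades that lose monophyly under pruning are dropped with a warning.

## Synthetic data generator

The generator's defaults are the study conditions every test and the
acceptance script use; they emulate:

* **Compound families** (default 8 per mode, 4 members, 8 peaks): a base
  spectrum (precursor U(350, 800) Da; fragment m/z ≥ 20 Da apart, below
  precursor − 30; lognormal intensities scaled to max 100) plus
  derivatives shifted by cumulative glycosidic neutral losses (hexoside
  162.053, deoxyhexoside 146.058, pentoside 132.042, water 18.011 Da),
  with fragments above the median mass shifted along. Within a family
  every fragment aligns directly or via Δprecursor, so the modified cosine
  is ≈1 with ≥4 matched peaks by construction; between families chance
  alignments at 0.02 Da are negligible. Networking therefore recovers
  families as components (adjusted Rand ≥ 0.95 across seeds).
* **Clade-structured tables** (default 16 genera, 2 species each, 4
  derived clades): lognormal areas (μ = 10, σ = 1 on the log scale —
  typical peak-area dynamic range) with 10% Bernoulli dropout (at least
  one detection kept per feature). One class per clade is planted: its
  features have nonzero areas only in that clade's samples.
* **Solvent complementarity**: per-feature detection patterns across the
  two extraction solvents drawn with the shared / hydroethanolic-only /
  ethyl-acetate-only proportions reported per mode (74/21/5 % positive,
  59/36/5 % negative); planted features redraw between the two
  hydro-containing patterns so the downstream (hydroethanolic) analyses
  always see them. A per-feature lognormal factor (σ = 0.8) scales
  ethyl-acetate areas, emulating extraction-dependent relative abundance.
* **Mode complementarity**: planted classes ionize in both modes; the
  remaining class inventory alternates between modes.
* **Phylogeny**: pure-birth (Yule) tree conditioned on the tip count,
  made ultrametric, root age normalized to 1. Named clades either derive
  from the drawn tree (guaranteed monophyletic) or honor an explicit
  partition by resampling. Because the process is conditioned on tip
  count, the birth-process tip-count expectation is not directly
  testable; the suite instead checks ultrametricity, determinism,
  monophyly, and the per-branch Mk flip frequency against its closed form.
* **Mk characters** (default q = 0.5 on the height-1 tree — moderately
  informative, ~⅔ of characters variable): forward simulation recording
  true node states and origin counts.
* **Fingerprints**: one random binary prototype per class (length 64),
  inherited with 3% bit flips; 10% of features left unclassified to
  exercise pruning.

A single seed drives one child RNG stream per artifact
(`numpy.random.SeedSequence.spawn`), so identical seeds reproduce
byte-identical files even when stages are re-run alone.

What the generator does **not** model: chromatography (retention-time
structure), isotopes and adducts, instrument noise, mass-calibration
drift, shared peaks between unrelated compounds, or rate variation across
characters. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted structure under idealized
conditions, not robustness to real-data artifacts.

## Problem sizes and numerics

Tests and the acceptance script run the study at desk scale: 10–16 genera,
2 species per genus, 6–8 compound families per mode, 500 characters (32
tips) for rate recovery, 999 permutations per PERMANOVA and 500 null
resamplings for calibration. Tolerances: oracle agreement 1e-9 (cosine)
and 1e-10 (likelihood); PCoA/PCA agreement 1e-8; BH agreement 1e-12;
PERMANOVA/ANOVA equality 1e-10. Degenerate inputs are either errors
(all-zero samples, empty post-pruning trees, non-monophyletic clades) or
flagged deterministic choices (zero-area network nodes, MAP ties,
two-group clustering of identical points).

## Pipeline and CLI

`run_pipeline` executes ingest → network (+ library search + solvent
overlap) → ordination/PERMANOVA (+ two-group clustering) → enrichment (+
chemistry tree) → character coding → ancestral reconstruction, writing
plain-text artifacts and a manifest (package version, config hash, seed,
per-stage counts). Stages are individually skippable; a failure aborts
with the stage name and leaves a `.partial` marker. The `chemophylo` CLI
wraps simulation, ingestion, the full run, stage-wise runs, and ASR.

## Known limitations

* Single-rate, two-state characters only; no ambiguity codes, no rate
  heterogeneity, no stochastic character mapping.
* Per-character ML rates from one binary character are noisy by nature;
  synapomorphy calls therefore rest on the parsimony labeling (see above).
* The 2-medoid profile clustering is an operationalization of a visual
  judgement; with weak separation its output is deterministic but not
  meaningful, and it is flagged.
* GNPS-style topK-neighbor pruning and maximum-component splitting are
  available as options but off by default, since the modeled workflow did
  not report them.
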