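# Methods

## The classification model

Each protein is represented by one fixed-width vector: the mean over
per-residue encoder states of a frozen protein language model (ProtT5,
1024 dimensions) or of a synthetic provider implementing the same pooling
contract. Mean pooling is the standard per-protein reduction for ProtT5;
providers are deterministic by contract (identical sequence → bit-identical
vector), and the per-protein vector of a homopolymer equals the
single-residue state exactly, which the tests use as a pooling identity.

Both cascade stages are C-support vector machines with an RBF kernel at
ecosystem-default hyperparameters: regularization C = 1.0 and kernel width
γ = 1 / (n_features · Var(X)) (the "scale" heuristic). Probabilities come
from Platt-style sigmoid calibration of decision values, fitted by the
library's internal cross-validation and seeded for reproducibility. No
hyperparameter search is performed anywhere: the method's claim is that
embeddings plus default SVMs suffice, and the package preserves that.

Decisions are strict inequalities throughout. Stage 1 calls a lysin iff
P(lysin) > t₁; a score exactly at the threshold is negative. Stage 2 runs
only on predicted lysins and calls endolysin iff P(endolysin) > t₂, else
VAL, mirroring the stage-1 rule. Which subtype the published models
thresholded on is not documented; this package thresholds the endolysin
probability and records the choice in the model-bundle metadata so it is
auditable. Thresholds default to 0.5 internally; the CLI speaks percent.

## Dataset construction

Negatives for stage 1 are built in two steps. First, annotation-exclusion
filtering retains a protein iff it has at least one annotation term and no
term contains (case-insensitive substring) any exclusion term. The packaged
exclusion list (peptidase, amidase, lysozyme, deacetylase, endolysin,
lysin, glucosaminidase, muramidase, transglycosylase, glycosidase, spanin,
holin, …) covers the canonical lysin-related vocabulary but is explicitly
non-authoritative and user-overridable: free-text annotation vocabularies
differ between sources, and a production build should review the list
against its own annotation source. Second, the retained set is
dereplicated to one uniformly drawn representative per homology cluster
(seeded). Positives are never dereplicated — intra-cluster sequence
variation among lysins is training signal — so `assemble_dataset` takes
positives as the full member set and negatives as representatives.
Substring matching is deliberately aggressive (it removes, e.g., any
"...amidase..." annotation): false negatives in the negative pool are far
more damaging than discarded candidates when negatives outnumber positives
by orders of magnitude.

## Evaluation protocol

Cross-validation folds are assigned to homology clusters, not proteins.
Per repeat, clusters are shuffled with the seeded generator, stably sorted
by descending member count (the shuffle breaks ties), and greedily
assigned to the currently smallest fold by protein count. This is
deterministic, and bounds fold imbalance by the largest cluster size,
whereas pure random assignment can produce empty or degenerate folds on
skewed cluster-size distributions. Each fold serves once as the test set;
r repeats of k folds yield r·k iterations (10×10 = 100 for stage 1,
50×5 = 250 for stage 2 at production scale).

Metrics are positive-class precision, recall and F1 from the confusion
matrix. Zero-denominator cases yield *missing* — not 0, not 1 — and F1 is
missing whenever either parent is; this keeps threshold-sweep endpoints
honest instead of silently imputing. Threshold sweeps evaluate the fixed
per-iteration score vector at 0–100% in 5% steps (21 rows, strict >);
refitting per threshold cannot change scores, so one fit per iteration is
used. Aggregate uncertainty is the empirical 2.5/97.5 percentile interval
across iterations — distribution-free and standard for repeated CV. Splits
whose training side lacks a class are recorded as skipped with a warning,
never silently dropped.

## Domain-architecture analysis

Domain segments (SPAED-style structure-derived intervals, 1-based
inclusive) are categorized from Pfam hits: hits with missing E-value or
E-value ≥ 0.001 (strict <) are discarded; each surviving hit is attributed
to the segment containing the midpoint of its interval (robust to small
boundary disagreement between segmentation and HMM alignment; hits already
in per-segment coordinates trivially contain their own midpoint); each
segment takes the category of its lowest-E-value attributed hit whose
accession is in the domain dictionary, with ties broken by longer hit then
lexicographic accession for determinism. Segments whose only hits are
absent from the dictionary stay UNKNOWN but record the best accession, so
"unknown-with-hit" cases remain auditable. The packaged dictionary maps
the canonical lysin domain families (Ami2/PF01510, SLT/PF01464,
GH_108/PF05838, the four PET_M15 accessions, glucosaminidase, lysozymes,
CHAP, PET_M23 → EAD; PG1/PF01471, PG3/PF09374, SH3 family, LysM → CBD) and
is user-extendable; because the PET_M15 family spans four accessions,
frequency tables are emitted per accession, which callers can regroup.

Downstream statistics follow directly: architecture strings in N→C order,
modularity histograms binned 1/2/3/4/≥5, positional fractions over the
bimodular stratum (EAD@N, EAD@C, CBD@N, CBD@C — not summing to 1 because
UNKNOWN and MISC exist), and occurrence counts split by globular
(modularity 1) vs modular context with repeated copies each counted.
Structure-confidence filtering retains proteins with mean pLDDT strictly
above 70. The physicochemical panel uses Biopython: molecular weight from
average isotopic residue masses minus (n−1) waters, and GRAVY as mean
Kyte–Doolittle hydropathy; only the 20 canonical residues are accepted and
offending positions are reported. Isoelectric point is deliberately
omitted from the default panel.

## The synthetic benchmark

The generator draws a two-level hierarchical Gaussian in d dimensions:
class means sit `class_separation` apart on the first axis; cluster
centers ~ N(class mean, σ_b²·I); members ~ N(center, σ_w²·I). Within the
positive class, subtypes are a cluster-level property (alternating across
clusters, offset `subtype_separation` on the second axis), matching how
real homology groups share function. Defaults — d = 32, 40 clusters per
class of 25 members (2000 vectors), σ_w = 0.5, σ_b = 1.0, separations 4 —
give a benchmark that is clearly separable in aggregate yet has individual
clusters near the boundary, so cluster-aware CV is genuinely exercised;
it runs in seconds. The label-permuted variant shuffles the cluster→label
map while keeping each cluster label-coherent, destroying signal but
preserving the grouping structure.

What the generator does *not* emulate: the anisotropic, manifold-like
geometry of real protein-language-model embeddings, class imbalance at
production ratios (≈1:3 lysin:non-lysin and worse), heavy-tailed cluster
sizes, and annotation noise. Passing tests therefore demonstrate that the
pipeline's machinery is correct — leakage-free splitting, calibrated
thresholding, exact bookkeeping — not that production-scale F1 on real
data will match the synthetic figure.

## Problem sizes and numerical choices

The test and acceptance workloads use the 2000-point default draw with
3×3 cluster-aware CV (9 SVM fits per condition) and a 200-dataset leakage
audit at small cluster counts — sizes chosen so the whole suite completes
in seconds while the statistics of interest (mean F1 over iterations,
split invariants) are stable. Embeddings are stored as float32 (matching
half/single-precision encoder output); SVM fits run in float64. All
randomness flows through seeded NumPy generators; CV, dataset draws,
representative selection and label permutation are bit-reproducible per
seed.

## Known limitations

- The real ProtT5 backend requires the optional heavy dependencies and
  locally cached weights; without them it raises a "provider unavailable"
  error rather than falling back, and the test suite exercises only the
  error path plus the synthetic providers.
- The packaged exclusion-term list and domain dictionary are reasonable
  defaults, not curated authorities; production analyses should supply
  their own.
- Whether consensus-sequence embeddings should use the same pooling as
  member embeddings is an open modelling question; the embedding store
  records the provider name so mixed-provenance stores remain auditable.
- MMseqs2, InterProScan, structure prediction and domain segmentation are
  consumed as inputs, never executed by this package.
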