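# Methods

## Model

The regressor maps a (drug, sample) pair to a scalar ln IC50 (natural log
of a µM concentration; stored exactly as screening databases provide it and
never re-transformed internally).

**Drug featurization.** Atoms are nodes; hydrogens are implicit, encoded
only through the per-atom total-H-count block, which keeps node counts in
the 5–96 range typical of screening libraries. The 75 columns decompose as
44 (element one-hot, last slot = "other") + 11 (degree 0–10) + 7 (implicit
valence 0–6) + 1 (formal charge) + 1 (radical electrons) + 5 (hybridization
SP/SP2/SP3/SP3D/SP3D2) + 1 (aromatic flag) + 5 (H-count 0–4). The element
vocabulary is frozen as a module constant so featurization is reproducible
across toolkit versions; unknown elements map to "other" rather than
erroring. Degenerate inputs clamp: degree/valence/H-count above the block
range take the final slot, and hybridizations outside the five listed
states (e.g. the S state of an isolated ion) take the SP slot. Bond order
and stereochemistry are deliberately not encoded — the adjacency is binary.

**Padding.** All drug graphs embed top-left into a 100-node zero template
with a node mask. The normalized adjacency of the padded graph has the
native graph's normalized adjacency as its top-left block (padded nodes
receive only a unit self-loop), and batch-norm statistics and pooling are
restricted to masked-in nodes, so padding is exactly neutral: the padded
embedding equals the native-size embedding bit-for-bit in exact arithmetic,
and within 1e-5 in float32 (measured 0.0).

**Graph convolution.** `H' = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)` with
`D̃[k,k] = Σ_m (A+I)[k,m]`. Isolated nodes get Â[k,k] = 1, the limit of the
formula at degree zero. The layer order — propagate → batch-norm → ReLU →
dropout — is a design choice; the components are standard, their order is
not dictated by the architecture. GCN layers carry no additive bias when
batch-norm is enabled (the BN shift subsumes it).

**Bio branch.** The (expression, CNV) pair per gene passes through a
two-layer MLP (2 → 32 → 32 by default) applied independently per gene; the
encoded features then propagate over the shared PPI adjacency. The PPI
adjacency is built from a scored edge list with a configurable minimum
combined score (default 700 on the STRING 0–1000 scale; the appropriate
cutoff depends on the database release, so it is a parameter rather than a
constant). Genes missing from an omics source impute to 0 — the population
mean on the z-score scale — with a logged warning.

**Head and training.** Branch embeddings (masked global max pooling;
masked mean available) are concatenated into an MLP with ReLU hidden
layers and a linear scalar output. Loss is MSE on ln IC50; optimizer is
Adam (lr 1e-3, batch 64); an internal seeded 90/10 split drives early
stopping (patience 10) with best-epoch weight restoration. Targets are
centered by the training-set mean, which is stored in the model and added
back at inference — without this the scalar output bias must drift slowly
toward the target mean (ln IC50 means are far from zero) and wastes most
of the optimization budget. One seed controls initialization, the split,
shuffling and dropout; repeated runs are bit-identical on one machine
(cross-machine bitwise equality is not promised). The whole network —
layers, hand-derived backward passes, Adam — is NumPy in float32.

Default widths are two 64-wide GCN layers per branch and a 128→64→1 head
with dropout 0.2. These are CPU-scale defaults chosen so that the test and
verification workloads (hundreds of pairs, tens of epochs) train in tens
of seconds on one core; all widths, depths and optimization settings are
configuration fields, so larger settings used for full screening corpora
are reachable without code changes.

## Preprocessing rules

Cell-line filters: drop samples missing expression or CNV, drop samples
without a cancer-type annotation, then drop every sample whose cancer type
retains fewer than 10 samples; each removal is logged with its reason, and
the filter is idempotent. Drug filters: keep only drugs with a PubChem
identifier, and drop every member of any group of distinct screening-panel
identifiers sharing one PubChem identifier (ambiguous chemical identity).
Expression is log2(TPM+1), copy number log2(CN+1); z-scoring is per gene
with population SD, fit on training folds only and applied to held-out
folds — the conservative choice where pooling before cross-validation
would leak validation statistics. Constant genes map to 0 under z-scoring.

Segment-level clinical CNV collapses onto a gene of length L as
`log2(Σ_s c_s·l_s/L + (1 − Σ_s l_s/L) + 1)`: a length-weighted mean ratio
with the uncovered remainder at neutral ratio 1. Coordinates are 1-based
inclusive (Ensembl convention); BED input is converted on read. Segments
that mutually overlap within a gene are an error, not silently averaged —
the formula presumes a partition of the covered portion.

## Evaluation protocol

k-fold (default 5) cross-validation partitions drug–sample pairs at
random with seeded folds whose sizes differ by at most one. Pair-level
splitting is the convention this family of regressors is compared under;
leave-drug-out or leave-sample-out regimes answer a different question and
are not implemented. Metrics: Pearson r, Spearman ρ (average ranks on
ties), RMSE; constant vectors yield NaN correlations with a warning rather
than a silent 0. Per-group aggregation (cancer type or drug) computes the
within-fold Pearson r per group, then the mean and population variance of
r across scored folds plus the mean per-fold group size; folds where a
group has fewer than two pairs or a constant vector are skipped with a log
message. The report stores per-fold values so either SD or variance can be
presented.

## Clinical scoring

TCGA-style response grades binarize as complete/partial response →
sensitive, progressive/stable disease → resistant; any other string is an
error listing the valid categories. Duplicate annotations for one
(patient, drug) resolve to the worst response (resistant dominates),
logged. The DSS formula operates on the linear µM scale, so model output
is exponentiated exactly once, at the DSS boundary. DSS is strictly
decreasing in IC50, bounded above by ln 2, unbounded below; its sign is
positive exactly when IC50 < MSC. The ROC uses observed DSS values as
thresholds; the AUC is the Mann–Whitney statistic with half credit for
ties, and trapezoidal integration of the emitted curve reproduces it to
machine precision (tied scores advance the curve diagonally in one step).
No confidence interval is reported for the AUC: none of the standard
constructions was singled out by the use case, and reporting an arbitrary
one would suggest more precision than intended.

## Synthetic data

The generator emulates every external input at desk scale. Molecules are a
50/50 mix of a bundled pool of 32 real small-molecule SMILES and random
connected graphs (random spanning tree plus extra edges, degree ≤ 10)
whose one-hot blocks are internally consistent — degree one-hots always
match adjacency row sums — with atom counts uniform on [5, 96] and a
per-molecule aromatic probability drawn uniformly so aromatic fractions
vary across drugs. PPI networks are Erdős–Rényi (default density 0.10) or
preferential-attachment graphs. Expression is log-normal TPM and CNV is
log-normal around the neutral ratio, both then log-transformed like real
data; the first ~10% of genes form a designated module sharing per-sample
latent factors in each channel.

The planted response is
`ln IC50 = α·(aromatic fraction) + β·(mean module expression) + γ·(mean
module CNV) + δ·(aromatic × expression) + N(0, σ)` with defaults α = 2,
β = 1, γ = 2.5, δ = 0.5, σ = 0.3 and default sizes 20 drugs × 30 samples ×
50 genes. The predictors were chosen to be representable by both branches
(a graph-level atom-feature fraction; module-mean omics readable through
the gene encoder and pooling), so recovery experiments test the
implementation rather than the architecture's ceiling: at these defaults a
60-epoch model reaches held-out Pearson ≈ 0.95–0.98 against a noise
ceiling of ≈ 0.97. What passing does not show: real dose–response data
have heteroscedastic noise, drug- and tissue-specific IC50 ranges,
non-additive drug–pathway interactions and measurement batch effects, none
of which the generator emulates — synthetic recovery validates the
machinery, not biological predictive power.

## Verification workloads

The acceptance script and test suite use deliberately small problem sizes
— 100 random graphs of ≤ 8 nodes for the propagation oracle, 50 molecules
for padding invariance, 32 pairs for the overfit capacity check (500
epochs, no early stopping, dropout off), three seeds of the
20 × 30 × 50-gene recovery experiment at 60 epochs, n = 2000 for the
permuted-label AUC — chosen so the full suite runs in a few minutes on a
single core while still exercising every code path at the sizes the
properties are stated for.

## Known limitations

* No bond features, 3-D conformers or stereochemistry in the drug branch.
* Gene identifiers match exactly; no identifier-mapping service.
* Training is dense NumPy; it is sized for hundreds-to-thousands of pairs,
  not the ~10^5-pair full screening corpora (which need GPU-scale widths).
* Cross-device bit-reproducibility is not guaranteed (BLAS-dependent).
* The bio graph is shared across samples; per-sample network rewiring is
  out of scope.
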