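# Methods

This note documents the algorithms and default parameters implemented in
`ms2deep`. All defaults live on frozen dataclasses (`QCThresholds`,
`RedundancyRules`, `MergeParams`, `SimilarityParams`, `SearchParams`,
`ScanParams`, `AlignParams`, `MCODEParams`) and can be overridden per call.

## 1. MS2T feature-library construction (`ms2deep.features`)

### Quality control (`qc_filter`)

A feature passes QC when, over the injection classes recorded in its aligned
feature table:

- **reproducibility** — detected (area > 0) in ≥ 90% of reference-mixture
  injections;
- **sample:blank ratio** — mean sample area ≥ 10× mean blank area (features
  absent from blanks pass trivially);
- **RSD** — relative standard deviation of the nonzero reference areas
  ≤ 0.50;
- **area floor** — maximal area across injections ≥ 1 × 10⁵.

The filter returns the surviving features plus a per-feature report listing
every violated criterion, so failures are auditable. Upstream peak-picking
settings (minimum peak intensity, signal-to-noise) are assumed to have been
applied by the alignment software and are not re-checked.

### Redundancy removal (`remove_redundancy`)

Candidate parents are visited in descending maximal area. A feature is
removed as redundant when it co-elutes with a larger parent (|ΔRT| ≤ 0.05
min) and its m/z matches, within 5 ppm, one of:

- **isotope**: parent + k × 1.003355 (k ∈ {1, 2}), with area ≤ parent;
- **adduct**: parent + Na−H (21.981944), + K−H (37.955882), + NH₄−H
  (17.026549) in positive mode; + Cl−H (35.976678) in negative mode;
- **dimer**: 2 (parent − p) + p with p the proton mass 1.00727646;
- **in-source fragment**: a fragment m/z of the parent's MS2 spectrum.

When several parents explain a feature, the smallest ppm error wins. Each
removal records its kind, parent and ppm error.

### Cross-mode merging (`merge_modes`)

Positive and negative features are converted to neutral masses (∓ proton)
and paired greedily when within 5 ppm and 0.5 min, candidates ordered by
(ppm, |ΔRT|). Each surviving feature becomes an `MS2TEntry`; merged pairs
share a `partner_id` and are quantified in the mode with the larger maximal
area. Entries are serialized as a TSV plus a companion MSP of MS2 spectra.

## 2. Spectral-library annotation (`ms2deep.matching`)

Peaks are weighted as `w = intensity^a · mz^b`. Peak pairs across two
spectra are matched greedily by smallest m/z gap within
`max(0.01 Th, 20 ppm at the mean m/z)`, each peak used once.

- **NDP** (a = 0.5, b = 2): squared weighted cosine over the full peak
  vectors — unmatched peaks contribute to the norms, penalizing extra peaks.
- **INCOS** (a = 0.5, b = 1): squared cosine over matched pairs only,
  multiplied by the geometric mean of the matched-intensity fractions of
  both spectra, penalizing low matched coverage.

`library_search` gates references by precursor m/z (10 ppm), scores with
INCOS by default, keeps scores strictly above 0.75, and returns the top 5
ranked by score, ties broken by precursor ppm then name.
`evaluate_identification` computes top-k identification rates over labelled
query/library pairs (self-matches excluded).

## 3. In-silico branch (`ms2deep.insilico`)

Structure tables from multiple sources are merged identifier-keyed into a
single database; on conflicting fields the source priority is
kegg > biochem > knapsack, missing fields are backfilled, and every conflict
is logged. The merged table is sorted by exact mass so `retrieve_candidates`
can binary-search a 5 ppm window. Predicted spectra at several collision
energies are merged by concatenation and per-m/z (5-decimal) maximum
intensity; `insilico_search` scores queries against merged predictions with
INCOS and keeps scores strictly above 0.3.

## 4. Substructure annotation (`ms2deep.substructure`)

Tables of structural motifs (featured aglycone ions, e.g. apigenin
C₁₅H₁₀O₅ → [M+H]⁺ 271.0600999) and neutral losses (hexoside C₆H₁₀O₅,
pentoside, rhamnoside, hexuronide, sulfate, coumaroylhexoside) are computed
from molecular formulas via monoisotopic atomic masses (`ms2deep.chem`).

`scan_spectrum`:

1. detects motif ions among the 20 most intense peaks (tolerance
   `max(0.01 Th, 20 ppm)`, matching ion mode);
2. decomposes the precursor−motif mass gap into loss multisets
   (`decompose_mass`: bounded DFS, ≤ 4 modifications, per-loss multiplicity
   ≤ 3, tolerance 0.01 Da);
3. counts how many proposed losses are independently **witnessed** as
   precursor-fragment or fragment-fragment m/z differences;
4. ranks proposals by witnessed count, then |mass-balance error| (ppm),
   then fewer modifications.

Note that loss tables can contain near-degenerate masses (coumaroylhexoside
is 0.015 Da from hexuronide + pentoside); compositions whose total masses
are closer than twice the scan tolerance are inherently ambiguous.

`mine_motifs` pools fragment m/z values and all ion-pair differences across
a labelled corpus, single-linkage clusters them at 0.01 Da, and reports
clusters contributed to by at least half the spectra, using
intensity-weighted mean masses.

## 5. Association networks (`ms2deep.network`)

### Profiles

`align_profiles` assigns per-sample features to library entries within 0.35
min and 5 ppm (nearest RT, then smallest ppm). `normalize_profiles` divides
each injection by its internal-standard area, removes per-feature
instrumental drift by linear interpolation between flanking
reference-mixture injections, averages biological replicates, and
log₂-transforms with a half-minimum pseudo-count.

### Shrinkage partial correlations (`estimate_pcor`)

Columns are standardized; the sample correlation R is shrunk toward the
identity, `R* = (1−λ) R + λ I`, with the analytic variance-minimizing
intensity `λ = Σ var(r_ij) / Σ r_ij²` (clipped to [0, 1]), where the
variances are the unbiased estimates from the standardized cross-products.
Partial correlations are the negative scaled inverse of R*.

### Edge probabilities (`fit_null_and_probabilities`)

Observed partial correlations r follow the two-component mixture
`η₀ f₀(r; κ) + (1−η₀) f_A(r)` with the null density
`f₀(r; κ) ∝ (1−r²)^((κ−3)/2)`. κ is fitted by maximum likelihood of the
null truncated to the central 75% of |r|; η₀ is the central count divided
by the null mass there (capped at 1). The total density f is a Gaussian
kernel estimate floored by η₀ f₀; the local false discovery rate is
`η₀ f₀ / f` and an edge's posterior probability `1 − fdr` is made monotone
non-decreasing in |r| by a running maximum. Edges with probability strictly
above 0.99 enter the network. If shrinkage saturates (λ = 1, all partial
correlations zero), every probability is 0. A permutation-based null
(`permutation_null_probabilities`) is available as an assumption-free
alternative.

### Clustering and transfer

`mcode_cluster` weights each vertex by the highest core number of its closed
neighbourhood times that core's density, expands seeds breadth-first
(admitting neighbours with weight ≥ 0.8× the seed's), applies a haircut
(removes degree-1 members), requires a 2-core, and ranks clusters by
density × size. `transfer_annotations` gives each unannotated cluster
member the majority compound class among its annotated in-cluster
neighbours (all classes on a tie).

## 6. Synthetic fixtures (`ms2deep.simulate`)

Generators return data plus exact ground truth: a forward fragmentation
model producing ladder spectra (geometric intensity decay 0.6 per loss,
optional uniform ppm jitter); feature tables with planted QC failures,
redundant children and cross-mode twins; sparse precision matrices with
degree-capped planted partial correlations (0.30–0.45, strictly diagonally
dominant by construction, so planted magnitudes are exact); multivariate
normal profiles; class-labelled corpora with planted motif/loss
frequencies; and replicate query/library pairs with a planted recoverable
fraction. All generators are driven by a single seeded NumPy generator and
are fully deterministic per seed.
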