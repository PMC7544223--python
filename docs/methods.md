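# Methods

## The matrix model

A bitome is a sparse binary matrix **B** over a single circular or linear
replicon: rows are genomic features, columns are genomic positions
(0-based, half-open intervals throughout the library; GenBank's and the
TSV dialect's 1-based inclusive coordinates are converted at the parsing
boundary). An element is 1 exactly when the feature covers the position.
Binarity is preserved by two rules:

* **Row splitting.** A feature class whose instances can overlap in
  incompatible ways is split across rows. Gene-like features (CDS,
  pseudogene, RNA gene), codons, amino acids, proteins, per-residue
  structural tracks and COG categories get six rows per subtype — three
  frames × two strands — because neighboring genes in different frames or
  strands would otherwise collide. Positional regulatory features
  (operons, TUs, promoters, −10/−35 boxes, TSS, terminators, attenuators,
  Shine–Dalgarno sites, riboswitches) get a forward and a reverse row.
  Regulons, sigmulons, i-modulons and TFBS have no strand and stay single
  rows.
* **OR semantics.** Two same-row features overlapping a position still
  yield a single 1. Overlap multiplicities are kept out of the matrix and
  exposed as a build diagnostic (`Bitome.overlap_counts`).

The *frame* of a feature is mod-3 of its start coordinate. By default the
anchor is the leftmost genomic coordinate on both strands; an alternative
anchoring on the first *coding* base (rightmost coordinate for
reverse-strand features) is available via `BuildConfig(frame_anchor=
"coding")`. The left anchor was chosen as the default because it is the
plainest reading of "start location" and is reproducible without knowing
a feature's orientation semantics.

Derived sequence tracks are generated during assembly rather than parsed:

* **Nucleobase rows** — 8 rows (A/C/G/T × forward/reverse, the reverse row
  holding the complement). Every unambiguous position therefore carries
  exactly 2 sequence bits, which fixes the column bit-count floor at 2.
* **Codon rows** — each CDS codon yields a 3-bp record whose subtype is
  the codon read 5′→3′ on the coding strand (64 possible subtypes).
* **Amino-acid rows** — one record per non-stop residue over the same
  three positions (21 subtypes including selenocysteine). When the
  annotation carries a `translation`, it overrides naive translation; this
  is how a recoded internal UGA becomes Sec rather than a stop. Stop
  codons produce codon records but no amino-acid record, so codon coverage
  equals CDS coverage while amino-acid coverage matches protein length.
* **Protein rows** — per-gene presence over the CDS minus its stop codon,
  in six (strand, frame) variants. This treats "protein" as a gene-level
  track distinct from the residue-level amino-acid tracks; the
  interpretation is deliberate and flagged here since other conventions
  (e.g. including the stop) are defensible.

Compound (join) locations are supported as multi-interval features;
codon order follows the spliced coding order, not genomic order.
Origin-spanning intervals on circular genomes carry a `wraps` flag and an
effective length of `(L − start) + end`.

Serialization is MatrixMarket coordinate format plus a row-key TSV sidecar
and a JSON header; per-row BED export supports genome-browser inspection.

## Input handling and filters

Regulatory tables use one TSV per feature class (`id`, `left`, `right`,
`strand`, `linked_locus_tags`, plus promoter-specific TSS/box columns; set
classes carry only `id` + members). Three filters apply at parse time:
promoters with no transcription-unit link are dropped; operons/TUs linked
to no known gene are dropped; links naming unknown locus tags are warned
about and removed (genes left unlinked are reported, not deleted).
Promoters keep whatever sub-elements they have; geometry statistics use
only promoters with a TSS and both boxes. SNP tables (TSV or minimal VCF)
keep single-nucleotide substitutions only; label tables default absent
genes to 0, since essentiality-style tables list one class.

## Statistics

* **Coverage** of a row set is the fraction of columns with ≥1 bit among
  those rows (a union, not a sum). **Bit density** over a range is total
  bits divided by range length; the genome-wide density times length
  recovers the total bit count exactly.
* **Moving density** uses a 100-kb window by default with a 1-kb step (the
  window is the standard genome-scale profiling resolution; the step is a
  free resolution choice), wrapping on circular genomes; the profile
  carries mean and SD for ±2σ banding.
* **UTRs**: 5′ UTR is the strand-aware distance from the TU 5′ end to its
  first gene, 3′ UTR from the last gene to the TU 3′ end. Zero-length UTRs
  are recorded but excluded from the reported lists by default, since
  length histograms describe UTRs that exist. A 1.5×IQR filter is
  available as a view; raw lists are retained.
* **Promoter geometry**: element centers are `floor((start + end) / 2)` of
  the half-open box interval (the rounding convention for even-length
  boxes is arbitrary and fixed here); distances to the TSS are unsigned;
  the spacer is the gap between the TSS-proximal end of the −35 box and
  the TSS-distal end of the −10 box. Boxes downstream of the TSS are kept
  but flagged.
* **Inter-TU regions** are maximal intervals covered by no TU on either
  strand; by construction they tile the genome together with TU coverage.
* **Folding windows**: a pluggable engine maps each sliding window
  (default 100 bp, step configurable) to a scalar. The default engine is a
  Nussinov-style base-pair maximization (Watson–Crick + GU wobble, minimum
  hairpin loop 3) returning the negated pair count — a structure-propensity
  score, not a free energy; a thermodynamic engine can be passed as any
  `str -> float` callable. "Tight" windows are those at or below the 10%
  quantile, ties included (deterministic and conservative); with the
  discrete default score, ties can push the selected fraction well above
  10%, which is expected behavior rather than an error.

## SNP analysis

SNPs are deduplicated to unique genomic positions by default (a flag
preserves multiplicity). SNP density for a feature set is SNPs at covered
positions divided by covered positions. Per-amino-acid frequencies count
all three codon positions of each residue of that type; the baseline is
total SNPs over genome length.

The bit-count test is a two-sided Mann–Whitney U comparing column bit
counts over all coding positions (population, size n) against bit counts
at coding SNP positions (sample, size m). Because bit counts are small
integers with massive ties, the implementation switches by instance size:
exhaustive enumeration of all C(n+m, m) group assignments (exact even
under ties) when that count is ≤ 2×10⁵, otherwise the normal approximation
with the standard tie-corrected variance and continuity correction. The
asymptotic branch is cross-checked against an independent library
implementation in the tests; the exact branch against brute-force
enumeration.

## Classification workflow

Gene feature vectors collapse the gene-span sub-matrix per row by sum
(bit totals) or mean (per-bp rates; used for essentiality-style problems).
Columns are min/max-normalized, constant columns mapping to 0. A
stratified 20% lockbox is held out before any training; the remaining data
are rebalanced by downsampling the majority class (or, alternatively,
class-frequency-weighted losses). Evaluation is 5-fold stratified CV over
five downsampled resamples, reported as accuracy mean ± SD with a pooled
row-normalized confusion matrix, alongside a shuffled-label negative
control (expected accuracy 0.5 on balanced data) and a sequence-only
baseline restricted to the nucleobase rows. The final model is an
L1-regularized linear SVM (hinge loss, primal, C = 0.1); logistic
regression is available behind the same model-spec interface, and any
sklearn-compatible classifier can be plugged in. Feature importance is the
ranked nonzero |coefficient| list with signs retained. All randomness
flows from one run seed expanded into per-stage seeds that are logged in
the report. Models persist as JSON (coefficients + intercept + row keys).

A design note on lockbox handling: re-training on downsampled versions of
the *test* set would break the holdout contract, so the final model is
trained on the training set only and the lockbox is used purely for
evaluation.

## The synthetic generator

`synth.generate_annotation` lays out operons left to right: an inter-TU
gap (50–300 bp) holding the promoter and, with probability 0.5, a TFBS;
then the TU — 5′ UTR, genes, 3′ UTR — on a random strand. Defaults: 30
operons; 1 + Poisson(0.7) genes per operon; gene lengths ≈ N(900, 250) bp
rounded to codons (floor 150); UTR lengths geometric with mean 50 bp
(matching typical bacterial medians); −10/−35 box centers at 11 and 33 bp
from the TSS with ±1 bp jitter; 6-bp boxes. Genes are valid ORFs (ATG
start, in-frame stops only terminal); one gene carries a recoded internal
UGA with a selenocysteine translation so the 21st amino-acid subtype is
exercised. Regulons/sigmulons/i-modulons are random gene subsets; every
gene gets a COG letter; a tail region holds a pseudogene, RNA genes, a
repeat, an insertion element and an origin. The genome auto-sizes to the
layout (~50–60 kb at defaults), giving an emergent TU occupancy around
85–90%. Every planted quantity is written to a truth record, and tests
compare measurements to truth, never to constants.

SNP generation biases sampling odds by a configurable odds ratio (default
2) for positions below the median bit count of the candidate set, mimicking
the depletion of adaptive mutations at feature-rich positions; optional
per-amino-acid enrichment factors multiply on top. Labels come from a
logistic model over normalized gene features with configurable informative
row keys, effect sizes, intercept (auto-centered by default) and a label
noise rate.

What the generator does **not** emulate: real codon usage, GC skew,
macrodomain structure, overlapping genes, multi-TU operons, or realistic
TFBS sequence motifs. Passing tests therefore demonstrate correctness of
the accounting and statistics on feature geometry, not biological fidelity
of any particular genome; analyses of real genomes depend on the quality
and versions of the annotation resources supplied.

## Problem sizes and numerical choices

The test suite and the acceptance script run on the generator's default
~50–60 kb genome (≈ 45 genes, ≈ 590 matrix rows), with 500-draw null
calibration and 200-simulation power checks for the rank test and a
500-gene × 200-feature planted-signal dataset for the classification
checks — sizes chosen so every property is measured with comfortable
margins while the whole pipeline stays fast on a laptop. Degenerate inputs
are rejected loudly (empty intervals, zero-length genes, empty energy
vectors, classes too small to stratify); warnings cover droppable problems
(unknown link targets, non-SNP rows, CDS lengths not divisible by 3).

## Known limitations

* Single replicon only; no multi-chromosome genomes.
* The default folding engine is a combinatorial stand-in; its scores are
  not free energies and its tight-region fractions are tie-inflated.
* Structural (secondary-structure/exposure) tracks are consumed from
  per-residue TSVs, not computed.
* The classification harness reproduces the workflow, not any particular
  published accuracy: those depend on specific external database versions
  and hyperparameter-search outcomes, and the package makes no attempt to
  ship or fake that data.
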