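# Methods

## The observation-frequency model

The unit of observation is the peptide-spectrum match (PSM): one MS/MS
spectrum correlated to one peptide sequence with an engine fit score.
A protein's observation frequency in a treatment is the count of
retained PSMs carrying its gene symbol. Spectral counting of this kind
is a robust relative-abundance measure for label-free surveys, but the
two arms of a comparison are never sampled to exactly the same depth,
so raw counts are not directly comparable.

**Depth correction.** Let `T_case` and `T_control` be the total numbers
of retained correlations in the two arms of one stream. Control counts
are rescaled into the case's sampling depth,

    corrected_control = count_control · T_case / T_control.

The correction is applied multiplicatively to the control (reference)
side only; this keeps the case count an integer observation and puts
the rescaled reference in the denominator of the test statistic, which
is how the statistic's asymmetry reads most naturally. The direction is
recorded in every run's metadata.

**The screen statistic.** Each symbol is scored with

    χ² = (count_case − corrected_control)² / (corrected_control + 1).

This is the textbook one-cell statistic `(obs − exp)²/exp` with a +1
pseudocount in the denominator. The pseudocount keeps the statistic
finite for symbols never seen in the control arm and shrinks it at low
expected counts, making the screen *conservative* there: under a null
simulation with equal rates and depths the fraction of symbols reaching
χ² ≥ 25 stays well below the nominal 0.001 tail (the acceptance suite
asserts ≤ 1% per replicate; observed values are an order of magnitude
lower). As `corrected_control → ∞` the statistic converges to the
textbook form; the relative difference decays like `1/exp` (tested).

p-values are the upper tail of χ² at 1 degree of freedom and are
labeled *nominal (df=1)* in outputs, because the pseudocounted
statistic is not an exact Pearson statistic. They are floored at the
smallest positive normal double (~2.2e-308): planted enrichments of the
size the generator produces push the exact tail below double-precision
underflow, and the floor preserves the contract that p ∈ (0, 1] (which
the FDR step requires) without affecting any decision.

**Multiplicity.** Benjamini–Hochberg q-values are computed within each
stream separately (`q_(i) = min_{j≥i} p_(j)·m/j` on the sorted
p-values, clipped at 1), since the TRYP and STYP streams are analyzed
as independent experiments. The step-up is implemented directly and is
cross-checked in the tests against both an exhaustive brute-force
enumeration and `statsmodels.stats.multitest.multipletests`.

**Aggregation and selection.** Counting is per (gene symbol, protein
accession); accession rows are rolled up to one row per symbol two
ways: counts summed with χ² recomputed from the sums (so the defining
identity holds for the aggregated row — this is the `chi2` column), and
the arithmetic mean of the accession-level χ² values (`chi2_mean`, the
per-symbol averaging used in headline tables). The candidate gate —
Δ ≥ 9 corrected counts and χ² ≥ 25, both inclusive — is applied to the
averaged value; with one accession per symbol (the common case, and the
generator's case) the two coincide. The Δ gate matters: when the case
arm carries genuinely enriched symbols the depth correction inflates
the corrected control of every *null* symbol, pushing their Δ negative;
requiring a positive difference of at least 9 keeps those off the
candidate list.

## Retention rules

- **Intensity floor:** precursor intensity ≥ 10,000 arbitrary counts
  (E4), inclusive. The floor is inclusive because the retained-count
  totals that drive the correction are defined as "≥ E4" collections;
  the threshold is configurable.
- **Deduplication:** one record per spectrum id — the highest engine
  score, ties broken deterministically by lower charge, then
  lexicographically smaller peptide, then smaller accession. The
  tie-break chain is a reproducibility device, not a claim about engine
  semantics; any fixed rule serves.
- **Streams:** a PSM is STYP iff it carries at least one S/T/Y
  phosphorylation; acetylation, methionine oxidation and neutral losses
  do not change the stream. The pipeline order filter → dedup → split
  is fixed and is part of the contract (reversing filter and dedup can
  change which record of a redundant pair survives).
- **Engines:** when a table mixes X!TANDEM and SEQUEST attributions,
  counting restricts to the SEQUEST rows; cross-engine identifications
  are treated as annotation.

## Intensity analysis

Log10 precursor intensity is treated as approximately normal.
Per-treatment tables report mean, SE = sd/√n (sample sd; SE is emitted
as missing at n = 1) and N, where every retained PSM is one record —
replicate observations of one peptide in one patient are *not* pooled,
and the tables say how many records contributed.

One-way ANOVA is computed from the explicit sum-of-squares
decomposition; the two-way model is *additive* (treatment + peptide,
no interaction) fit by least squares with Type II sums of squares via
statsmodels. The additive choice is forced by estimability: treatment ×
peptide layouts from real surveys leave most cells empty, so the
interaction is not identifiable; Type II is the SS convention least
sensitive to unbalanced cell counts, and the choice is recorded in the
result object. Degenerate inputs are reported, not hidden: equal values
everywhere give F = 0, p = 1; zero residual variance with unequal means
gives F = ∞, p = 0 with a degeneracy flag.

Quantile and box-plot exports use linear interpolation between order
statistics (the numpy default), stated in the output metadata because
five-number summaries at small n are convention-sensitive.

## Sequence utilities

Tryptic digestion cleaves after K or R except before P; the proline
rule matches the default trypsin definition of the common search
engines and can be disabled. Coordinates are 1-based inclusive
throughout. Hydropathy profiles are centered sliding-window means of
the Kyte–Doolittle scale, defined where the full window fits.

The bundled DISC1-like reference (`data/disc1_synthetic.fasta`) is a
**synthetic stand-in**, not a database entry: it is constructed so the
two reported N-terminal-domain tryptic peptides sit at their published
coordinates (MPGGGPQGAPAAAGGGGVSHRAGSRDCLPPAACFR at 1–35, ARQCGLDSR at
83–91, preceded by K and fully tryptic). Tests assert the 83–91
location only; the published subscript "1–45" on the 35-residue
N-terminal peptide is internally inconsistent and is not asserted.

## Network descriptors

Descriptors are computed on user-supplied undirected simple edge lists
(self-loops rejected, duplicate edges collapsed): node count, edge
count, average degree 2E/N over the declared node set (isolated nodes
count with degree 0), and the average local clustering coefficient with
the convention that degree-<2 nodes contribute 0 — the alternative
(excluding them) changes the average, so the convention is stated in
CLI output. No interaction database is queried; service-internal
quantities (expected edge counts, enrichment p-values) are out of
scope.

## The synthetic generator

`simulate_experiment` emulates the design the analysis assumes, not any
particular dataset:

- **Arms and structure:** 12 case + 12 control patients, 10 fractions
  per patient (defaults). Patients and fractions are generated as
  metadata and pooled for frequency analysis, mirroring the pooling of
  all sample-fractions per treatment.
- **Counts:** per peptide per patient-fraction cell ~ Poisson(rate);
  baseline rate 2.0, multiplied by the enrichment ratio (default 5) for
  enriched symbols (default 20 of 200) in the case arm only. The
  Poisson choice is a modeling convenience for count data; only the
  log10-normality of intensity is asserted by the analysis itself.
- **Intensities:** 10^Normal(4.5, 0.5), truncated at E4·10⁻⁰·⁵, so a
  known ≈16% of records fall below the retention floor in both arms.
- **Streams:** each *symbol* is assigned STYP with probability
  `phospho_fraction` (default 0.3); all its PSMs then carry one phospho
  modification on a random S/T/Y of the peptide. Assignment is
  per-symbol rather than per-PSM so the truth manifest can state one
  stream, one rate pair and one enrichment flag per symbol; the
  fraction of STYP PSMs still converges to `phospho_fraction` in
  expectation. STYP symbols draw only peptides containing S/T/Y.
- **Redundancy:** with probability 0.1 a spectrum receives a second
  correlation at the other charge state with strictly lower score,
  exercising the deduplication stage; spectrum ids encode arm and
  serial so dedup behavior is auditable.
- **Sequences:** parent proteins are random sequences with residue
  frequencies tilted toward K/R and S/T/Y; peptides are drawn from
  their tryptic digests, so every generated peptide is fully tryptic
  against its parent by construction (property-tested).

Everything derives from one `numpy.random.default_rng(seed)`, so
`(config, seed)` determines every output byte.

What the generator does **not** emulate: retention-time structure,
ionization suppression and fraction-to-fraction intensity correlation,
engine score distributions (the score column is ordinal only),
peptides shared between proteins, and patient-level biological
variance beyond Poisson sampling. Passing recovery and calibration
tests therefore demonstrate correctness of the statistical machinery
under the stated design, not performance on clinical data — in real
surveys between-patient overdispersion will widen the null beyond the
Poisson tail, and shared peptides blur symbol attribution upstream of
this pipeline.

## Problem sizes and defaults

The recovery and null-calibration checks run the default design
(200 symbols, 2–4 peptides each, 12+12 patients, 10 fractions,
~380,000 PSMs per replicate; 20 replicates for calibration) — large
enough that the planted 5× enrichment yields χ² in the thousands while
the null tail stays below 1%, and small enough to run on a laptop in
about a minute per replicate group. Enrichment ratio 5 is a
test-design choice for clean separation, not an estimate of any real
effect size.

## Error handling conventions

Validation is total: malformed input rows raise with the file and line
number, never a silent drop. Tables round-trip (integers exactly, reals
to 17 significant digits, i.e. bit-exact doubles). The CLI exits 0 on
success, 2 on validation errors, 3 on I/O errors.
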