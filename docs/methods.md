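# Methods

## Quantification model

Each identified phosphopeptide species — a (sequence, phospho-position
set, charge) triple with one theoretical m/z — is quantified in every
run from its extracted ion chromatogram (XIC). Per MS1 scan within
±`rt_tol` of the peptide's reference retention time, the XIC point is
the **sum** of centroid intensities inside the relative mass window
m/z·(1 ± ppm_tol·10⁻⁶). Summing (rather than taking the apex centroid)
is robust to centroid splitting and keeps the measurement linear in
signal; the window lookup is a binary search over each scan's sorted
m/z array and is contract-tested against a linear scan. The trace is
integrated by the trapezoidal rule over retention time in minutes;
empty and single-point traces integrate to 0, since a width-less peak
has no defined area. Defaults are ppm_tol = 7, rt_tol = 2 min.

Cross-run quantification is complete by construction ("match between
runs" with zero-fill): every (peptide, run) cell is extracted, and cells
with no signal inside the windows are exactly 0. No intensity floor is
applied before integration, so zeros arise only from absent signal. The
reference RT used to anchor extraction in runs where a peptide was never
identified is the **median** of its observed identification RTs across
runs. Peptides identified at several charge states are distinct rows
(distinct m/z targets; no aggregation is attempted).

## Abundance matrix

Technical replicates of a sample are collapsed by the arithmetic mean,
with zero-filled values participating as true zeros (no exclusion rule).
Each sample column is then divided by its total intensity and rescaled
by the mean of all column totals: the ratio profile is what
normalization fixes, and the mean-total rescale keeps values on the
input's intensity scale while making all column sums equal (to 1e-10
relative). Consequently the normalized **profiles** are exactly
invariant to rescaling any single sample, while the absolute matrix
carries a global factor tied to the mean total. The stage order —
average, then normalize — is fixed in the pipeline.

## Differential statistics

Group comparisons use the classical two-sample pooled-variance Student's
t test, two-sided (not Welch; group sizes and the design's variance
assumptions are symmetric). Degenerate inputs are defined: identical
constant groups give p = 1; zero-variance groups with unequal means give
the smallest representable positive probability and a logged warning,
preserving significance ordering without dividing by zero.

Fold changes are log2((mean_B + ε)/(mean_A + ε)) with
ε = half the smallest positive value of the normalized matrix — a
deterministic, scale-aware pseudocount that keeps zero-filled peptides
finite. Classification: `sig_p01` if p < 0.01 and |log2FC| > 0.8,
`sig_p05` if 0.01 ≤ p < 0.05 at the same gate, `ns` otherwise; the
fold-change threshold is interpreted on the log2 axis and is a
parameter (`fc_threshold`). Raw P values are used deliberately — the
volcano gate combines significance with effect size, and no
multiple-testing correction is applied at this stage. Venn partitions
of the significant sets are computed separately for up- and
down-regulated peptides and combined; region counts always sum to the
union cardinality. Heatmap cells are log2 fold changes by default, with
a `linear=True` option for plain mean-fold-change display.

## Phosphosite localization confidence

A peptide with m candidate S/T/Y residues and k phosphate groups has
C(m, k) positional isoforms, enumerated in lexicographic order. The
delta score is best − second-best isoform search score; scores are
consumed from the identification table, not computed (database-search
scoring is upstream of this package). Single-isoform peptides are
unambiguous and default to delta = their own score (configurable to a
sentinel). No delta-score filter is applied by default.

## Synthetic study generator

The generator emulates the structure the analysis assumes, not an
instrument: each peptide is a single monoisotopic centroid tracing a
Gaussian elution profile whose base width is interpreted as 4σ (30 s
base → σ = 7.5 s), so the elution area has the closed form
A·σ·√(2π) used by the oracle tests. Scan times follow a fixed duty
cycle (2.1 s), giving ≥ 10 MS1 points across a 30 s peak. Sampled
variability, per (peptide, run): multiplicative log-normal noise at the
biological (per sample) then technical (per run) level; normal m/z
error in ppm and normal RT jitter in minutes, drawn once per
peptide-run so the extraction windows are genuinely exercised;
Bernoulli dropout of the whole peptide-run observation (the
"undetectable, zero-filled" case); uniform background centroids at a
configurable per-scan density. Regulated peptides carry a fixed ±
log2 fold change in the mutant genotype, signs alternating.

Defaults, chosen as the study conditions: 24 samples (2 genotypes × 3
treatments × 4 biological replicates) × 2 technical runs; 500 peptides
with 10 % regulated at |log2FC| = 2; biological CV 0.2 and technical CV
0.05 (technical variability well below biological, as in replicate
LC-MS acquisitions); dropout 0.05; m/z error SD 2 ppm (errors inside
the ±7 ppm window with probability ≈ 0.9995); RT jitter SD 0.3 min
(inside ±2 min); background 5 peaks/scan at ≤ 200 intensity, three
orders below peptide amplitudes of 10⁵–10⁷. The default gradient is 20
minutes to keep a full 48-run study at desk scale (a 120 min gradient
is available by configuration; peak shape, sampling density and all
noise processes are unaffected by the gradient length). All randomness
derives from one seed via spawned per-run substreams, and identical
seeds give bit-identical studies.

What the generator does **not** emulate — isotope and charge-state
envelopes, chimeric spectra, RT nonlinearity between runs,
intensity-dependent missingness, interference from co-eluting peptides —
bounds what passing tests show: they validate the extraction,
bookkeeping and statistics of the pipeline, not its robustness to
real-data pathologies such as alignment drift or envelope overlap.

## Numerical and design choices

- RTs are minutes everywhere; mzML readers convert from seconds at the
  boundary. mzML support is a minimal MS1-centroid reader/writer
  (uncompressed or zlib 64/32-bit arrays, standard CV accessions).
- Matrix completeness and non-negativity are enforced by the
  `QuantMatrix` container at construction.
- Ties and degenerate inputs are defined rather than accidental:
  zero-tolerance windows are valid (point windows), empty runs produce
  all-zero columns with a warning, empty mzML files are valid empty
  runs, and an all-zero sample column is a named normalization error.
- Statistical experiments that do not involve the chromatographic layer
  (null calibration at 2000 peptides) run on the generator's abundance
  level directly; the raw-signal path is exercised by the 500-peptide
  recovery experiment and the end-to-end tests.

## Known limitations

- The pooled t test on raw (not log) intensities is slightly
  conservative in the presence of dropout zeros, which inflate
  within-group variance; the null simulation keeps the empirical
  type-I rate near but sometimes just below 0.05.
- No RT alignment: cross-run extraction relies on the median-RT anchor
  staying within ±2 min, which holds for the simulated jitter but not
  necessarily for long real gradients with drift.
- Identification-level concerns (search FDR, isoform score generation)
  are consumed as inputs and not modelled beyond plausible placeholders.
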