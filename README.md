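# phospholfq

Label-free quantification (LFQ) of phosphopeptides from LC-MS survey
scans, and the differential-regulation statistics that sit on top of it.
The package is aimed at proteomics analysts who have peptide
identifications (from a database search) plus centroided MS1 spectra and
want a complete, reproducible route from raw signal to "which
phosphopeptides changed between groups" — together with a synthetic
LC-MS study generator so every stage can be validated against a known
ground truth without any raw-data downloads.

## What it computes

**XIC quantification with match-between-runs zero-fill.** For every
identified phosphopeptide *p* (target m/z, reference retention time) and
every run *r*, an extracted ion chromatogram is built by summing, in
each MS1 scan within ±2 min of the reference RT, the centroid
intensities inside a ±7 ppm window around the target m/z. The peptide's
intensity in that run is the trapezoidal area

&nbsp;&nbsp;&nbsp;&nbsp;*I(p, r) = ∫ XIC(t) dt*

Every (peptide, run) cell is computed — also in runs where the peptide
was never identified — and peptides with no detectable signal get
intensity 0, so the matrix is complete. Technical replicates are then
averaged per sample, and each sample column is normalized to total
sample intensity.

**Differential regulation.** For each comparison (e.g. mutant vs.
control within a treatment arm) and each peptide: the log2 fold change
log2((mean_B + ε) / (mean_A + ε)) with ε = half the smallest positive
matrix value, and a two-sided pooled-variance Student's *t* test. A
peptide is called regulated at the P < 0.01 (or P < 0.05) tier when it
also has |log2FC| > 0.8 — the classic volcano-plot gate. Overlaps of the
significant sets across comparisons are reported as Venn partitions;
volcano and fold-change heatmap figures are rendered from the same
tables. Phosphosite-assignment confidence is annotated as a delta score
(best minus second-best positional-isoform search score).

**Synthetic studies.** `generate_study` simulates a factorial design —
by default 2 genotypes × 3 treatments (vehicle 24 h, 4-OHT 24 h, 4-OHT
96 h) × 4 biological replicates = 24 samples, each acquired twice — with
Gaussian elution peaks (≈30 s base), a 2.1 s MS1 duty cycle, log-normal
biological/technical noise, per-run m/z and RT errors, dropout, and a
known regulated subset, returning the raw runs, the identification
table, and the ground truth.

## Worked example

```python
import phospholfq as plq
from phospholfq.design import StudyDesign, TruthParams

design = StudyDesign()                      # 2 genotypes x 3 treatments x 4 mice, 2 runs each
truth = TruthParams(n_peptides=200, frac_regulated=0.1)
runs, ids, gt = plq.generate_study(design, truth, seed=1)

matrix = plq.quantify_all(runs, plq.collapse_identifications(ids))
rep_map = dict(zip(gt.runs["run_id"], gt.runs["sample_id"]))
normalized = plq.normalize_total_intensity(
    plq.average_technical_replicates(matrix, rep_map))

for comp in plq.comparisons_from_design(design.samples()):
    res = plq.run_comparison(normalized, comp)
    ...
```

prints

```
48 runs over 24 samples; 9116 identifications of 200 phosphopeptides
quantification matrix: 200 x 48 = 9600 data points
vehicle_24h: 18 peptides at P<0.01, 2 at P<0.05 (|log2FC| > 0.8)
oht_24h: 18 peptides at P<0.01, 1 at P<0.05 (|log2FC| > 0.8)
oht_96h: 16 peptides at P<0.01, 5 at P<0.05 (|log2FC| > 0.8)
```

The 48 runs are the 24 samples × 2 technical replicates; the matrix is
complete (one area per peptide per run, zeros where the peptide was
undetectable); 20 of the 200 peptides carry a true ±2 log2-fold genotype
effect, and essentially all of them are recovered at the P < 0.01 tier
in each of the three genotype contrasts while unregulated peptides
almost never pass the gate.

The same stages are available from a shell:

```sh
phospholfq simulate --seed 1 --outdir study/
phospholfq quantify --mzml-dir study/mzml --ids study/identifications.csv \
    --runs study/runs.csv --ppm 7 --rt-tol 2 --out quant.csv
phospholfq normalize --in quant.csv --rep-map study/runs.csv --out norm.csv
phospholfq diffstats --in norm.csv --design samples.csv --outdir results/
phospholfq run --config config.yaml     # everything, with provenance
```

## Layout

| module | contents |
| --- | --- |
| `phospholfq.design` | study design and truth parameters |
| `phospholfq.simulate` | synthetic runs, identifications, ground truth |
| `phospholfq.xic` | ppm windows, XIC extraction, zero-filled matrix |
| `phospholfq.abundance` | technical-replicate averaging, normalization |
| `phospholfq.diffstats` | t tests, fold changes, volcano classes, Venn |
| `phospholfq.siteloc` | site-isoform enumeration, delta scores |
| `phospholfq.io` | mzML (MS1 centroid), CSV schemas, provenance |
| `phospholfq.pipeline`, `phospholfq.cli` | end-to-end runs, `phospholfq` command |

See `docs/methods.md` for the model, parameter and design details.
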