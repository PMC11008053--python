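# sclineage

Expressed-barcode lineage tracing of drug-tolerant cancer clones, end to end:
from raw cassette-bearing scRNA-seq reads to clone dynamics, pseudotime-resolved
expression programs, and a contrastive classifier of drug response.

## The problem

A cancer cell population under targeted therapy is rarely uniform: a small,
pre-existing subpopulation of *tolerant* clones survives selection while the
rest die, and among the survivors a few *dominant* clones expand to take over
the culture. Expressed DNA barcoding makes this visible at single-clone
resolution. Each founder cell receives a heritable 48-nt cassette —
`bc14 + TGGT + bc30`, with bc14 and bc30 drawn from fixed vocabularies
(whitelists) — transcribed into the 3'UTR of a reporter so it appears directly
in 10x-style scRNA-seq reads. Reading the cassette back per cell links every
transcriptome to its clone of origin, enabling:

- **retrospective tracing** — label untreated (day-0) cells by the eventual
  fate of their lineage and test which genes already distinguish
  tolerant from sensitive clones *before* any drug is seen;
- **prospective tracing** — follow each tolerant clone's frequency
  (cells of the clone / cells sequenced) across treatment days and call the
  dominant clones whose share increases;
- **time-course analysis** — order cells on a supervised pseudotime (an
  L1-penalized cumulative-logit regression of the sampling day on expression,
  pseudotime = w·x), smooth each gene with a rolling median (window 51), bin
  into 50 pseudotime bins, and compare dominant vs neutral profiles with a
  spline-basis F-test;
- **response prediction** — embed cells (CPM → marker panel → tf-idf) with a
  contrastive autoencoder (panel→64→32, ReLU, mirrored decoder; cosine
  embedding loss + reconstruction + latent-norm penalty) and classify the
  32-d embedding with a cosine-kernel SVM (C=100); cells whose calibrated
  probability is ≤ 0.75 are "undetermined".

Everything is exercised on a synthetic-data generator
(`sclineage.synthdata`) that emulates the experimental design with known
ground truth: Poisson(MOI) lentiviral barcoding from a 10⁷-barcode library,
selection leaving ~8% tolerant lineages with 2 dominant clones, per-day
multinomial cell sampling, negative-binomial expression with marker programs,
mitochondrial/doublet artifacts, and FASTQ with substitution errors.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
and write their tables under `results/`:

```bash
python analysis/01_simulate.py        # barcoded population + FASTQ + counts
python analysis/02_trace_barcodes.py  # lineage retrieval from reads
python analysis/03_qc.py              # cell/gene filters
python analysis/04_clone_dynamics.py  # markers + dominance calls
python analysis/05_timecourse.py      # pseudotime + spline time-course test
python analysis/06_scastral.py        # response classifier
```

Output of a full run (seeds fixed in the scripts):

```
01: infected cells: 2416 (4.8% of plated)
    lineages: 2117 founder, 174 tolerant (8%), 2 dominant
02: assigned 4000/4000 cells; 100.00% assigned the true lineage; 0 ambiguous
03: cells: 4000 -> 3667 (UMI>=5,000, mito FDR<0.1, doublet FDR<0.1)
    doublets: 96% of planted doublets flagged, 1.7% of singlets lost
04: day-0 marker panel: 49 up in tolerant, 28 up in sensitive (FDR < 0.05)
    dominance: called ['L048:000742', 'L094:000660']; planted the same two
05: dominant: Spearman(pseudotime, day) = 0.89
    spline test: 50/50 planted up-regulated driver genes found
06: selected model left-out accuracy: 0.955
    Spearman(predicted tolerant fraction, planted fraction) = 0.99
```

Reading it: transduction at MOI 0.05 infects ~5% of 50,000 cells, giving a
founder population of ~2,100 distinct lineages, of which 8% survive selection
and exactly the two planted dominant clones are called by the two-proportion
test. Barcode retrieval is error-correcting (Hamming-1 against the
whitelists), so every cell gets its true lineage back even at a 0.5% per-base
error rate. The classifier separates tolerant from sensitive day-0 cells at
95% left-out accuracy and ranks synthetic samples by their planted tolerant
fraction almost perfectly.

The same stages are scriptable on your own files through the `sclineage` CLI
(`sclineage simulate / trace / qc / clones / timecourse / scastral-*`).

## Layout

```
src/sclineage/
  synthdata.py      generator: infection, selection, expression, FASTQ
  barcode_trace.py  cassette retrieval: anchor search, correction, assignment
  qc.py             UMI / mito / doublet / gene filters
  clonedyn.py       marker testing, clone frequencies, dominance calls
  timecourse.py     ordinal pseudotime, binning, spline test, clustering
  scastral.py       contrastive autoencoder + cosine-kernel SVM, PFI, benchmark
  matrix.py         genes x cells container with MTX trio IO
  cli.py            `sclineage` command group
analysis/           numbered narrative drivers (see worked example)
tests/              pytest suite incl. the acceptance tests
docs/methods.md     models, parameters, conventions, limitations
```
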