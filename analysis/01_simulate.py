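#!/usr/bin/env python
"""Simulate the barcoded drug-selection experiment.

Generates the whole study in miniature: a 50,000-cell population transduced at
MOI 0.05 (yielding ~2,500 barcoded founder lineages), selection that keeps
~8% of lineages with two dominant clones, 4 timepoints x 1,000 sampled cells,
a 2,000-gene negative-binomial count matrix with marker programs and QC
artifacts, and cassette-bearing paired FASTQ at a 0.5% substitution rate.

Writes whitelists, FASTQ, the MTX trio and the ground-truth table under
results/data/.
"""

from pathlib import Path

from sclineage import synthdata as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # a 10,000-barcode library keeps the whitelist small enough to iterate on
    # while preserving the ~2,500-lineage founder diversity of the experiment
    pop = sd.PopulationConfig(n_cells=50_000, moi=0.05, library_size=10_000,
                              n14=100, n30=1000, seed=SEED)
    wl = sd.make_whitelist(pop.n14, pop.n30, seed=SEED)
    founder = sd.simulate_infection(pop)
    print(f"infected cells: {founder.n_infected} "
          f"({founder.n_infected / pop.n_cells:.1%} of plated)")
    print(f"distinct founder barcodes: {founder.n_distinct_barcodes()}")

    sel = sd.SelectionConfig(seed=SEED + 1)  # defaults: 8.22% tolerant, 2 dominant
    truth, cells = sd.simulate_selection(founder, sel)
    n_tol = len(truth.tolerant_lineages)
    print(f"lineages: {len(truth.lineages)} founder, {n_tol} tolerant "
          f"({n_tol / len(truth.lineages):.0%}), "
          f"{len(truth.dominant_lineages)} dominant")

    expr = sd.ExpressionConfig(seed=SEED + 2)  # 2,000 genes, artifacts on
    matrix = sd.simulate_expression(truth, expr)
    print(f"count matrix: {matrix.n_genes} genes x {matrix.n_cells} cells, "
          f"median depth {int(matrix.total_umi().mean())} UMI")

    wl.write(OUT / "bc14.txt", OUT / "bc30.txt")
    matrix.write_mtx(OUT)
    sd.write_truth(truth, OUT / "truth.tsv")
    sd.write_reads(cells, wl, truth, OUT / "R1.fastq.gz", OUT / "R2.fastq.gz",
                   error_rate=0.005, reads_per_cell=5, seed=SEED + 3)
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
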