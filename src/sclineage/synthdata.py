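"""Synthetic barcoded cell populations under drug selection.

Generates every input the pipeline consumes, with full ground truth: a founder
population created by low-MOI lentiviral barcoding (Poisson integrations drawn
from a large bc14:bc30 library), selection that leaves a minority of tolerant
lineages of which a few become dominant, per-timepoint cell sampling,
negative-binomial expression with an up-regulated marker program in tolerant
clones plus mitochondrial-fraction and doublet artifacts, and cassette-bearing
paired FASTQ with uniform substitution errors.

Default parameters mirror the experimental design the generator emulates:
50,000 plated cells transduced at MOI 0.05 from a 10-million-barcode library
(100 bc14 x 100,000 bc30), ~8% of founder lineages surviving selection, two of
them with a strong growth advantage, and sampling at days 0, 3, 6, 9.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sclineage.barcode_trace import BC14_LEN, BC30_LEN, CELL_BC_LEN, UMI_LEN, Whitelist
from sclineage.matrix import CountMatrix

# Above this size the lentiviral library is not materialized; each library slot
# maps to its bc14/bc30 pair through a counter-based hash so that memory stays
# flat while draws remain deterministic in the seed.
_LAZY_LIBRARY_THRESHOLD = 1_000_000


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Founder-population barcoding parameters."""

    n_cells: int = 50_000
    moi: float = 0.05
    library_size: int = 10_000_000
    n14: int = 100
    n30: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.moi < 0:
            raise ValueError("moi must be non-negative")
        if self.library_size > self.n14 * self.n30:
            raise ValueError("library_size exceeds n14 * n30 distinct pairs")


@dataclass
class SelectionConfig:
    """Drug-selection dynamics parameters.

    ``advantage`` is the per-interval multiplicative growth factor of dominant
    clones relative to neutral tolerant clones; sensitive lineages decay
    linearly to zero across the timepoints.
    """

    frac_tolerant: float = 0.0822
    n_dominant: int = 2
    # 4.3 per 3-day interval puts the two dominant clones at ~45% of the
    # population by day 9 (2 * 4.3^3 / (190 + 2 * 4.3^3) ~ 0.45)
    advantage: float = 4.3
    timepoints: Sequence[int] = (0, 3, 6, 9)
    cells_per_timepoint: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.frac_tolerant <= 1:
            raise ValueError("frac_tolerant must be in (0, 1]")
        if self.advantage < 1:
            raise ValueError("advantage must be >= 1")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")


@dataclass
class ExpressionConfig:
    """Negative-binomial expression model parameters.

    Baseline gene means are log-normal; dispersion is shared across genes.
    ``n_marker_up`` genes are up-regulated (by ``effect_log2fc`` log2 units) in
    tolerant cells and ``n_marker_down`` genes in sensitive cells.
    """

    n_genes: int = 2000
    n_marker_up: int = 50
    n_marker_down: int = 30
    effect_log2fc: float = 1.0
    nb_dispersion: float = 2.0
    mean_umi_per_cell: float = 10_000.0
    mito_frac_mean: float = 0.05
    mito_frac_outlier: float = 0.4
    mito_outlier_rate: float = 0.02
    doublet_rate: float = 0.05
    doublet_concentration: float = 2.0
    n_mito_genes: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("mito_frac_mean", "mito_frac_outlier", "mito_outlier_rate", "doublet_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_marker_up + self.n_marker_down + self.n_mito_genes > self.n_genes:
            raise ValueError("marker + mito gene counts exceed n_genes")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class FounderPopulation:
    """Result of the infection step: integrations per plated cell.

    ``cell_of_integration``/``pair14``/``pair30`` are parallel arrays over all
    lentiviral integrations.  A cell's reported lineage is its first
    integration; cells with more than one integration are flagged.
    """

    n_cells: int
    cell_of_integration: np.ndarray
    pair14: np.ndarray
    pair30: np.ndarray

    @property
    def n_integrations(self) -> int:
        return len(self.cell_of_integration)

    @property
    def infected_cells(self) -> np.ndarray:
        return np.unique(self.cell_of_integration)

    @property
    def n_infected(self) -> int:
        return len(self.infected_cells)

    def n_distinct_barcodes(self) -> int:
        """Distinct bc14:bc30 pairs across all integrations in the population."""
        pairs = self.pair14.astype(np.int64) * np.int64(2**32) + self.pair30
        return len(np.unique(pairs))

    def founder_table(self) -> pd.DataFrame:
        """Per infected cell: first-integration lineage and integration count."""
        order = np.argsort(self.cell_of_integration, kind="stable")
        cells = self.cell_of_integration[order]
        first = np.concatenate(([True], cells[1:] != cells[:-1]))
        counts = pd.Series(cells).value_counts().sort_index()
        return pd.DataFrame(
            {
                "cell": cells[first],
                "i14": self.pair14[order][first],
                "i30": self.pair30[order][first],
                "n_integrations": counts.to_numpy(),
                "multi_integration": counts.to_numpy() > 1,
            }
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``lineages``: per lineage id, response class (tolerant/sensitive),
    dynamics class (dominant/neutral/na) and founder cell count.
    ``frequencies``: true expected lineage frequencies, lineages x timepoints.
    ``cells``: one row per sampled cell (cell id, 16-nt barcode, lineage,
    timepoint; a ``doublet`` column is added by :func:`simulate_expression`).
    ``markers``: filled by :func:`simulate_expression` (gene, sign).
    """

    lineages: pd.DataFrame
    frequencies: pd.DataFrame
    cells: pd.DataFrame
    markers: Optional[pd.DataFrame] = None

    def validate(self) -> None:
        sums = self.frequencies.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError("per-timepoint frequencies do not sum to 1")
        missing = set(self.cells["lineage"]) - set(self.lineages.index)
        if missing:
            raise AssertionError(f"sampled lineages missing from map: {missing}")

    @property
    def tolerant_lineages(self) -> pd.Index:
        return self.lineages.index[self.lineages["response"] == "tolerant"]

    def lineage_sequences(self, wl: Whitelist) -> pd.Series:
        """Map each truth lineage id to its ``bc14seq:bc30seq`` string."""
        return pd.Series(
            [wl.lineage_id(int(r.i14), int(r.i30)) for r in self.lineages.itertuples()],
            index=self.lineages.index,
        )

    @property
    def dominant_lineages(self) -> pd.Index:
        return self.lineages.index[self.lineages["dynamics"] == "dominant"]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _random_kmers(n: int, k: int, rng: np.random.Generator,
                  forbid_anchor: bool = False) -> np.ndarray:
    """Draw ``n`` distinct random k-mers over ACGT (as an object array of str).

    With ``forbid_anchor`` words containing the TGGT anchor motif, or ending in
    its 3-nt prefix "TGG" (which would recreate the motif at the barcode-anchor
    junction), are rejected — mirroring a vendor vocabulary designed so the
    anchor occurs exactly once per cassette.
    """
    if n > 4 ** k:
        raise ValueError(f"cannot draw {n} distinct {k}-mers (only {4**k} exist)")
    seen: dict[str, None] = {}
    while len(seen) < n:
        need = n - len(seen)
        block = rng.integers(0, 4, size=(int(need * 1.1) + 8, k))
        for row in block:
            s = "".join(_ALPH[c] for c in row)
            if forbid_anchor and ("TGGT" in s or s.endswith("TGG")):
                continue
            if s not in seen:
                seen[s] = None
                if len(seen) == n:
                    break
    return np.array(list(seen.keys()), dtype=object)


_ALPH = "ACGT"


def make_whitelist(n14: int, n30: int, seed: int = 0) -> Whitelist:
    """Generate bc14/bc30 vocabularies of random distinct k-mers.

    Near-collisions (two vocabulary words at Hamming distance 1) are *not*
    excluded — real vendor whitelists have them, and downstream correction must
    reject the resulting ambiguity rather than assume it away.  Words that
    would place a second copy of the TGGT anchor upstream of the true one are
    excluded, so every clean cassette parses unambiguously.
    """
    if n14 < 1 or n30 < 1:
        raise ValueError("vocabulary sizes must be >= 1")
    rng = np.random.default_rng(seed)
    bc14 = tuple(_random_kmers(n14, BC14_LEN, rng, forbid_anchor=True))
    bc30 = tuple(_random_kmers(n30, BC30_LEN, rng, forbid_anchor=True))
    return Whitelist(bc14, bc30)


def _slots_to_pairs(slots: np.ndarray, cfg: PopulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Map library slot indices to (i14, i30) whitelist indices.

    Small libraries are materialized; huge ones use a counter-based generator
    keyed on (seed, slot), so only the drawn slots are ever expanded.
    """
    if cfg.library_size <= _LAZY_LIBRARY_THRESHOLD:
        lib_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB14)))
        lib14 = lib_rng.integers(0, cfg.n14, size=cfg.library_size)
        lib30 = lib_rng.integers(0, cfg.n30, size=cfg.library_size)
        return lib14[slots].astype(np.int64), lib30[slots].astype(np.int64)
    uniq, inverse = np.unique(slots, return_inverse=True)
    p14 = np.empty(len(uniq), dtype=np.int64)
    p30 = np.empty(len(uniq), dtype=np.int64)
    for j, slot in enumerate(uniq):
        g = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB14, int(slot))))
        p14[j] = g.integers(0, cfg.n14)
        p30[j] = g.integers(0, cfg.n30)
    return p14[inverse], p30[inverse]


def simulate_infection(cfg: PopulationConfig) -> FounderPopulation:
    """Poisson(moi) lentiviral integrations per plated cell.

    Each integration draws a barcode uniformly (with replacement) from the
    library; the library itself samples bc14:bc30 pairs uniformly, so pair
    collisions within the library are allowed, mirroring a real pooled library.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_int_per_cell = rng.poisson(cfg.moi, size=cfg.n_cells)
    cell_of_integration = np.repeat(np.arange(cfg.n_cells), n_int_per_cell)
    slots = rng.integers(0, cfg.library_size, size=len(cell_of_integration))
    pair14, pair30 = _slots_to_pairs(slots, cfg)
    return FounderPopulation(cfg.n_cells, cell_of_integration, pair14, pair30)


def _cell_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """Distinct random 16-nt droplet cell barcodes."""
    seen: dict[str, None] = {}
    while len(seen) < n:
        block = rng.integers(0, 4, size=(n - len(seen) + 4, CELL_BC_LEN))
        for row in block:
            s = "".join(_ALPH[c] for c in row)
            seen.setdefault(s, None)
            if len(seen) == n:
                break
    return list(seen.keys())


def simulate_selection(founder: FounderPopulation,
                       cfg: SelectionConfig) -> tuple[SimTruth, pd.DataFrame]:
    """Apply drug selection to the founder population and sample cells per day.

    Tolerant lineages are drawn without replacement at rate ``frac_tolerant``;
    ``n_dominant`` of them gain a multiplicative per-interval ``advantage``;
    sensitive lineages decay linearly to zero by the terminal timepoint.
    Per-timepoint samples of ``cells_per_timepoint`` cells are multinomial in
    the true frequencies.  Returns ``(truth, cells)`` where ``cells`` is the
    sampled-cell table (also stored in ``truth.cells``).
    """
    cfg.validate()
    if founder.n_integrations == 0:
        raise ValueError("founder population has no infected cells")
    if cfg.cells_per_timepoint > founder.n_cells:
        raise ValueError("cells_per_timepoint exceeds the plated population")
    rng = np.random.default_rng(cfg.seed)

    ft = founder.founder_table()
    lineage_ids = np.array(
        [f"L{i14:03d}:{i30:06d}" for i14, i30 in zip(ft["i14"], ft["i30"])], dtype=object
    )
    # founder cells sharing a barcode collapse into one lineage
    lin = pd.DataFrame({"lineage": lineage_ids, "i14": ft["i14"], "i30": ft["i30"]})
    lin = lin.groupby("lineage", sort=True).agg(
        i14=("i14", "first"), i30=("i30", "first"), founder_cells=("i14", "size")
    )
    n_lin = len(lin)
    n_tol = int(round(cfg.frac_tolerant * n_lin))
    n_tol = max(1, n_tol)
    if cfg.n_dominant > n_tol:
        raise ValueError("n_dominant exceeds the number of tolerant lineages")

    tol_idx = rng.choice(n_lin, size=n_tol, replace=False)
    dom_idx = rng.choice(tol_idx, size=cfg.n_dominant, replace=False)
    response = np.full(n_lin, "sensitive", dtype=object)
    response[tol_idx] = "tolerant"
    dynamics = np.full(n_lin, "na", dtype=object)
    dynamics[tol_idx] = "neutral"
    dynamics[dom_idx] = "dominant"
    lin["response"] = response
    lin["dynamics"] = dynamics

    base = lin["founder_cells"].to_numpy(dtype=float)
    T = len(cfg.timepoints)
    freqs = np.empty((n_lin, T))
    for i in range(T):
        w = base.copy()
        decay = 1.0 - i / (T - 1)
        w[response == "sensitive"] *= decay
        w[dynamics == "dominant"] *= cfg.advantage ** i
        freqs[:, i] = w / w.sum()
    freq_df = pd.DataFrame(freqs, index=lin.index,
                           columns=[f"d{t}" for t in cfg.timepoints])

    # sample cells
    rows = []
    for i, t in enumerate(cfg.timepoints):
        draws = rng.multinomial(cfg.cells_per_timepoint, freqs[:, i])
        lineages = np.repeat(lin.index.to_numpy(), draws)
        rng.shuffle(lineages)
        for j, lineage in enumerate(lineages):
            rows.append((f"d{t}_c{j:05d}", lineage, t))
    cells = pd.DataFrame(rows, columns=["cell", "lineage", "timepoint"])
    cells["cell_barcode"] = _cell_barcodes(len(cells), rng)
    cells = cells.set_index("cell")

    truth = SimTruth(lineages=lin, frequencies=freq_df, cells=cells)
    truth.validate()
    return truth, cells


def simulate_expression(truth: SimTruth, cfg: ExpressionConfig) -> CountMatrix:
    """Negative-binomial UMI counts for the sampled cells.

    Counts are NB(mean = size_factor * baseline * 2^(lfc * sign * indicator),
    dispersion) with log-normal baseline gene means and a shared dispersion.
    Mitochondrial genes receive the configured UMI share (outlier cells a
    higher one); doublets are sums of two random cells' count vectors and are
    flagged in ``truth.cells['doublet']``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cells = truth.cells
    n_cells = len(cells)
    n_genes = cfg.n_genes

    gene_ids = np.array(
        [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
        + [f"G{i + 1:05d}" for i in range(n_genes - cfg.n_mito_genes)],
        dtype=object,
    )
    mito = np.zeros(n_genes, dtype=bool)
    mito[: cfg.n_mito_genes] = True
    nuclear_idx = np.flatnonzero(~mito)
    up_idx = nuclear_idx[: cfg.n_marker_up]
    down_idx = nuclear_idx[cfg.n_marker_up: cfg.n_marker_up + cfg.n_marker_down]

    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    base[mito] = rng.lognormal(mean=0.0, sigma=0.3, size=cfg.n_mito_genes)
    # scale nuclear / mito blocks to the configured UMI shares
    nuc_target = cfg.mean_umi_per_cell * (1 - cfg.mito_frac_mean)
    base[~mito] *= nuc_target / base[~mito].sum()
    if cfg.n_mito_genes:
        base[mito] *= (cfg.mean_umi_per_cell * cfg.mito_frac_mean) / base[mito].sum()

    tolerant = cells["lineage"].map(truth.lineages["response"]).eq("tolerant").to_numpy()
    lfc = np.zeros((n_genes, n_cells))
    lfc[np.ix_(up_idx, tolerant)] = cfg.effect_log2fc
    lfc[np.ix_(down_idx, ~tolerant)] = cfg.effect_log2fc

    size_factor = rng.lognormal(mean=0.0, sigma=0.25, size=n_cells)
    mean = base[:, None] * (2.0 ** lfc) * size_factor[None, :]

    # mitochondrial outlier cells: boost the mito block to the outlier share
    n_outlier = rng.binomial(n_cells, cfg.mito_outlier_rate)
    outlier_cells = rng.choice(n_cells, size=n_outlier, replace=False)
    mito_outlier = np.zeros(n_cells, dtype=bool)
    if cfg.n_mito_genes and len(outlier_cells):
        boost = (cfg.mito_frac_outlier / max(cfg.mito_frac_mean, 1e-12))
        mean[np.ix_(mito, outlier_cells)] *= boost
        mito_outlier[outlier_cells] = True

    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean))

    # Doublets: the two cells' counts are summed, then the droplet's library is
    # re-captured multinomially with gene shares sharpened by
    # ``doublet_concentration`` — the capture-saturation artifact of overloaded
    # droplets, whose UMIs concentrate in the most abundant transcripts.  This
    # is the signature the downstream genes/UMI-ratio filter looks for.
    doublet = np.zeros(n_cells, dtype=bool)
    n_doub = rng.binomial(n_cells, cfg.doublet_rate)
    if n_doub:
        targets = rng.choice(n_cells, size=n_doub, replace=False)
        partners = rng.integers(0, n_cells, size=n_doub)
        summed = counts[:, targets] + counts[:, partners]
        shares = summed / np.maximum(summed.sum(axis=0, keepdims=True), 1)
        sharp = shares ** cfg.doublet_concentration
        sharp /= np.maximum(sharp.sum(axis=0, keepdims=True), 1e-300)
        for j, t in enumerate(targets):
            counts[:, t] = rng.multinomial(int(summed[:, j].sum()), sharp[:, j])
        doublet[targets] = True
    truth.cells = cells.assign(doublet=doublet, mito_outlier=mito_outlier)

    truth.markers = pd.DataFrame(
        {
            "gene": np.concatenate([gene_ids[up_idx], gene_ids[down_idx]]),
            "sign": [1] * len(up_idx) + [-1] * len(down_idx),
        }
    ).set_index("gene")

    genes = pd.DataFrame({"mito": mito}, index=pd.Index(gene_ids, name="gene"))
    cell_meta = truth.cells[
        ["timepoint", "lineage", "cell_barcode", "doublet", "mito_outlier"]
    ].copy()
    return CountMatrix(counts.astype(np.int64), genes, cell_meta)


def write_reads(cells: pd.DataFrame, wl: Whitelist, truth: SimTruth,
                r1_path: str | Path, r2_path: str | Path,
                error_rate: float = 0.0, reads_per_cell: int = 5,
                read2_length: int = 90, flank: int = 10,
                seed: int = 0) -> None:
    """Write paired cassette FASTQ(.gz) for the sampled cells.

    Read 1 is the 16-nt cell barcode followed by a random 12-nt UMI; read 2 is
    a random 5' flank, the 48-nt cassette, and a poly-A-like tail padding to
    ``read2_length``.  Substitution errors are injected i.i.d. at
    ``error_rate`` into read 2 (cassette) bases.
    """
    if read2_length < flank + 48:
        raise ValueError("read2_length too short for flank + 48-nt cassette")
    rng = np.random.default_rng(seed)

    lin = truth.lineages
    cassette_of = {
        lid: wl.cassette(int(row.i14), int(row.i30)) for lid, row in lin.iterrows()
    }

    def mutate(seq: str) -> str:
        if error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = rng.random(len(arr)) < error_rate
        for i in np.flatnonzero(hit):
            choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
            arr[i] = bytes([choices[rng.integers(0, 3)]])
        return arr.tobytes().decode()

    opener1 = gzip.open if str(r1_path).endswith(".gz") else open
    opener2 = gzip.open if str(r2_path).endswith(".gz") else open
    with opener1(str(r1_path), "wt") as f1, opener2(str(r2_path), "wt") as f2:
        rec = 0
        for cell_id, row in cells.iterrows():
            cassette = cassette_of[row["lineage"]]
            for _ in range(reads_per_cell):
                rec += 1
                umi = "".join(_ALPH[c] for c in rng.integers(0, 4, size=UMI_LEN))
                r1 = row["cell_barcode"] + umi
                left = "".join(_ALPH[c] for c in rng.integers(0, 4, size=flank))
                tail = "A" * (read2_length - flank - len(cassette))
                r2 = mutate(left + cassette + tail)
                f1.write(f"@r{rec} 1:{cell_id}\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@r{rec} 2:{cell_id}\n{r2}\n+\n{'I' * len(r2)}\n")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write the per-cell ground truth table (cell, lineage, class, timepoint)."""
    out = truth.cells.copy()
    out["response"] = out["lineage"].map(truth.lineages["response"])
    out["dynamics"] = out["lineage"].map(truth.lineages["dynamics"])
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# One-call convenience wrapper used by the analysis drivers and the CLI
# ---------------------------------------------------------------------------

def simulate_experiment(pop: PopulationConfig | None = None,
                        sel: SelectionConfig | None = None,
                        expr: ExpressionConfig | None = None,
                        ) -> tuple[Whitelist, SimTruth, CountMatrix]:
    """Run infection -> selection -> expression with the given (or default) configs."""
    pop = pop or PopulationConfig()
    sel = sel or SelectionConfig(seed=pop.seed + 1)
    expr = expr or ExpressionConfig(seed=pop.seed + 2)
    wl = make_whitelist(pop.n14, pop.n30, seed=pop.seed)
    founder = simulate_infection(pop)
    truth, _ = simulate_selection(founder, sel)
    matrix = simulate_expression(truth, expr)
    return wl, truth, matrix
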