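"""Shared fixtures: small synthetic experiments with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sclineage import synthdata as sd


@pytest.fixture(scope="session")
def small_whitelist():
    """20 bc14 x 50 bc30 vocabulary, enough for collision-free round trips."""
    return sd.make_whitelist(20, 50, seed=1)


@pytest.fixture(scope="session")
def small_experiment():
    """Founder -> selection -> expression at test scale, with artifacts off.

    ~750 infected cells, 4 timepoints x 250 cells, 400 genes with 20 up / 10
    down markers.  Doublet and mito artifacts are disabled so that tests of
    the statistical modules see clean signal; artifact-specific tests build
    their own matrices.
    """
    pop = sd.PopulationConfig(n_cells=3000, moi=0.3, library_size=1000,
                              n14=20, n30=50, seed=11)
    founder = sd.simulate_infection(pop)
    sel = sd.SelectionConfig(frac_tolerant=0.2, n_dominant=2, advantage=3.0,
                             cells_per_timepoint=250, seed=12)
    truth, cells = sd.simulate_selection(founder, sel)
    expr = sd.ExpressionConfig(n_genes=400, n_marker_up=20, n_marker_down=10,
                               mean_umi_per_cell=8000.0, doublet_rate=0.0,
                               mito_outlier_rate=0.0, seed=13)
    matrix = sd.simulate_expression(truth, expr)
    return truth, matrix


@pytest.fixture(scope="session")
def separable_counts():
    """Linearly separable two-class NB counts for the classifier tests.

    300 tolerant + 300 sensitive cells, 300 genes; the 60-gene panel contains
    30 genes at 2x in tolerant and 30 at 2x in sensitive cells.
    """
    rng = np.random.default_rng(7)
    n_genes, n_half = 300, 300
    gene_ids = pd.Index([f"G{i:04d}" for i in range(n_genes)])
    labels = np.array(["tolerant"] * n_half + ["sensitive"] * n_half)
    base = rng.lognormal(1.0, 1.0, n_genes)
    lfc = np.zeros((n_genes, 2 * n_half))
    lfc[:30, :n_half] = 1.0
    lfc[30:60, n_half:] = 1.0
    mean = base[:, None] * 2.0 ** lfc * rng.lognormal(0, 0.2, 2 * n_half)[None, :]
    counts = rng.negative_binomial(2, 2 / (2 + mean))
    panel = list(gene_ids[:60])
    return counts, gene_ids, labels, panel
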