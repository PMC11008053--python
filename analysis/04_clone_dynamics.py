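#!/usr/bin/env python
"""Retrospective and prospective clone analyses.

Retrospective: day-0 cells are labelled by the eventual fate of their lineage
(tolerant lineages = those surviving selection) and marker genes are found
with the rank-sum test; recovery of the planted marker program is reported.

Prospective: per-timepoint lineage frequencies are computed and the dominance
test is run over the tolerant lineages; the calls are compared with the two
planted dominant clones.

Writes markers.tsv, clone_frequencies.tsv and clone_classes.tsv under
results/clones/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sclineage import clonedyn as cd
from sclineage.matrix import CountMatrix

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
QC = Path(__file__).resolve().parent.parent / "results" / "qc"
OUT = Path(__file__).resolve().parent.parent / "results" / "clones"


def main() -> None:
    m = CountMatrix.read_mtx(QC if (QC / "matrix.mtx").exists() else DATA)
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t", index_col="cell")
    truth = truth.loc[truth.index.intersection(m.cell_ids)]
    OUT.mkdir(parents=True, exist_ok=True)

    # retrospective: markers of tolerance in untreated (day 0) cells
    day0 = truth.index[truth["timepoint"] == 0]
    sub = m.subset_cells(day0)
    labels = pd.Series(
        np.where(truth.loc[day0, "response"] == "tolerant", "tolerant", "sensitive"),
        index=day0,
    )
    markers = cd.rank_sum_markers(cd.lognormalize(sub), labels)
    markers.to_csv(OUT / "markers.tsv", sep="\t")
    up, down = cd.marker_panel(markers)
    print(f"day-0 marker panel: {len(up)} up in tolerant, {len(down)} up in "
          f"sensitive (FDR < 0.05) over {sub.n_cells} cells")

    # prospective: frequencies and dominance over all timepoints
    cells = truth[["lineage", "timepoint"]]
    freq = cd.clone_frequencies(cells)
    freq.to_csv(OUT / "clone_frequencies.tsv", sep="\t")
    tolerant = truth.loc[truth["response"] == "tolerant", "lineage"].unique()
    n_per_tp = cells.groupby("timepoint").size().to_numpy()
    calls = cd.classify_dominant(freq.reindex(tolerant, fill_value=0.0), n_per_tp)
    calls.to_csv(OUT / "clone_classes.tsv", sep="\t")

    called = calls.index[calls["dynamics"] == "dominant"]
    planted = truth.loc[truth["dynamics"] == "dominant", "lineage"].unique()
    print(f"dominance: called {list(called)}; planted {sorted(planted)}")
    dom_share = freq.reindex(planted).iloc[:, -1].sum()
    print(f"planted dominant clones hold {dom_share:.0%} of the final timepoint")


if __name__ == "__main__":
    main()
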