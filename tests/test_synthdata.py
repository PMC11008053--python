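"""Generator contracts: determinism, Poisson infection, selection dynamics,
negative-binomial expression and FASTQ bookkeeping."""

from __future__ import annotations

import gzip

import numpy as np
import pytest
from scipy import stats

from sclineage import synthdata as sd
from sclineage.barcode_trace import CASSETTE_LEN, trace_fastq


class TestWhitelist:
    def test_sizes_lengths_and_cassette(self):
        wl = sd.make_whitelist(100, 1000, seed=1)
        assert len(wl.bc14) == 100 and len(set(wl.bc14)) == 100
        assert len(wl.bc30) == 1000 and len(set(wl.bc30)) == 1000
        assert all(len(s) == 14 for s in wl.bc14)
        assert all(len(s) == 30 for s in wl.bc30)
        assert len(wl.cassette(0, 0)) == CASSETTE_LEN == 48

    def test_single_pair(self):
        wl = sd.make_whitelist(1, 1, seed=0)
        assert len(wl.cassette(0, 0)) == 48

    def test_deterministic_in_seed(self):
        assert sd.make_whitelist(30, 40, seed=5).bc30 == sd.make_whitelist(30, 40, seed=5).bc30
        assert sd.make_whitelist(30, 40, seed=5).bc14 != sd.make_whitelist(30, 40, seed=6).bc14

    def test_impossible_size_rejected(self):
        with pytest.raises(ValueError):
            sd._random_kmers(5, 1, np.random.default_rng(0))


class TestInfection:
    def test_zero_moi_infects_nobody(self):
        pop = sd.PopulationConfig(n_cells=500, moi=0.0, library_size=100,
                                  n14=10, n30=10, seed=0)
        assert sd.simulate_infection(pop).n_infected == 0

    def test_infected_fraction_converges_to_poisson_rate(self):
        # P(infected) = 1 - exp(-moi); checked within 3 binomial s.e.
        pop = sd.PopulationConfig(n_cells=200_000, moi=0.05, library_size=10_000,
                                  n14=100, n30=100, seed=3)
        frac = sd.simulate_infection(pop).n_infected / pop.n_cells
        expected = 1 - np.exp(-0.05)
        se = np.sqrt(expected * (1 - expected) / pop.n_cells)
        assert abs(frac - expected) < 3 * se

    def test_determinism_and_invalid_config(self):
        pop = sd.PopulationConfig(n_cells=1000, moi=0.5, library_size=100,
                                  n14=10, n30=10, seed=9)
        a, b = sd.simulate_infection(pop), sd.simulate_infection(pop)
        assert np.array_equal(a.pair30, b.pair30)
        with pytest.raises(ValueError):
            sd.simulate_infection(sd.PopulationConfig(library_size=101, n14=10, n30=10))


def _uniform_founder(n_lineages: int, n_cells: int = 50_000) -> sd.FounderPopulation:
    """One integration per infected cell, all lineages distinct."""
    return sd.FounderPopulation(
        n_cells=n_cells,
        cell_of_integration=np.arange(n_lineages),
        pair14=np.arange(n_lineages) % 20,
        pair30=np.arange(n_lineages),
    )


class TestSelection:
    def test_neutral_dynamics_keep_tolerant_frequencies_constant(self):
        founder = _uniform_founder(100)
        sel = sd.SelectionConfig(frac_tolerant=0.5, n_dominant=0, advantage=1.0,
                                 cells_per_timepoint=50, seed=1)
        truth, _ = sd.simulate_selection(founder, sel)
        tol = truth.frequencies.loc[truth.tolerant_lineages]
        # sensitive decay renormalizes everything, but tolerant stay equal to
        # each other at every timepoint, and constant once sensitives are gone
        assert np.allclose(tol.to_numpy(), tol.to_numpy()[0:1, :])

    def test_dominant_combined_frequency_strictly_increases(self):
        founder = _uniform_founder(200)
        sel = sd.SelectionConfig(frac_tolerant=0.25, n_dominant=2, advantage=3.0,
                                 cells_per_timepoint=100, seed=2)
        truth, _ = sd.simulate_selection(founder, sel)
        dom = truth.frequencies.loc[truth.dominant_lineages].sum(axis=0).to_numpy()
        assert np.all(np.diff(dom) > 0)

    def test_survival_arithmetic_192_of_2336(self):
        founder = _uniform_founder(2336)
        sel = sd.SelectionConfig(frac_tolerant=0.0822, cells_per_timepoint=100, seed=3)
        truth, _ = sd.simulate_selection(founder, sel)
        assert len(truth.tolerant_lineages) == 192

    def test_frequencies_sum_to_one_and_sampling_matches(self):
        founder = _uniform_founder(50)
        sel = sd.SelectionConfig(frac_tolerant=0.4, n_dominant=1, advantage=2.0,
                                 cells_per_timepoint=2000, seed=4)
        truth, cells = sd.simulate_selection(founder, sel)
        assert np.allclose(truth.frequencies.sum(axis=0), 1.0, atol=1e-9)
        # sampled frequencies within multinomial error of the truth
        for i, t in enumerate(sel.timepoints):
            obs = cells[cells["timepoint"] == t]["lineage"].value_counts() / 2000
            for lineage, f in truth.frequencies.iloc[:, i].items():
                se = np.sqrt(f * (1 - f) / 2000)
                assert abs(obs.get(lineage, 0.0) - f) < 4 * se + 1e-12

    def test_oversampling_rejected(self):
        founder = _uniform_founder(10, n_cells=50)
        sel = sd.SelectionConfig(frac_tolerant=0.5, cells_per_timepoint=100, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_selection(founder, sel)


@pytest.fixture(scope="module")
def truth():
    founder = _uniform_founder(40)
    sel = sd.SelectionConfig(frac_tolerant=0.5, n_dominant=1, advantage=2.0,
                             cells_per_timepoint=250, seed=5)
    return sd.simulate_selection(founder, sel)[0]


class TestExpression:

    def test_null_effect_gives_uniform_pvalues(self, truth):
        cfg = sd.ExpressionConfig(n_genes=300, n_marker_up=20, n_marker_down=0,
                                  effect_log2fc=0.0, doublet_rate=0, mito_outlier_rate=0,
                                  seed=6)
        m = sd.simulate_expression(truth, cfg)
        tol = m.cells["lineage"].map(truth.lineages["response"]).eq("tolerant").to_numpy()
        pvals = stats.mannwhitneyu(m.counts[10:, tol], m.counts[10:, ~tol],
                                   axis=1, method="asymptotic").pvalue
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_marker_mean_ratio_matches_effect(self, truth):
        cfg = sd.ExpressionConfig(n_genes=300, n_marker_up=20, n_marker_down=0,
                                  effect_log2fc=1.0, doublet_rate=0, mito_outlier_rate=0,
                                  seed=7)
        m = sd.simulate_expression(truth, cfg)
        tol = m.cells["lineage"].map(truth.lineages["response"]).eq("tolerant").to_numpy()
        up = m.gene_ids.get_indexer(truth.markers.index[truth.markers["sign"] == 1])
        ratio = m.counts[np.ix_(up, tol)].mean() / m.counts[np.ix_(up, ~tol)].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_doublet_rate_zero_flags_nothing(self, truth):
        cfg = sd.ExpressionConfig(n_genes=100, n_marker_up=5, n_marker_down=5,
                                  doublet_rate=0.0, seed=8)
        sd.simulate_expression(truth, cfg)
        assert not truth.cells["doublet"].any()

    def test_determinism(self, truth):
        cfg = sd.ExpressionConfig(n_genes=100, n_marker_up=5, n_marker_down=5, seed=9)
        a = sd.simulate_expression(truth, cfg)
        b = sd.simulate_expression(truth, cfg)
        assert np.array_equal(a.counts, b.counts)


class TestWriteReads:
    def _sample(self, n_lineages=10, n_cells=10, seed=1):
        founder = _uniform_founder(n_lineages)
        sel = sd.SelectionConfig(frac_tolerant=0.5, cells_per_timepoint=n_cells,
                                 timepoints=(0, 3), seed=seed)
        return sd.simulate_selection(founder, sel)

    def test_error_free_reads_have_exact_cassette(self, small_whitelist, tmp_path):
        truth, cells = self._sample()
        head = cells.head(10)
        sd.write_reads(head, small_whitelist, truth, tmp_path / "R1.fastq",
                       tmp_path / "R2.fastq", error_rate=0.0, reads_per_cell=5, seed=2)
        r2 = (tmp_path / "R2.fastq").read_text().splitlines()
        seqs = r2[1::4]
        assert len(seqs) == 50  # 10 cells x 5 reads, paired bookkeeping below
        r1 = (tmp_path / "R1.fastq").read_text().splitlines()
        assert len(r1) == 200
        expected = {lid: small_whitelist.cassette(int(r.i14), int(r.i30))
                    for lid, r in truth.lineages.iterrows()}
        by_cell = dict(zip(head.index, head["lineage"]))
        for title, seq in zip(r2[0::4], seqs):
            cell_id = title.split("2:")[1]
            assert seq[10:58] == expected[by_cell[cell_id]]
            assert seq[24:28] == "TGGT"

    def test_error_rate_hits_expected_cassette_fraction(self, small_whitelist, tmp_path):
        truth, cells = self._sample(n_cells=1000, seed=3)
        sd.write_reads(cells, small_whitelist, truth, tmp_path / "R1.fastq.gz",
                       tmp_path / "R2.fastq.gz", error_rate=0.01, reads_per_cell=5,
                       seed=4)
        expected_by_cell = {
            c: small_whitelist.cassette(
                int(truth.lineages.loc[l, "i14"]), int(truth.lineages.loc[l, "i30"]))
            for c, l in zip(cells.index, cells["lineage"])
        }
        with gzip.open(tmp_path / "R2.fastq.gz", "rt") as fh:
            lines = fh.read().splitlines()
        n_err = sum(
            seq[10:58] != expected_by_cell[title.split("2:")[1]]
            for title, seq in zip(lines[0::4], lines[1::4])
        )
        frac = n_err / (len(lines) // 4)
        assert frac == pytest.approx(1 - 0.99 ** 48, abs=0.03)

    def test_short_read2_rejected(self, small_whitelist, tmp_path):
        truth, cells = self._sample()
        with pytest.raises(ValueError):
            sd.write_reads(cells, small_whitelist, truth, tmp_path / "a", tmp_path / "b",
                           read2_length=40)

    def test_fastq_byte_identical_across_runs(self, small_whitelist, tmp_path):
        truth, cells = self._sample()
        for tag in ("a", "b"):
            sd.write_reads(cells, small_whitelist, truth, tmp_path / f"{tag}1.fastq",
                           tmp_path / f"{tag}2.fastq", error_rate=0.02,
                           reads_per_cell=3, seed=5)
        assert (tmp_path / "a2.fastq").read_bytes() == (tmp_path / "b2.fastq").read_bytes()

    def test_roundtrip_recovers_every_lineage(self, small_whitelist, tmp_path):
        truth, cells = self._sample(n_lineages=30, n_cells=50, seed=6)
        sd.write_reads(cells, small_whitelist, truth, tmp_path / "R1.fastq.gz",
                       tmp_path / "R2.fastq.gz", error_rate=0.0, reads_per_cell=4, seed=7)
        table, _ = trace_fastq(tmp_path / "R1.fastq.gz", tmp_path / "R2.fastq.gz",
                               small_whitelist)
        seqs = truth.lineage_sequences(small_whitelist)
        expected = cells.set_index("cell_barcode")["lineage"].map(seqs)
        assert len(table) == len(cells)
        assert (table["lineage"] == expected.reindex(table.index)).all()
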