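"""Synthetic community generators: determinism, truth tables, and the
analytic substitution-process oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pelagiq.sequences import mutate, random_dna
from pelagiq.synthetic import (CellPopulationSpec, CommunitySpec, SimGenome,
                               TaxonLineage, evolve_reference_db,
                               mutate_genome, simulate_cells, simulate_genome,
                               simulate_reads)


def hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestLineage:
    def test_labels_must_be_non_empty(self):
        with pytest.raises(ValueError):
            TaxonLineage(domain="", phylum="P", class_="C")

    def test_cluster_optional(self):
        lin = TaxonLineage(domain="Bacteria", phylum="P", class_="C")
        assert lin.cluster is None


class TestEvolveReferenceDB:
    def test_deterministic_for_fixed_seed(self):
        kwargs = dict(root_length=600, n_classes=4, per_class_divergence=0.10,
                      seqs_per_class=5, seed=7)
        a = evolve_reference_db(**kwargs)
        b = evolve_reference_db(**kwargs)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_zero_divergence_gives_identical_class_members(self):
        db = evolve_reference_db(root_length=600, n_classes=2,
                                 per_class_divergence=0.0, seqs_per_class=4,
                                 seed=1)
        for members in db.by_cluster.values():
            assert len({m.sequence for m in members}) == 1

    def test_within_class_identity_matches_substitution_process(self):
        # two leaves at w = d * factor from their ancestor agree per site
        # with probability (1-w)^2 + w^2/3; check the mean Hamming identity
        # over 50 within-class pairs against this at 3 SE.
        d, factor = 0.10, 0.2
        db = evolve_reference_db(root_length=1500, n_classes=5,
                                 per_class_divergence=d, seqs_per_class=5,
                                 seed=11, within_class_factor=factor)
        w = d * factor
        p_same = (1 - w) ** 2 + w ** 2 / 3
        idents = []
        for members in db.by_cluster.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    idents.append(hamming_identity(members[i].sequence,
                                                   members[j].sequence))
        idents = np.asarray(idents[:50])
        se = np.sqrt(p_same * (1 - p_same) / 1500) / np.sqrt(len(idents))
        assert abs(idents.mean() - p_same) < 3 * se + 1e-12

    def test_within_class_identity_exceeds_between_class(self):
        db = evolve_reference_db(root_length=800, n_classes=3,
                                 per_class_divergence=0.12, seqs_per_class=3,
                                 seed=3)
        clusters = list(db.by_cluster.values())
        within = np.mean([hamming_identity(c[0].sequence, c[1].sequence)
                          for c in clusters])
        between = np.mean([hamming_identity(a[0].sequence, b[0].sequence)
                           for a in clusters for b in clusters if a is not b])
        assert within > between

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evolve_reference_db(per_class_divergence=0.5)
        with pytest.raises(ValueError):
            evolve_reference_db(n_classes=1)


class TestSimulateReads:
    def test_single_taxon_community(self, small_db):
        spec = CommunitySpec(fractions={"Bac_CL01": 1.0}, n_reads=100, seed=5)
        reads, truth = simulate_reads(small_db, spec)
        assert len(reads) == len(truth) == 100
        assert (truth["cluster"] == "Bac_CL01").all()

    def test_error_free_reads_are_exact_substrings(self, small_db):
        spec = CommunitySpec(fractions={"Bac_CL02": 1.0}, n_reads=20,
                             error_rate=0.0, seed=5)
        reads, truth = simulate_reads(small_db, spec)
        for read, src_id in zip(reads, truth["source_id"]):
            assert read.sequence in small_db.by_id[src_id].sequence

    def test_realized_counts_binomial(self, small_db):
        frac = 0.10
        spec = CommunitySpec(
            fractions={"Bac_CL01": frac, "Bac_CL02": 1 - frac},
            n_reads=10_000, seed=17)
        _, truth = simulate_reads(small_db, spec)
        count = int((truth["cluster"] == "Bac_CL01").sum())
        se = np.sqrt(10_000 * frac * (1 - frac))
        assert abs(count - 1000) <= 3 * se

    def test_truth_table_columns_and_row_count(self, small_db):
        spec = CommunitySpec(fractions={"Bac_CL01": 0.5, "Bac_CL03": 0.5},
                             n_reads=57, seed=2)
        reads, truth = simulate_reads(small_db, spec)
        assert list(truth.columns) == ["read_id", "source_id", "domain",
                                       "phylum", "class", "cluster"]
        assert len(truth) == len(reads) == 57

    def test_unknown_cluster_label_rejected(self, small_db):
        spec = CommunitySpec(fractions={"nope": 1.0}, n_reads=10, seed=1)
        with pytest.raises(KeyError):
            simulate_reads(small_db, spec)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CommunitySpec(fractions={"a": 0.5, "b": 0.4}, n_reads=10)

    def test_deterministic_per_seed(self, small_db):
        spec = CommunitySpec(fractions={"Bac_CL01": 1.0}, n_reads=30, seed=9)
        r1, t1 = simulate_reads(small_db, spec)
        r2, t2 = simulate_reads(small_db, spec)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        pd.testing.assert_frame_equal(t1, t2)


class TestMutateGenome:
    def test_zero_divergence_identity(self):
        g = simulate_genome(5000, seed=1)
        assert mutate_genome(g, 0.0, seed=2).sequence == g.sequence

    def test_length_and_intervals_preserved(self):
        g = simulate_genome(10_000, seed=1, rrna_intervals=[(100, 1600)])
        g.gene_intervals = [(2000, 2900, "PhX")]
        mut = mutate_genome(g, 0.05, seed=3)
        assert len(mut.sequence) == len(g.sequence)
        assert mut.rrna_intervals == g.rrna_intervals
        assert mut.gene_intervals == g.gene_intervals

    def test_realized_substitution_fraction_binomial(self):
        d, L = 0.03, 100_000
        g = simulate_genome(L, seed=4)
        mut = mutate_genome(g, d, seed=5)
        frac = mut.n_substitutions / L
        assert abs(frac - d) <= 3 * np.sqrt(d * (1 - d) / L)
        observed = sum(a != b for a, b in zip(g.sequence, mut.sequence))
        assert observed == mut.n_substitutions

    def test_deterministic_per_seed(self):
        g = simulate_genome(3000, seed=1)
        assert (mutate_genome(g, 0.1, seed=7).sequence
                == mutate_genome(g, 0.1, seed=7).sequence)

    def test_interval_bounds_validated(self):
        with pytest.raises(ValueError):
            SimGenome(id="g", sequence="ACGT" * 10, rrna_intervals=[(30, 50)])
        with pytest.raises(ValueError):
            SimGenome(id="g", sequence="ACGT" * 100,
                      rrna_intervals=[(0, 50), (40, 90)])


class TestSimulateCells:
    def test_degenerate_sphere_population(self):
        pop = CellPopulationSpec(label="x", shape="sphere", n_cells=10,
                                 length_dist=("fixed", {"value": 1.0}))
        cells = simulate_cells([pop])
        assert (cells["length_um"] == 1.0).all()
        assert (cells["width_um"] == 1.0).all()

    def test_total_row_count(self):
        pops = [
            CellPopulationSpec(label="a", shape="rod", n_cells=100,
                               length_dist=("normal", {"mean": 1.0, "sd": 0.1}),
                               width_dist=("normal", {"mean": 0.3, "sd": 0.02}),
                               seed=1),
            CellPopulationSpec(label="b", shape="sphere", n_cells=900,
                               length_dist=("fixed", {"value": 0.4}), seed=2),
        ]
        cells = simulate_cells(pops)
        assert len(cells) == 1000
        assert cells["population"].value_counts().to_dict() == {"b": 900, "a": 100}

    def test_rod_length_mean_recovered(self):
        mean, sd, n = 0.92, 0.2, 277
        pop = CellPopulationSpec(label="cl", shape="rod", n_cells=n,
                                 length_dist=("normal", {"mean": mean, "sd": sd}),
                                 width_dist=("fixed", {"value": 0.28}), seed=3)
        cells = simulate_cells([pop])
        # CLT: sample mean within 3 SE (resampling of width>length pairs
        # trims almost nothing at these parameters)
        assert abs(cells["length_um"].mean() - mean) < 3 * sd / np.sqrt(n)

    def test_rod_width_never_exceeds_length(self):
        pop = CellPopulationSpec(label="r", shape="rod", n_cells=500,
                                 length_dist=("normal", {"mean": 0.5, "sd": 0.2}),
                                 width_dist=("normal", {"mean": 0.4, "sd": 0.2}),
                                 seed=4)
        cells = simulate_cells([pop])
        assert (cells["width_um"] <= cells["length_um"]).all()
        assert (cells["width_um"] > 0).all()

    def test_impossible_distribution_errors(self):
        pop = CellPopulationSpec(label="bad", shape="sphere", n_cells=5,
                                 length_dist=("fixed", {"value": -1.0}))
        with pytest.raises(ValueError):
            simulate_cells([pop])
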