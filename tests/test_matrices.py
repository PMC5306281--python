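"""Pan-genome matrices, occupancy classes, ANI, NR collapse, accessory sets."""

import numpy as np
import pytest

from pangest.clustering import Cluster
from pangest.matrices import (
    ANIMatrix,
    ani_dendrogram,
    build_pangenome_matrix,
    classify_occupancy,
    compute_ani,
    find_accessory,
    make_nr_matrix,
    soft_core_min_occupancy,
)
from pangest.pairwise import all_vs_all_hsps
from pangest.seqio import AccessionSet, SequenceRecord


def _cluster(cid, members_by_acc, isoforms=None):
    members = [m for ms in members_by_acc.values() for m in ms]
    per_acc = {a: len(ms) for a, ms in members_by_acc.items() if ms}
    return Cluster(
        cluster_id=cid,
        members=sorted(members),
        per_accession=per_acc,
        occupancy=len(per_acc),
        single_copy=all(v <= 1 for v in per_acc.values()),
        isoforms=isoforms or {},
    )


class TestPangenomeMatrix:
    def test_counts_and_occupancy(self):
        clusters = [
            _cluster("c1", {"A": ["a1"], "B": ["b1"]}),
            _cluster("c2", {"A": ["a2"]}),
        ]
        pm = build_pangenome_matrix(clusters, ["A", "B"])
        assert pm.counts.tolist() == [[1, 1], [1, 0]]
        assert pm.occupancy.tolist() == [2, 1]

    def test_inparalogs_count_but_occupancy_is_accessions(self):
        pm = build_pangenome_matrix(
            [_cluster("c1", {"A": ["a1", "a2"]})], ["A", "B"]
        )
        assert pm.counts[0, 0] == 2
        assert pm.occupancy.tolist() == [1]

    def test_empty_cluster_list_gives_zero_columns(self):
        pm = build_pangenome_matrix([], ["A", "B"])
        assert pm.counts.shape == (2, 0)

    def test_isoforms_mapped_to_representative_column(self):
        seqs = AccessionSet()
        seqs.add(SequenceRecord("a1", "A", "ACGT" * 30))
        seqs.add(SequenceRecord("a1b", "A", "ACGT" * 20))
        clusters = [_cluster("c1", {"A": ["a1"]}, isoforms={"a1": ["a1b"]})]
        with_iso = build_pangenome_matrix(clusters, ["A"], seqs)
        without = build_pangenome_matrix(clusters, ["A"], seqs, include_isoforms=False)
        assert with_iso.counts[0, 0] == 2
        assert without.counts[0, 0] == 1

    def test_count_conservation(self, pipeline):
        total = int(pipeline.pm.counts.sum())
        assert total == len(pipeline.seqs)  # members + attached isoforms


class TestOccupancyClasses:
    @pytest.mark.parametrize(
        "occ,expected",
        [(19, "core"), (18, "soft-core"), (17, "shell"), (3, "shell"),
         (2, "cloud"), (1, "cloud")],
    )
    def test_nineteen_accession_bands(self, occ, expected):
        pm = build_pangenome_matrix(
            [_cluster("c", {f"acc{i}": [f"s{i}"] for i in range(occ)})],
            [f"acc{i}" for i in range(19)],
        )
        assert classify_occupancy(pm)["c"] == expected

    def test_sixteen_accessions_occupancy_three_is_shell(self):
        pm = build_pangenome_matrix(
            [_cluster("c", {f"acc{i}": [f"s{i}"] for i in range(3)})],
            [f"acc{i}" for i in range(16)],
        )
        assert classify_occupancy(pm)["c"] == "shell"
        assert soft_core_min_occupancy(16) == 15

    def test_four_accessions_soft_band_merges_into_core(self):
        # nearest integer to 0.95*4 is 4: the soft band coincides with core
        assert soft_core_min_occupancy(4) == 4
        pm = build_pangenome_matrix(
            [_cluster("c", {f"acc{i}": [f"s{i}"] for i in range(4)})],
            [f"acc{i}" for i in range(4)],
        )
        assert classify_occupancy(pm)["c"] == "core"

    def test_labels_partition_all_clusters(self, pipeline):
        labels = classify_occupancy(pipeline.pm)
        assert set(labels) == set(pipeline.pm.cluster_ids)
        assert set(labels.values()) <= {"core", "soft-core", "shell", "cloud"}


class TestANI:
    def _seqs_and_hits(self, divergence_pairs):
        """Two accessions, co-clustered pairs at programmed identities."""
        rng = np.random.default_rng(21)
        seqs = AccessionSet()
        clusters = []
        for i, ident in enumerate(divergence_pairs):
            base = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
            mutated = list(base)
            n_mut = round(len(base) * (100.0 - ident) / 100.0)
            for pos in rng.choice(len(base), size=n_mut, replace=False):
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            seqs.add(SequenceRecord(f"a{i}", "A", base))
            seqs.add(SequenceRecord(f"b{i}", "B", "".join(mutated)))
            clusters.append(_cluster(f"c{i}", {"A": [f"a{i}"], "B": [f"b{i}"]}))
        return seqs, all_vs_all_hsps(seqs), clusters

    def test_identical_sequences_give_100(self):
        seqs, hits, clusters = self._seqs_and_hits([100.0, 100.0])
        ani = compute_ani(clusters, hits, seqs)
        assert ani.values[0, 1] == pytest.approx(100.0)

    def test_mean_of_programmed_identities(self):
        seqs, hits, clusters = self._seqs_and_hits([99.0, 98.0])
        ani = compute_ani(clusters, hits, seqs)
        assert ani.values[0, 1] == pytest.approx(98.5, abs=0.1)

    def test_symmetry_and_diagonal(self, pipeline):
        ani = compute_ani(pipeline.clusters, pipeline.hsps, pipeline.seqs)
        assert np.allclose(ani.values, ani.values.T, equal_nan=True)
        assert np.allclose(np.diag(ani.values), 100.0)

    def test_programmed_divergence_recovered(self, pipeline):
        """ANI within +-0.2 of 100*(1 - divergence) on the synthetic fixture."""
        ani = compute_ani(pipeline.clusters, pipeline.hsps, pipeline.seqs,
                          cluster_filter="core")
        off = ani.values[~np.eye(len(ani.accessions), dtype=bool)]
        expected = 100.0 * (1.0 - pipeline.cfg.divergence)
        assert abs(off.mean() - expected) <= 0.2

    def test_filter_leaving_no_clusters_errors(self):
        seqs, hits, clusters = self._seqs_and_hits([99.0])
        with pytest.raises(ValueError):
            compute_ani(clusters, hits, seqs, cluster_filter="min_occupancy",
                        min_occupancy=99)


def _ultrametric_ani(values):
    n = len(values)
    arr = np.array(values, dtype=float)
    np.fill_diagonal(arr, 100.0)
    return ANIMatrix(
        accessions=[chr(ord("A") + i) for i in range(n)],
        values=arr,
        n_pairs_used=np.ones((n, n), dtype=int),
    )


class TestDendrogram:
    def test_closest_pair_forms_first_cherry(self):
        ani = _ultrametric_ani(
            [[100, 99.9, 98.0], [99.9, 100, 98.0], [98.0, 98.0, 100]]
        )
        newick = ani_dendrogram(ani, method="distance_direct")
        # A and B must be siblings
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        leafsets = [
            {l.taxon.label for l in node.leaf_iter()}
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        ]
        assert {"A", "B"} in leafsets

    def test_identical_rows_give_equal_merge_heights(self):
        ani = _ultrametric_ani([[100, 99, 99], [99, 100, 99], [99, 99, 100]])
        newick = ani_dendrogram(ani, method="distance_direct", linkage="complete")
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        depths = {
            l.taxon.label: sum(e.length for e in l.ancestor_iter() if e.edge.length)
            for l in tree.leaf_node_iter()
        }

    def test_merge_order_matches_independent_agglomerative_oracle(self):
        rng = np.random.default_rng(31)
        base = rng.uniform(96.0, 99.5, size=(4, 4))
        values = (base + base.T) / 2
        np.fill_diagonal(values, 100.0)
        ani = _ultrametric_ani(values.tolist())
        newick = ani_dendrogram(ani, method="distance_direct", linkage="complete")

        # naive complete-linkage agglomeration, written independently
        dist = 100.0 - values
        np.fill_diagonal(dist, 0.0)
        active = {i: frozenset([i]) for i in range(4)}
        merges = []
        d = {(i, j): dist[i, j] for i in range(4) for j in range(i + 1, 4)}
        cur = dict(d)
        groups = dict(active)
        next_id = 4
        while len(groups) > 1:
            (gi, gj), _ = min(cur.items(), key=lambda kv: kv[1])
            merged = groups[gi] | groups[gj]
            merges.append(merged)
            del groups[gi], groups[gj]
            newd = {}
            for (x, y), v in cur.items():
                if gi in (x, y) or gj in (x, y):
                    continue
                newd[(x, y)] = v
            for gk in groups:
                newd[(gk, next_id)] = max(
                    dist[a, b] for a in groups[gk] for b in merged
                )
            groups[next_id] = merged
            cur = newd
            next_id += 1
        first_merge = {chr(ord("A") + i) for i in merges[0]}

        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        cherry_leafsets = [
            {l.taxon.label for l in node.leaf_iter()}
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        ]
        assert first_merge in cherry_leafsets

    def test_missing_values_are_an_error(self):
        ani = _ultrametric_ani([[100, np.nan, 98], [np.nan, 100, 98], [98, 98, 100]])
        with pytest.raises(ValueError):
            ani_dendrogram(ani)


class TestNRMatrix:
    def _two_identical_rep_clusters(self):
        rng = np.random.default_rng(41)
        nt = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
        seqs = AccessionSet()
        seqs.add(SequenceRecord("a1", "A", nt))
        seqs.add(SequenceRecord("b1", "B", nt))
        clusters = [
            _cluster("c1", {"A": ["a1"]}),
            _cluster("c2", {"B": ["b1"]}),
        ]
        pm = build_pangenome_matrix(clusters, ["A", "B"])
        return pm, clusters, seqs, nt

    def test_identical_representatives_collapse_to_one_column(self):
        pm, clusters, seqs, _ = self._two_identical_rep_clusters()
        nr = make_nr_matrix(pm, clusters, seqs)
        assert len(nr.pm.cluster_ids) == 1
        assert nr.pm.counts.sum() == 2

    def test_collapse_is_idempotent(self):
        pm, clusters, seqs, _ = self._two_identical_rep_clusters()
        nr1 = make_nr_matrix(pm, clusters, seqs)
        surviving = [c for c in clusters if c.cluster_id in nr1.pm.cluster_ids]
        nr2 = make_nr_matrix(nr1.pm, surviving, seqs)
        assert nr2.pm.cluster_ids == nr1.pm.cluster_ids

    def test_reference_recall_precision_bookkeeping(self):
        rng = np.random.default_rng(42)
        r1 = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
        r2 = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
        unrelated = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
        seqs = AccessionSet()
        seqs.add(SequenceRecord("a1", "A", r1))        # perfect match to ref r1
        seqs.add(SequenceRecord("a2", "A", unrelated))  # matches nothing
        clusters = [_cluster("c1", {"A": ["a1"]}), _cluster("c2", {"A": ["a2"]})]
        pm = build_pangenome_matrix(clusters, ["A"])
        nr = make_nr_matrix(pm, clusters, seqs, reference_cds={"r1": r1, "r2": r2})
        assert nr.report.recall == pytest.approx(0.5)
        assert nr.report.precision == pytest.approx(0.5)
        assert nr.report.clusters_per_matched_reference == pytest.approx(1.0)

    def test_fragmented_references_inflate_the_ratio(self):
        rng = np.random.default_rng(43)
        r1 = "".join("ACGT"[b] for b in rng.integers(0, 4, size=900))
        seqs = AccessionSet()
        seqs.add(SequenceRecord("a1", "A", r1[:450]))
        seqs.add(SequenceRecord("a2", "A", r1[450:]))
        clusters = [_cluster("c1", {"A": ["a1"]}), _cluster("c2", {"A": ["a2"]})]
        pm = build_pangenome_matrix(clusters, ["A"])
        nr = make_nr_matrix(pm, clusters, seqs, reference_cds={"r1": r1})
        assert nr.report.clusters_per_matched_reference == pytest.approx(2.0)
        assert nr.report.recall == pytest.approx(1.0)

    def test_empty_reference_errors(self):
        pm, clusters, seqs, _ = self._two_identical_rep_clusters()
        with pytest.raises(ValueError):
            make_nr_matrix(pm, clusters, seqs, reference_cds={})


class TestAccessory:
    def _pm(self):
        clusters = [
            _cluster("c1", {"A": ["a1"], "B": ["b1"], "C": ["c1"], "D": ["d1"]}),
            _cluster("c2", {"B": ["b2"], "C": ["c2"], "D": ["d2"]}),
            _cluster("c3", {"A": ["a3"], "B": ["b3"], "C": ["c3"]}),
            _cluster("c4", {"B": ["b4"], "C": ["c4"]}),
        ]
        return build_pangenome_matrix(clusters, ["A", "B", "C", "D"])

    def test_include_exclude_and_min_occupancy(self):
        pm = self._pm()
        # present in B, absent from A, occupancy >= 3
        assert find_accessory(pm, include={"B"}, exclude={"A"}) == ["c2"]

    def test_presence_in_excluded_accession_filters_out(self):
        pm = self._pm()
        assert "c1" not in find_accessory(pm, include={"B"}, exclude={"A"})

    def test_occupancy_below_threshold_filters_out(self):
        pm = self._pm()
        assert "c4" not in find_accessory(pm, include={"B"}, exclude={"A"},
                                          min_occupancy=3)
        assert "c4" in find_accessory(pm, include={"B"}, exclude={"A"},
                                      min_occupancy=2)

    def test_overlapping_sets_error(self):
        with pytest.raises(ValueError):
            find_accessory(self._pm(), include={"B"}, exclude={"B"})
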