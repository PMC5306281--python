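"""NG86 dN/dS, codon alignments, notched box stats, tree distances."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from pangest.evolution import (
    _pathway_counts,
    _syn_fraction,
    align_codons,
    box_stats,
    cluster_omega,
    notches_overlap,
    pairwise_ng86,
    prune_to_common,
    stratify_by_occupancy,
    tree_distance,
)
from pangest.seqio import SequenceRecord
from pangest.synth import mutate_sequence

CODE = {}
from Bio.Data.CodonTable import standard_dna_table as _tab

CODE.update(_tab.forward_table)
for c in _tab.stop_codons:
    CODE[c] = "*"
BASES = "ACGT"
SENSE_CODONS = [c for c in ("".join(p) for p in itertools.product(BASES, repeat=3))
                if CODE[c] != "*"]


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNG86:
    def test_identical_rows_have_zero_distances_and_undefined_omega(self):
        row = "ATGGCTAAACCC"
        est = pairwise_ng86(row, row)
        assert est.dN == 0.0 and est.dS == 0.0
        assert est.omega is None

    def test_single_synonymous_change_gives_omega_zero(self):
        codons = ["GGT"] + ["ATG", "CAT", "TGG", "AAA"] * 24  # 97 codons
        a = "".join(codons)
        b = "GGC" + a[3:]  # GGT -> GGC, synonymous
        est = pairwise_ng86(a, b)
        assert est.dN == 0.0
        assert est.dS > 0.0
        assert est.omega == 0.0

    def test_single_nonsynonymous_change_gives_ds_zero(self):
        a = "".join(["ATG", "CAT", "TGG", "AAA"] * 25)
        b = "CTG" + a[3:]  # ATG -> CTG, M -> L
        est = pairwise_ng86(a, b)
        assert est.dS == 0.0 and est.dN > 0.0
        assert est.omega is None

    def test_site_counts_sum_to_three_per_codon_for_random_pairs(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            a = "".join(rng.choice(SENSE_CODONS, size=n))
            b = "".join(rng.choice(SENSE_CODONS, size=n))
            est = pairwise_ng86(a, b)
            assert est.s_sites + est.n_sites == pytest.approx(3 * est.n_codons_used)

    def test_omega_symmetric_under_row_swap(self):
        rng = np.random.default_rng(62)
        a = "".join(rng.choice(SENSE_CODONS, size=80))
        b = mutate_sequence(a, 0.03, mode="any", seed=1)
        e1, e2 = pairwise_ng86(a, b), pairwise_ng86(b, a)
        assert e1.dN == pytest.approx(e2.dN)
        assert e1.dS == pytest.approx(e2.dS)

    def test_gap_and_n_codons_skipped_pairwise(self):
        a = "ATG---GCTAAA"
        b = "ATGCCCGCTANA"
        est = pairwise_ng86(a, b)
        assert est.n_codons_used == 2  # ATG and GCT only

    def test_pathway_counts_match_exhaustive_enumeration(self):
        """Oracle: enumerate mutation orders independently for every
        two-difference sense-codon pair."""

        def oracle(ca, cb):
            diffs = [i for i in range(3) if ca[i] != cb[i]]
            paths = []
            for order in itertools.permutations(diffs):
                cur = ca
                steps = []
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if CODE[nxt] == "*":
                        blocked = True
                        break
                    steps.append((cur, nxt))
                    cur = nxt
                if not blocked:
                    paths.append(steps)
            if not paths:
                return None
            syn = np.mean([
                sum(1 for c1, c2 in p if CODE[c1] == CODE[c2]) for p in paths
            ])
            return syn, len(diffs) - syn

        rng = np.random.default_rng(63)
        checked = 0
        for ca in rng.choice(SENSE_CODONS, size=40):
            for cb in rng.choice(SENSE_CODONS, size=10):
                diffs = sum(1 for i in range(3) if ca[i] != cb[i])
                if diffs != 2:
                    continue
                expected = oracle(ca, cb)
                if expected is None:
                    continue
                syn, nonsyn = _pathway_counts(ca, cb)
                assert syn == pytest.approx(expected[0]), (ca, cb)
                assert nonsyn == pytest.approx(expected[1]), (ca, cb)
                checked += 1
        assert checked > 30

    def test_site_fractions_match_independent_count(self):
        """Oracle: recount synonymous changes straight from the genetic code."""
        for codon in ("GGG", "ATG", "TGG", "CTA", "AAA", "TCG"):
            syn = 0
            for pos, base in itertools.product(range(3), BASES):
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if CODE[alt] == CODE[codon] and CODE[alt] != "*":
                    syn += 1
            assert _syn_fraction(codon) == pytest.approx(syn / 3.0)

    def test_synonymous_only_mutations_give_cluster_omega_zero(self):
        rng = np.random.default_rng(64)
        base = "ATG" + "".join(rng.choice(SENSE_CODONS, size=100)) + "TAA"
        recs = [SequenceRecord(f"s{i}", f"acc{i}",
                               mutate_sequence(base, 0.05, "synonymous_only", seed=i))
                for i in range(4)]
        aln = align_codons(recs)
        summary = cluster_omega(aln)
        assert summary.mean_omega == pytest.approx(0.0, abs=1e-12)
        assert summary.classification == "purifying"

    def test_nonsynonymous_only_never_returns_infinite_omega(self):
        a = "".join(["ATG", "CAT", "TGG", "AAA"] * 25)
        b = "CTG" + a[3:]
        recs = [SequenceRecord("x", "A", a + "TAA"), SequenceRecord("y", "B", b + "TAA")]
        aln = align_codons(recs)
        summary = cluster_omega(aln)
        assert summary.mean_omega is None
        assert summary.classification is None


class TestClusterOmega:
    def test_mean_exceeding_threshold_is_excluded(self):
        rng = np.random.default_rng(65)
        base = "ATG" + "".join(rng.choice(SENSE_CODONS, size=120)) + "TAA"
        recs = [
            SequenceRecord(f"s{i}", f"acc{i}",
                           mutate_sequence(base, 0.08, "nonsynonymous_biased", seed=i))
            for i in range(4)
        ]
        aln = align_codons(recs)
        summary = cluster_omega(aln, max_omega=0.05)
        assert summary.excluded

    def test_mean_equals_hand_computed_pairwise_mean(self):
        rng = np.random.default_rng(66)
        base = "ATG" + "".join(rng.choice(SENSE_CODONS, size=120)) + "TAA"
        recs = [SequenceRecord(f"s{i}", f"acc{i}",
                               mutate_sequence(base, 0.03, "any", seed=10 + i))
                for i in range(4)]
        aln = align_codons(recs)
        summary = cluster_omega(aln)
        manual = []
        for i in range(4):
            for j in range(i + 1, 4):
                est = pairwise_ng86(aln.rows[i], aln.rows[j])
                if est.usable and est.omega is not None:
                    manual.append(est.omega)
        assert summary.mean_omega == pytest.approx(float(np.mean(manual)))
        assert summary.n_pairs == 6


class TestAlignCodons:
    def test_identical_pair_aligns_gapless(self):
        nt = "ATGGCTGCAACCTAA"
        recs = [SequenceRecord("a", "A", nt), SequenceRecord("b", "B", nt)]
        aln = align_codons(recs)
        assert aln.rows[0] == aln.rows[1]
        assert "-" not in aln.rows[0]

    def test_codon_insertion_becomes_one_gap_codon(self):
        a = "ATG" + "GCTGCAACCTGGCATAAAGAA" * 3 + "TAA"
        b = a[:24] + "AAA" + a[24:]  # one extra codon
        aln = align_codons([SequenceRecord("a", "A", a), SequenceRecord("b", "B", b)])
        row_a = aln.rows[aln.seq_ids.index("a")]
        assert row_a.count("-") == 3
        # rows cover the coding part; the terminal stop codon is not aligned
        assert row_a.replace("-", "") == a[:-3]

    def test_gaps_verified_against_exhaustive_global_alignment(self):
        from Bio import Align

        a = "ATG" + "GCTGCAACCTGGCATAAAGAA" * 3 + "TAA"
        b = a[:24] + "AAA" + a[24:]
        from Bio.Seq import Seq

        pa, pb = str(Seq(a).translate())[:-1], str(Seq(b).translate())[:-1]
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        ref = aligner.align(pb, pa)[0]
        gap_col = str(ref[1]).index("-")
        aln = align_codons([SequenceRecord("a", "A", a), SequenceRecord("b", "B", b)])
        row_a = aln.rows[aln.seq_ids.index("a")]
        assert row_a[3 * gap_col: 3 * gap_col + 3] == "---"

    def test_member_with_internal_stop_is_excluded(self):
        good = "ATGGCTGCAACCTAA"
        bad = "ATGTAAGCAACCTAA"
        with pytest.warns(UserWarning, match="internal stop"):
            aln = align_codons(
                [
                    SequenceRecord("g1", "A", good),
                    SequenceRecord("g2", "B", good),
                    SequenceRecord("b1", "C", bad),
                ]
            )
        assert aln.excluded == ["b1"]
        assert set(aln.seq_ids) == {"g1", "g2"}

    def test_too_few_usable_members_errors(self):
        with pytest.raises(ValueError):
            align_codons([SequenceRecord("a", "A", "ATGGCTTAA")])


# ---------------------------------------------------------------------------
# box statistics
# ---------------------------------------------------------------------------

class TestBoxStats:
    def test_notch_formula(self):
        # n=100, iqr=4, median=10 -> notch 10 +- 1.58*4/10 = 0.632
        stats = box_stats([10.0] * 100)
        stats.q1, stats.q3 = 8.0, 12.0
        assert stats.notch_half_width == pytest.approx(0.632)
        assert stats.notch_low == pytest.approx(9.368)
        assert stats.notch_high == pytest.approx(10.632)

    def test_single_value_notch_degenerates_wide(self):
        stats = box_stats([5.0])
        stats.q1, stats.q3 = 4.0, 6.0
        assert stats.notch_half_width == pytest.approx(1.58 * 2.0)

    def test_programmed_separation_gives_non_overlapping_notches(self):
        rng = np.random.default_rng(67)
        low = rng.normal(0.2, 0.05, size=200)
        high = rng.normal(0.5, 0.05, size=200)
        values = {f"l{i}": float(v) for i, v in enumerate(low)}
        values.update({f"h{i}": float(v) for i, v in enumerate(high)})
        occ = {k: (4 if k.startswith("l") else 9) for k in values}
        strata = stratify_by_occupancy(values, occ)
        assert not notches_overlap(strata[4], strata[9])
        assert strata[4].median < strata[9].median


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def _random_tree(rng, leaves):
    nodes = [f"{l}:{rng.uniform(0.1, 2.0):.3f}" for l in leaves]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.3f}")
    return f"({nodes[0]},{nodes[1]});"


class TestTreeDistance:
    def test_identical_trees_are_at_distance_zero(self):
        t = "((A:1,B:2):0.5,(C:1,D:1):0.5);"
        d = tree_distance(t, t)
        assert d["symmetric"] == 0 and d["branch_score"] == 0.0

    def test_conflicting_quartets_have_rf_two(self):
        d = tree_distance("((A:1,B:1):1,(C:1,D:1):1);", "((A:1,C:1):1,(B:1,D:1):1);")
        assert d["symmetric"] == 2

    def test_matches_dendropy_oracle_on_random_pairs(self):
        """Oracle: dendropy's bipartition-based treecompare on shared taxa."""
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(68)
        leaves = list("ABCDEFGH")
        for _ in range(30):
            n1, n2 = _random_tree(rng, leaves), _random_tree(rng, leaves)
            mine = tree_distance(n1, n2)
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            assert mine["symmetric"] == treecompare.symmetric_difference(t1, t2)
            assert mine["branch_score_sqrt"] == pytest.approx(
                treecompare.euclidean_distance(t1, t2), rel=1e-6
            )

    def test_rf_is_a_metric_on_sampled_triples(self):
        rng = np.random.default_rng(69)
        leaves = list("ABCDEFGH")
        trees = [_random_tree(rng, leaves) for _ in range(6)]
        for a, b, c in itertools.combinations(trees, 3):
            dab = tree_distance(a, b)["symmetric"]
            dbc = tree_distance(b, c)["symmetric"]
            dac = tree_distance(a, c)["symmetric"]
            assert dab == tree_distance(b, a)["symmetric"]
            assert dac <= dab + dbc

    def test_leaf_set_mismatch_errors(self):
        with pytest.raises(ValueError):
            tree_distance("((A:1,B:1):1,C:1);", "((A:1,B:1):1,D:1);")


class TestPruneToCommon:
    def test_identical_leaf_sets_unchanged(self):
        t = "((A:1,B:2):0.5,(C:1,D:1):0.5);"
        t1, t2 = prune_to_common(t, t)
        assert tree_distance(t1, t2)["symmetric"] == 0
        assert tree_distance(t1, t)["branch_score"] == pytest.approx(0.0)

    def test_cherry_leaf_removal_sums_branch_lengths(self):
        t1 = "((A:1,B:2):3,(C:1,(D:2,E:5):1.5):1);"
        t2 = "((A:1,B:1):1,(C:1,D:1):1);"
        p1, _ = prune_to_common(t1, t2)
        leaf_d = {l.taxon.label: l.edge.length for l in p1.leaf_node_iter()}
        assert leaf_d["D"] == pytest.approx(3.5)  # 2 + suppressed parent 1.5

    def test_disjoint_leaf_sets_error(self):
        with pytest.raises(ValueError):
            prune_to_common("((A:1,B:1):1,C:1);", "((X:1,Y:1):1,Z:1);")
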