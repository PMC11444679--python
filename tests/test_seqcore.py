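import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyomine import seqcore as sc
from pyomine.seqcore import (
    ClusterAssignment,
    DistanceMatrix,
    MultipleAlignment,
    NoComparableColumnsError,
    ProteinSequence,
    conservation_profile,
    global_align,
    hierarchical_cluster,
    identity_percent,
    identity_to_distance,
    jukes_cantor_aa_distance,
    p_distance,
    pairwise_distance_matrix,
    partition_variable_regions,
    silhouette_index,
)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDEFGHIKL", "ACDEFGHIKL", 0.0),
            ("AAAA", "AAAC", 0.25),
            ("AC-D", "AG-D", 1 / 3),  # gap column excluded from the count
            ("AXCD", "AYCD", 0.0),  # X columns are not comparable
        ],
    )
    def test_hand_counts(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_columns_is_an_error_not_zero(self):
        with pytest.raises(NoComparableColumnsError):
            p_distance("--XX", "AA--")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AAA", "AAAA")


class TestJukesCantor:
    def test_anchor_values_from_closed_form(self):
        # -(19/20) ln(1 - (20/19) p), frozen from the closed form
        assert jukes_cantor_aa_distance(0.0) == 0.0
        assert jukes_cantor_aa_distance(0.5) == pytest.approx(0.70985368, abs=1e-7)
        assert jukes_cantor_aa_distance(0.1) == pytest.approx(0.10566435, abs=1e-7)

    def test_fifty_percent_identity_maps_to_the_0_7_threshold(self):
        assert round(jukes_cantor_aa_distance(0.5), 1) == 0.7

    def test_saturation_sentinel(self):
        assert jukes_cantor_aa_distance(0.96) == sc.SATURATION_DISTANCE
        assert jukes_cantor_aa_distance(19 / 20) == sc.SATURATION_DISTANCE

    @given(st.floats(min_value=0.0, max_value=0.94))
    @settings(derandomize=True, max_examples=200)
    def test_correction_is_increasing_and_at_least_p(self, p):
        d = jukes_cantor_aa_distance(p)
        assert d >= p * (1 - 1e-12)  # one-ulp slack at denormal scale
        assert jukes_cantor_aa_distance(p + 0.005) > d

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=100)
    def test_identity_distance_round_trip(self, d):
        assert identity_to_distance(identity_percent(d)) == pytest.approx(d)


def _brute_force_align_score(a, b, open_=-10.0, extend=-1.0):
    """Enumerate affine-gap global alignments of tiny sequences (oracle)."""
    from functools import lru_cache

    B = sc._BLOSUM62

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(float(B[a[i], b[j]]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = extend if state == "X" else open_
            options.append(cost + best(i + 1, j, "X"))
        if j < len(b):
            cost = extend if state == "Y" else open_
            options.append(cost + best(i, j + 1, "Y"))
        return max(options)

    return best(0, 0, "M")


class TestGlobalAlign:
    def test_self_alignment_is_ungapped_full_identity(self):
        aln = global_align("ACD", "ACD")
        assert aln.rows[0].residues == "ACD"
        assert p_distance(aln.rows[0], aln.rows[1]) == 0.0

    @pytest.mark.parametrize("a,b", [("ACD", "AD"), ("WKLS", "WLS"), ("AC", "CA")])
    def test_matches_brute_force_enumeration(self, a, b):
        aligner = sc._make_aligner()
        assert aligner.score(a, b) == pytest.approx(_brute_force_align_score(a, b))
        aln = global_align(a, b)
        assert aln.rows[0].residues.replace("-", "") == a
        assert aln.rows[1].residues.replace("-", "") == b

    def test_all_mismatch_pair_stays_ungapped(self):
        aln = global_align("AAAA", "CCCC")
        assert "-" not in aln.rows[0].residues + aln.rows[1].residues
        assert p_distance(aln.rows[0], aln.rows[1]) == 1.0


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        seqs = [ProteinSequence(f"s{i}", "ACDEF") for i in range(3)]
        m = pairwise_distance_matrix(seqs)
        assert np.allclose(m.values, 0)

    def test_fifty_percent_pair_under_jukes_cantor(self):
        seqs = [ProteinSequence("a", "AAAAAAAAAA"), ProteinSequence("b", "AAAAACCCCC")]
        m = pairwise_distance_matrix(seqs, metric="jukes_cantor")
        assert m[("a", "b")] == pytest.approx(0.70985368, abs=1e-7)

    def test_symmetry_on_random_sequences(self):
        rng = np.random.default_rng(7)
        seqs = [
            ProteinSequence(f"s{i}", "".join(rng.choice(list(sc.AMINO_ACIDS), 30)))
            for i in range(10)
        ]
        m = pairwise_distance_matrix(seqs)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)

    def test_construction_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_tsv_round_trip(self, tmp_path):
        seqs = [ProteinSequence("a", "AAAA"), ProteinSequence("b", "AACC")]
        m = pairwise_distance_matrix(seqs)
        m.to_tsv(tmp_path / "m.tsv")
        m2 = DistanceMatrix.from_tsv(tmp_path / "m.tsv")
        assert m2.labels == m.labels
        assert np.allclose(m2.values, m.values)


class TestHierarchicalCluster:
    def _matrix(self, values, labels=None):
        values = np.asarray(values, dtype=float)
        labels = labels or [f"s{i}" for i in range(len(values))]
        return DistanceMatrix(labels, values)

    def test_all_zero_matrix_is_one_cluster(self):
        m = self._matrix(np.zeros((4, 4)))
        assert hierarchical_cluster(m, "single", cut=0.1).n_clusters == 1

    def test_two_tight_blocks_split_at_the_cut(self):
        v = np.full((4, 4), 0.9)
        v[:2, :2] = 0.05
        v[2:, 2:] = 0.05
        np.fill_diagonal(v, 0)
        for linkage in ("ward", "single", "complete", "average"):
            a = hierarchical_cluster(self._matrix(v), linkage, cut=0.5)
            assert a.n_clusters == 2
            assert a.cluster_ids[0] == a.cluster_ids[1] != a.cluster_ids[2]

    def test_cut_below_min_distance_gives_singletons(self):
        v = np.array([[0, 0.4, 0.5], [0.4, 0, 0.6], [0.5, 0.6, 0]])
        a = hierarchical_cluster(self._matrix(v), "single", cut=0.1)
        assert a.n_clusters == 3

    def test_identity_cut_semantics(self):
        # join at >= 70% identity: d=0.25 joins, d=0.35 does not
        v = np.array([[0, 0.25, 0.9], [0.25, 0, 0.9], [0.9, 0.9, 0]])
        a = hierarchical_cluster(self._matrix(v), "single", cut_identity=70.0)
        assert a.cluster_ids[0] == a.cluster_ids[1] != a.cluster_ids[2]

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(self._matrix(np.zeros((2, 2))), "centroid", cut=1)

    def test_single_linkage_equals_connected_components_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = 8
            v = np.round(rng.random((n, n)), 3)
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            cut = 0.35
            a = hierarchical_cluster(self._matrix(v), "single", cut=cut)
            # brute-force transitive closure of edges d <= cut
            import networkx as nx

            gph = nx.Graph()
            gph.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if v[i, j] <= cut:
                        gph.add_edge(i, j)
            comps = {
                node: ci
                for ci, comp in enumerate(nx.connected_components(gph))
                for node in comp
            }
            got = a.cluster_ids
            assert all(
                (comps[i] == comps[j]) == (got[i] == got[j])
                for i in range(n)
                for j in range(n)
            )


class TestSilhouette:
    def test_perfectly_separated_blocks_score_one(self):
        v = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        m = DistanceMatrix(list("abcd"), v)
        assert silhouette_index(m, [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_random_labels_on_structureless_matrix_near_zero(self):
        rng = np.random.default_rng(3)
        scores = []
        for _ in range(20):
            n = 12
            v = rng.random((n, n)) * 0.1 + 0.45
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            m = DistanceMatrix([f"s{i}" for i in range(n)], v)
            labels = rng.integers(0, 2, size=n)
            if len(set(labels)) < 2:
                continue
            scores.append(silhouette_index(m, labels))
        assert abs(np.mean(scores)) < 0.1

    def test_label_permutation_invariance(self):
        v = np.array(
            [[0, 0.1, 0.9, 0.9], [0.1, 0, 0.9, 0.9],
             [0.9, 0.9, 0, 0.1], [0.9, 0.9, 0.1, 0]]
        )
        m = DistanceMatrix(list("abcd"), v)
        assert silhouette_index(m, [0, 0, 1, 1]) == pytest.approx(
            silhouette_index(m, [1, 1, 0, 0])
        )

    def test_single_cluster_is_an_error(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValueError):
            silhouette_index(m, [0, 0])


class TestConservation:
    def _msa(self, rows):
        return MultipleAlignment(
            [ProteinSequence(f"s{i}", r) for i, r in enumerate(rows)]
        )

    def test_column_scores(self):
        msa = self._msa(["AC", "AC", "AA", "AC"])
        prof = conservation_profile(msa)
        assert prof.scores[0] == 1.0
        assert prof.scores[1] == 0.75

    def test_all_gap_column_scores_zero(self):
        msa = self._msa(["A-C", "A-C", "A-C"])
        assert conservation_profile(msa).scores[1] == 0.0

    def test_exactly_ten_sites_on_hundred_columns_with_ties(self):
        # 15 fully conserved columns; the decile keeps the 10 lowest-indexed
        conserved_at = [3, 11, 19, 27, 35, 43, 51, 59, 67, 75, 83, 86, 91, 95, 99]
        cols = ["AACC"] * 100
        for j in conserved_at:
            cols[j] = "AAAA"
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        prof = conservation_profile(self._msa(rows))
        assert len(prof.conserved_sites) == 10
        assert prof.conserved_sites == conserved_at[:10]

    def test_row_order_invariance(self):
        rows = ["ACDEF", "ACDFF", "AADEF", "ACDEW"]
        a = conservation_profile(self._msa(rows)).scores
        b = conservation_profile(self._msa(rows[::-1])).scores
        assert np.allclose(a, b)


class TestVariableRegions:
    def test_regions_between_conserved_sites(self):
        from pyomine.seqcore import ConservationProfile

        msa = MultipleAlignment(
            [ProteinSequence(f"s{i}", "ABCDEFGHIJ".replace("B", "C")) for i in range(3)]
        )
        prof = ConservationProfile(scores=np.zeros(10), conserved_sites=[2, 7, 9])
        regions = partition_variable_regions(prof, msa)
        assert [(r.start_col, r.end_col) for r in regions] == [(3, 7), (8, 9)]

    def test_adjacent_conserved_sites_yield_no_region(self):
        from pyomine.seqcore import ConservationProfile

        msa = MultipleAlignment(
            [ProteinSequence(f"s{i}", "AAAAAA") for i in range(3)]
        )
        prof = ConservationProfile(scores=np.zeros(6), conserved_sites=[4, 5])
        assert partition_variable_regions(prof, msa) == []

    def test_fewer_than_two_sites_warns_and_returns_empty(self):
        from pyomine.seqcore import ConservationProfile

        msa = MultipleAlignment([ProteinSequence(f"s{i}", "AAAA") for i in range(3)])
        prof = ConservationProfile(scores=np.zeros(4), conserved_sites=[1])
        with pytest.warns(UserWarning):
            assert partition_variable_regions(prof, msa) == []

    def test_anchor_coordinate_mapping_round_trips(self):
        rows = ["AC-DEFG", "ACWDEFG", "AC-DEFG"]
        msa = MultipleAlignment(
            [ProteinSequence(f"s{i}", r) for i, r in enumerate(rows)]
        )
        # non-gap anchor columns map bijectively to residues and back
        for col in (0, 1, 3, 4, 5, 6):
            pos = msa.column_to_residue("s0", col)
            assert msa.residue_to_column("s0", pos) == col
        assert msa.column_to_residue("s0", 2) is None


class TestClusterAssignment:
    def test_ids_must_be_contiguous(self):
        with pytest.raises(ValueError):
            ClusterAssignment(["a", "b"], [0, 2])

    def test_members_lookup(self):
        a = ClusterAssignment(["a", "b", "c"], [0, 1, 0])
        assert a.members(0) == ["a", "c"]
        assert a.of("b") == 1


def test_fasta_round_trip(tmp_path):
    seqs = [ProteinSequence("a", "ACDEF" * 30), ProteinSequence("b", "WWWW")]
    sc.write_fasta(seqs, tmp_path / "x.fasta")
    text = (tmp_path / "x.fasta").read_text()
    assert max(len(l) for l in text.splitlines()) <= 60
    back = sc.read_fasta(tmp_path / "x.fasta")
    assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]
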