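import math

import numpy as np
import pytest

from pyomine import simulate as sim
from pyomine.receptors import (
    ReceptorCandidate,
    classify_receptor,
    extract_feature_sequence,
    fpv_like_filter,
    group_receptors,
    identification_score,
    pep_proximity,
    rank_regions,
    rank_regions_by_group,
    shannon_diversity,
)
from pyomine.seqcore import (
    MultipleAlignment,
    ProteinSequence,
    VariableRegion,
    conservation_profile,
    partition_variable_regions,
)


def _candidate(length=809, stn=30.0, plug=60.0, tonb=90.0, r1=77.0, r2=10.0):
    return ReceptorCandidate(
        strain_id="s", candidate_id="s:c:0", contig_id="c", start=0,
        end=length * 3, strand="+", protein="A" * length,
        domain_scores={"STN": stn, "Plug": plug, "TonB": tonb},
        region_scores={"R1": r1, "R2": r2},
    )


class TestGates:
    def test_typical_receptor_passes(self):
        ok, trace = fpv_like_filter(_candidate(length=809, stn=30, plug=60, tonb=90))
        assert ok
        assert all("pass" in t for t in trace)

    def test_short_cds_fails_on_length(self):
        ok, trace = fpv_like_filter(_candidate(length=700))
        assert not ok
        assert any("length" in t and "fail" in t for t in trace)

    def test_gate_equality_fails_strictly(self):
        ok, _ = fpv_like_filter(_candidate(length=800, plug=50.0))
        assert not ok

    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            (77.0, 10.0, "FpvA"),
            (38.0, 10.0, "other_TonB"),
            (38.0, 60.0, "other_TonB"),
            (80.0, 49.0, "FpvB"),
            (50.0, 10.0, "other_TonB"),  # boundary equality: conservative
            (80.0, 30.0, "FpvB"),  # boundary equality: FpvB over FpvA
        ],
    )
    def test_flowchart(self, r1, r2, expected):
        cls = classify_receptor(_candidate(r1=r1, r2=r2))
        assert cls.receptor_class == expected

    def test_rejected_candidate_never_reaches_region_gates(self):
        cls = classify_receptor(_candidate(length=700, r1=100.0, r2=0.0))
        assert cls.receptor_class == "rejected"

    def test_every_candidate_maps_to_exactly_one_class(self):
        rng = np.random.default_rng(1)
        classes = {"FpvA", "FpvB", "other_TonB", "rejected"}
        for _ in range(200):
            c = _candidate(
                length=int(rng.integers(600, 1000)),
                stn=float(rng.uniform(-10, 120)),
                plug=float(rng.uniform(-10, 220)),
                tonb=float(rng.uniform(-10, 320)),
                r1=float(rng.uniform(-20, 200)),
                r2=float(rng.uniform(-20, 90)),
            )
            cls = classify_receptor(c)
            assert cls.receptor_class in classes
            # the trace replays to the same class
            again = classify_receptor(c)
            assert again.receptor_class == cls.receptor_class
            assert again.trace == cls.trace


def _labelled_msa(rng, n_pos=6, n_neg=4, ncols=30, planted=None):
    rows = []
    labels = {}
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        row = sim._rand_aa(rng, ncols)
        if planted is not None and positive:
            a, b, motif = planted
            row = row[:a] + motif + row[b:]
        rid = f"r{i}"
        rows.append(ProteinSequence(rid, row))
        labels[rid] = positive
    return MultipleAlignment(rows), labels


class TestIdentificationScore:
    def test_identical_positives_distant_negatives_hits_sentinel(self):
        rows = [ProteinSequence(f"p{i}", "AAAA") for i in range(3)]
        rows += [ProteinSequence(f"n{i}", "WWWW") for i in range(2)]
        msa = MultipleAlignment(rows)
        labels = {r.id: r.id.startswith("p") for r in rows}
        card = identification_score(msa, VariableRegion(0, 4), labels)
        assert math.isinf(card.score)
        assert card.flagged_infinite

    def test_shuffled_labels_on_structureless_fixture_score_near_one(self):
        rng = np.random.default_rng(3)
        scores = []
        for _ in range(30):
            msa, labels = _labelled_msa(rng, ncols=40)
            ids = list(labels)
            perm = rng.permutation(len(ids))
            shuffled = {ids[i]: labels[ids[int(j)]] for i, j in enumerate(perm)}
            card = identification_score(msa, VariableRegion(0, 40), shuffled)
            scores.append(card.score)
        assert np.mean(scores) == pytest.approx(1.0, abs=0.05)

    def test_planted_motif_region_is_maximally_discriminative(self):
        rng = np.random.default_rng(4)
        msa, labels = _labelled_msa(rng, ncols=40, planted=(10, 20, "WKLSTDNPQR"))
        regions = [VariableRegion(0, 10), VariableRegion(10, 20), VariableRegion(25, 40)]
        cards = rank_regions(msa, regions, labels)
        assert (cards[0].region.start_col, cards[0].region.end_col) == (10, 20)
        assert cards[0].score > 1.5

    def test_scale_consistency_duplicating_columns_leaves_score_unchanged(self):
        rng = np.random.default_rng(5)
        msa, labels = _labelled_msa(rng, ncols=20)
        doubled = MultipleAlignment(
            [ProteinSequence(r.id, r.residues + r.residues) for r in msa.rows]
        )
        a = identification_score(msa, VariableRegion(0, 20), labels).score
        b = identification_score(doubled, VariableRegion(0, 40), labels).score
        assert a == pytest.approx(b)

    def test_needs_enough_references(self):
        rng = np.random.default_rng(6)
        msa, labels = _labelled_msa(rng, n_pos=1, n_neg=3)
        with pytest.raises(ValueError):
            identification_score(msa, VariableRegion(0, 5), labels)

    def test_ranking_invariant_to_region_enumeration_order(self):
        rng = np.random.default_rng(7)
        msa, labels = _labelled_msa(rng, ncols=40, planted=(10, 20, "WKLSTDNPQR"))
        regions = [VariableRegion(0, 10), VariableRegion(10, 20), VariableRegion(25, 40)]
        a = rank_regions(msa, regions, labels)
        b = rank_regions(msa, list(reversed(regions)), labels)
        assert [c.region.start_col for c in a] == [c.region.start_col for c in b]


class TestRegionDiscoveryOnFixture:
    def test_anchor_layout_recovered_and_designed_regions_rank_first(self, fixtures):
        msa = MultipleAlignment(
            [ProteinSequence(r["id"], r["sequence"]) for r in fixtures.receptor_refs]
        )
        prof = conservation_profile(msa, decile=0.10)
        assert prof.conserved_sites == fixtures.scaffold.anchors
        regions = partition_variable_regions(prof, msa, anchor_id=msa.rows[0].id)
        labels = {r["id"]: r["class"] == "FpvA" for r in fixtures.receptor_refs}
        cards = rank_regions(msa, regions, labels)
        r1 = (cards[0].region.start_col, cards[0].region.end_col)
        r2 = (cards[1].region.start_col, cards[1].region.end_col)
        assert r1 == sim._R1_REGION
        assert r2 == sim._R2_REGION

    def test_group_feature_regions_follow_alignment_order(self, fixtures):
        msa = MultipleAlignment(
            [
                ProteinSequence(r["id"], r["sequence"])
                for r in fixtures.receptor_refs
                if r["class"] == "FpvA"
            ]
        )
        prof = conservation_profile(
            MultipleAlignment(
                [ProteinSequence(r["id"], r["sequence"])
                 for r in fixtures.receptor_refs]
            ),
            decile=0.10,
        )
        regions = partition_variable_regions(prof, msa)
        groups = {
            r["id"]: r["group"]
            for r in fixtures.receptor_refs
            if r["class"] == "FpvA"
        }
        ranked = rank_regions_by_group(msa, regions, groups)
        top4 = sorted(
            [(r.start_col, r.end_col) for r, _ in ranked[:4]]
        )
        assert top4 == sorted(sim._GROUP_REGIONS)


class TestFeatureSequences:
    def test_fixture_receptor_features_equal_planted_blocks(self, fixtures):
        scaffold = fixtures.scaffold
        anchor = ProteinSequence("anchor", fixtures.receptor_refs[0]["sequence"])
        regions = [
            VariableRegion(a, b, anchor_id="anchor", anchor_start=a + 1, anchor_end=b)
            for a, b in sim._GROUP_REGIONS
        ]
        rng = np.random.default_rng(8)
        rec = sim.compose_receptor(rng, scaffold, "FpvA", 2, 0.0)
        feat, flagged = extract_feature_sequence(
            ProteinSequence("r", rec), regions, anchor
        )
        assert not flagged
        assert feat == sim._feature_blocks_of(rec, scaffold)

    def test_deletion_spanning_a_region_shortens_and_flags(self, fixtures):
        anchor = ProteinSequence("anchor", fixtures.receptor_refs[0]["sequence"])
        regions = [
            VariableRegion(a, b, anchor_id="anchor", anchor_start=a + 1, anchor_end=b)
            for a, b in sim._GROUP_REGIONS
        ]
        rng = np.random.default_rng(9)
        rec = sim.compose_receptor(rng, fixtures.scaffold, "FpvA", 1, 0.0)
        a, b = sim._GROUP_REGIONS[1]
        deleted = rec[:a] + rec[b:]
        feat, flagged = extract_feature_sequence(
            ProteinSequence("r", deleted), regions, anchor
        )
        full = sim._feature_blocks_of(rec, fixtures.scaffold)
        assert len(feat) < len(full)

    def test_divergence_outside_regions_leaves_feature_unchanged(self, fixtures):
        anchor = ProteinSequence("anchor", fixtures.receptor_refs[0]["sequence"])
        regions = [
            VariableRegion(a, b, anchor_id="anchor", anchor_start=a + 1, anchor_end=b)
            for a, b in sim._GROUP_REGIONS
        ]
        rng = np.random.default_rng(10)
        rec = sim.compose_receptor(rng, fixtures.scaffold, "FpvA", 3, 0.0)
        other = list(rec)
        gcols = set(fixtures.scaffold.group_cols)
        for j in range(0, 700, 13):
            if j not in gcols:
                other[j] = "W" if other[j] != "W" else "Y"
        f1, _ = extract_feature_sequence(ProteinSequence("r1", rec), regions, anchor)
        f2, _ = extract_feature_sequence(
            ProteinSequence("r2", "".join(other)), regions, anchor
        )
        assert f1 == f2


class TestGrouping:
    def test_identity_threshold_semantics(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        near = "ACDEFGHIKLMNPQWWWWWY"  # 75% identity (5/20 differ)
        far = "WCDWFGHWKLWNPQWSWVWW"  # 65% identity to base (7/20 differ)
        g = group_receptors({"a": base, "b": near}, identity_threshold=70.0)
        assert g.group_of("a") == g.group_of("b")
        g2 = group_receptors({"a": base, "c": far}, identity_threshold=70.0)
        assert g2.group_of("a") != g2.group_of("c")

    def test_full_identity_threshold_gives_unique_sequences(self):
        seqs = {"a": "AAAA", "b": "AAAA", "c": "AAAC", "d": "CCCC"}
        g = group_receptors(seqs, identity_threshold=100.0)
        assert g.group_of("a") == g.group_of("b")
        assert len({g.group_of(x) for x in "acd"}) == 3

    def test_single_receptor_forms_its_own_group(self):
        g = group_receptors({"only": "ACDEF"})
        assert g.assignments.n_clusters == 1


class TestGenomeContext:
    def test_gap_distance_and_window(self):
        d, prox = pep_proximity(("c1", 5000, 10000), ("c1", 15000, 40000))
        assert (d, prox) == (5000.0, True)

    def test_different_contigs_flagged(self):
        d, prox = pep_proximity(("c1", 0, 100), ("c2", 0, 100))
        assert math.isinf(d) and not prox

    def test_overlap_is_zero(self):
        d, prox = pep_proximity(("c1", 0, 5000), ("c1", 4000, 9000))
        assert (d, prox) == (0.0, True)

    def test_beyond_window_not_proximate(self):
        d, prox = pep_proximity(("c1", 0, 100), ("c1", 25000, 30000))
        assert d == 24900.0 and not prox


class TestShannon:
    def test_single_group_zero(self):
        assert shannon_diversity([7]) == 0.0

    def test_uniform_four_groups_ln4(self):
        assert shannon_diversity([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-12)

    def test_bits_base(self):
        assert shannon_diversity([1, 1], base="bits") == pytest.approx(1.0)

    def test_bounded_by_log_k(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(1, 50, size=rng.integers(1, 8))
            h = shannon_diversity(list(counts))
            assert -1e-12 <= h <= math.log(len(counts)) + 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0, 0])
        with pytest.raises(ValueError):
            shannon_diversity([-1, 2])
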