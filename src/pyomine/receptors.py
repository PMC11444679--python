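"""Region-based identification and grouping of FpvA pyoverdine receptors.

FpvA, the TonB-dependent receptor importing ferri-pyoverdine, cannot be told
apart from related siderophore receptors by whole-sequence similarity.  The
pipeline therefore (i) gates candidates on coding length (750-850 aa) and on
profile-HMM scores of the three canonical receptor domains (STN, Plug, TonB
barrel), then (ii) scores two short variable regions discovered from a
labelled reference alignment: R1, at the Plug/barrel intersection, separates
Fpv receptors from other siderophore receptors, and R2, in the N-terminal
signaling domain, separates FpvA from FpvB.  Receptor groups — proxies for
pyoverdine specificity — come from single-linkage clustering of a 'feature
sequence' concatenated from the four most group-discriminative variable
regions near the Plug domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from pyomine import phmm as _phmm
from pyomine.seqcore import (
    ClusterAssignment,
    MultipleAlignment,
    ProteinSequence,
    VariableRegion,
    global_align,
    hierarchical_cluster,
    p_distance,
    pairwise_distance_matrix,
)


@dataclass
class ReceptorCandidate:
    strain_id: str
    candidate_id: str
    contig_id: str
    start: int  # nt, 0-based half-open, forward strand
    end: int
    strand: str
    protein: str
    domain_scores: dict[str, float] = field(default_factory=dict)  # STN/Plug/TonB
    region_scores: dict[str, float] = field(default_factory=dict)  # R1/R2

    @property
    def length(self) -> int:
        return len(self.protein)


@dataclass
class ReceptorClassification:
    candidate_id: str
    receptor_class: str  # FpvA | FpvB | other_TonB | rejected
    trace: list[str] = field(default_factory=list)


@dataclass
class RegionScoreCard:
    region: VariableRegion
    score: float  # identification score I = d(pos:neg) / d(pos:pos)
    flagged_infinite: bool = False


@dataclass
class ReceptorGroupAssignment:
    assignments: ClusterAssignment
    feature_sequences: dict[str, str]

    def group_of(self, receptor_id: str) -> int:
        return self.assignments.of(receptor_id)


# ---------------------------------------------------------------------------
# gating and classification


def fpv_like_filter(
    c: ReceptorCandidate,
    min_len: int = 750,
    max_len: int = 850,
    stn_gate: float = 25.0,
    plug_gate: float = 50.0,
    tonb_gate: float = 80.0,
) -> tuple[bool, list[str]]:
    """Fpv-like gate: length within [750, 850] aa and STN/Plug/TonB pHMM
    scores strictly above their thresholds.  Returns (passed, gate trace)."""
    trace = []
    ok = True
    if min_len <= c.length <= max_len:
        trace.append(f"length {c.length} in [{min_len},{max_len}]: pass")
    else:
        trace.append(f"length {c.length} outside [{min_len},{max_len}]: fail")
        ok = False
    for name, gate in (("STN", stn_gate), ("Plug", plug_gate), ("TonB", tonb_gate)):
        score = c.domain_scores.get(name, float("-inf"))
        if score > gate:
            trace.append(f"{name} {score:.1f} > {gate:g}: pass")
        else:
            trace.append(f"{name} {score:.1f} <= {gate:g}: fail")
            ok = False
    return ok, trace


def classify_receptor(
    c: ReceptorCandidate,
    r1_gate: float = 50.0,
    r2_gate: float = 30.0,
    **gate_kwargs,
) -> ReceptorClassification:
    """Decision flowchart: rejected / other_TonB / FpvB / FpvA.

    Boundary equality routes to the more conservative class (other over FpvB,
    FpvB over FpvA), so an uncertain candidate is never promoted to FpvA.
    """
    ok, trace = fpv_like_filter(c, **gate_kwargs)
    if not ok:
        return ReceptorClassification(c.candidate_id, "rejected", trace)
    r1 = c.region_scores.get("R1", float("-inf"))
    r2 = c.region_scores.get("R2", float("-inf"))
    if r1 <= r1_gate:
        trace.append(f"R1 {r1:.1f} <= {r1_gate:g}: other siderophore receptor")
        return ReceptorClassification(c.candidate_id, "other_TonB", trace)
    trace.append(f"R1 {r1:.1f} > {r1_gate:g}: Fpv receptor")
    if r2 >= r2_gate:
        trace.append(f"R2 {r2:.1f} >= {r2_gate:g}: FpvB")
        return ReceptorClassification(c.candidate_id, "FpvB", trace)
    trace.append(f"R2 {r2:.1f} < {r2_gate:g}: FpvA")
    return ReceptorClassification(c.candidate_id, "FpvA", trace)


def score_candidate(
    c: ReceptorCandidate,
    domain_models: dict[str, _phmm.ProfileHMM],
    region_models: dict[str, _phmm.ProfileHMM],
) -> ReceptorCandidate:
    """Fill domain (STN/Plug/TonB) and region (R1/R2) pHMM scores in place."""
    seq = ProteinSequence(c.candidate_id, c.protein)
    for name, model in domain_models.items():
        c.domain_scores[name] = _phmm.score_sequence(model, seq, mode="local").score
    for name, model in region_models.items():
        c.region_scores[name] = _phmm.score_sequence(model, seq, mode="local").score
    return c


# ---------------------------------------------------------------------------
# identification scores and region ranking


def _mean_region_distance(
    msa: MultipleAlignment, region: VariableRegion, ids_a: list[str], ids_b: list[str]
) -> float:
    """Mean pairwise p-distance of the region slice between two id sets
    (within one set when the sets are identical)."""
    sub = msa.slice_columns(region.start_col, region.end_col)
    rows = {r.id: r.residues for r in sub.rows}
    total, count = 0.0, 0
    if ids_a is ids_b or ids_a == ids_b:
        for i, a in enumerate(ids_a):
            for b in ids_a[i + 1 :]:
                total += p_distance(rows[a], rows[b])
                count += 1
    else:
        for a in ids_a:
            for b in ids_b:
                total += p_distance(rows[a], rows[b])
                count += 1
    return total / count if count else float("nan")


def identification_score(
    msa: MultipleAlignment,
    region: VariableRegion,
    labels: dict[str, bool],
) -> RegionScoreCard:
    """I = mean positive-vs-negative distance / mean positive-vs-positive.

    Analogous to an intercluster-vs-intracluster variance ratio: the higher I,
    the better the region separates the positive class.  Zero within-class
    distance yields an infinite sentinel, flagged rather than silently capped.
    """
    pos = sorted(i for i, v in labels.items() if v)
    neg = sorted(i for i, v in labels.items() if not v)
    if len(pos) < 2 or len(neg) < 1:
        raise ValueError("need >=2 positive and >=1 negative references")
    d_aa = _mean_region_distance(msa, region, pos, pos)
    d_an = _mean_region_distance(msa, region, pos, neg)
    if d_aa == 0:
        if d_an == 0:  # region invariant in both classes: no signal either way
            return RegionScoreCard(region, 1.0, flagged_infinite=True)
        return RegionScoreCard(region, float("inf"), flagged_infinite=True)
    return RegionScoreCard(region, d_an / d_aa)


def group_identification_score(
    msa: MultipleAlignment,
    region: VariableRegion,
    groups: dict[str, int],
) -> float:
    """Between-group over within-group mean region distance, multi-class.

    Falls back to the mean within-set distance (pure diversity) when every
    member sits in one group — a degenerate labelling carries no between-group
    signal, but region diversity still ranks specificity-bearing regions.
    """
    ids = sorted(groups)
    sub = msa.slice_columns(region.start_col, region.end_col)
    rows = {r.id: r.residues for r in sub.rows}
    within, between = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = p_distance(rows[a], rows[b])
            (within if groups[a] == groups[b] else between).append(d)
    if not between:
        all_d = within
        return sum(all_d) / len(all_d) if all_d else float("nan")
    mean_between = sum(between) / len(between)
    if not within or sum(within) == 0:
        return float("inf")
    return mean_between / (sum(within) / len(within))


def rank_regions(
    msa: MultipleAlignment,
    regions: Sequence[VariableRegion],
    labels: dict[str, bool],
) -> list[RegionScoreCard]:
    """Regions ranked by FpvA identification score, descending; ties keep
    alignment order."""
    if len(regions) < 2:
        raise ValueError("need at least two variable regions to rank")
    cards = [identification_score(msa, r, labels) for r in regions]
    return sorted(cards, key=lambda c: (-c.score, c.region.start_col))


def rank_regions_by_group(
    msa: MultipleAlignment,
    regions: Sequence[VariableRegion],
    groups: dict[str, int],
) -> list[tuple[VariableRegion, float]]:
    scored = [(r, group_identification_score(msa, r, groups)) for r in regions]
    return sorted(scored, key=lambda t: (-t[1], t[0].start_col))


# ---------------------------------------------------------------------------
# feature sequences and grouping


def extract_feature_sequence(
    receptor: ProteinSequence,
    regions: Sequence[VariableRegion],
    anchor: ProteinSequence,
) -> tuple[str, bool]:
    """Concatenate the receptor's residues across the given regions, N->C.

    The receptor is globally aligned to the (ungapped) anchor sequence of the
    reference alignment; each region's anchor residue range maps through the
    alignment onto the receptor.  Returns (feature, flagged) where flagged
    marks a deletion spanning an entire region.
    """
    ordered = sorted(regions, key=lambda r: r.start_col)
    aln = global_align(receptor, anchor)
    rec_row, anc_row = aln.rows[0].residues, aln.rows[1].residues
    # anchor residue index (1-based) -> receptor residue slice
    anchor_pos_to_col: dict[int, int] = {}
    pos = 0
    for j, ch in enumerate(anc_row):
        if ch != "-":
            pos += 1
            anchor_pos_to_col[pos] = j
    parts: list[str] = []
    flagged = False
    for region in ordered:
        if region.anchor_start is None or region.anchor_end is None:
            flagged = True
            continue
        c0 = anchor_pos_to_col[region.anchor_start]
        c1 = anchor_pos_to_col[region.anchor_end]
        piece = rec_row[c0 : c1 + 1].replace("-", "")
        if not piece:
            flagged = True
        parts.append(piece)
    return "".join(parts), flagged


def group_receptors(
    feature_sequences: dict[str, str],
    identity_threshold: float = 70.0,
    linkage: str = "single",
) -> ReceptorGroupAssignment:
    """Group receptors by feature-sequence identity.

    Members joining at identity >= the threshold share a group (single
    linkage by default, i.e. transitive closure); a lone receptor forms its
    own group.
    """
    ids = sorted(feature_sequences)
    if not ids:
        raise ValueError("no feature sequences to group")
    if len(ids) == 1:
        return ReceptorGroupAssignment(
            ClusterAssignment(ids, [0]), dict(feature_sequences)
        )
    seqs = [ProteinSequence(i, feature_sequences[i]) for i in ids]
    mode = "aligned" if len({len(s) for s in seqs}) == 1 else "global_align"
    m = pairwise_distance_matrix(seqs, metric="p", mode=mode)
    assign = hierarchical_cluster(
        m, linkage=linkage, cut_identity=identity_threshold
    )
    return ReceptorGroupAssignment(assign, dict(feature_sequences))


# ---------------------------------------------------------------------------
# genome context


def pep_proximity(
    receptor_coords: tuple[str, int, int],
    pep_coords: tuple[str, int, int],
    window_bp: int = 20000,
) -> tuple[float, bool]:
    """Base-pair gap between a receptor gene and the Pep synthetase region.

    Overlapping features are at distance 0; features on different contigs are
    infinitely distant and never proximate.
    """
    rc, rs, re_ = receptor_coords
    pc, ps, pe = pep_coords
    if rc != pc:
        return float("inf"), False
    if re_ <= ps:
        d = ps - re_
    elif pe <= rs:
        d = rs - pe
    else:
        d = 0
    return float(d), d <= window_bp


def shannon_diversity(group_counts: Sequence[int], base: str = "nats") -> float:
    """Shannon entropy of a receptor-group abundance vector.

    -sum p_i log p_i with natural log by default ('bits' uses log2); zero
    counts are ignored.  Bounded by log(k) for k observed groups.
    """
    counts = [c for c in group_counts if c > 0]
    if not counts or any(c < 0 for c in group_counts):
        raise ValueError("counts must be non-negative with positive sum")
    total = sum(counts)
    log = math.log if base == "nats" else math.log2
    return -sum((c / total) * log(c / total) for c in counts) + 0.0
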