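"""Shared sequence primitives: distances, alignment, clustering, conservation.

Distances are expressed as dimensionless fractions; percent identity and
distance interconvert as ``identity = (1 - d) * 100``.  The amino-acid
Jukes-Cantor correction used throughout is the 20-state form
``-(19/20) * ln(1 - (20/19) * p)``, which maps 50% identity to a corrected
distance of ~0.71 — the scale on which the substrate-calling threshold of
0.7 is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: distance assigned when p >= 19/20 and the Jukes-Cantor log diverges
SATURATION_DISTANCE = 5.0


class NoComparableColumnsError(ValueError):
    """Raised when two gapped sequences share no both-ungapped, non-X column."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence; gaps ('-') only appear in alignment rows."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.id!r}")
        if self.residues != self.residues.upper():
            raise ValueError(f"residues must be uppercase for id {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "ProteinSequence":
        return ProteinSequence(self.id, self.residues.replace(GAP, ""))

    @property
    def is_gapped(self) -> bool:
        return GAP in self.residues


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows; ungapping a row recovers its source sequence."""

    rows: list[ProteinSequence]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> ProteinSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def slice_columns(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(
            [ProteinSequence(r.id, r.residues[start:end]) for r in self.rows]
        )

    def column_to_residue(self, seq_id: str, col: int) -> int | None:
        """Map alignment column -> 1-based residue position in `seq_id`.

        Returns None when the row is gapped at `col`.
        """
        row = self.row(seq_id).residues
        if row[col] == GAP:
            return None
        return col - row[:col].count(GAP) + 1

    def residue_to_column(self, seq_id: str, pos: int) -> int:
        """Map 1-based residue position in `seq_id` -> alignment column."""
        row = self.row(seq_id).residues
        seen = 0
        for j, ch in enumerate(row):
            if ch != GAP:
                seen += 1
                if seen == pos:
                    return j
        raise IndexError(f"residue {pos} beyond end of {seq_id!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by sequence ids."""

    labels: list[str]
    values: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


@dataclass
class ConservationProfile:
    """Per-column conservation scores plus the top-decile conserved columns."""

    scores: np.ndarray
    conserved_sites: list[int]


@dataclass
class VariableRegion:
    """Alignment columns [start_col, end_col) flanked by conserved sites.

    ``anchor_start``/``anchor_end`` give the 1-based inclusive residue range on
    the named anchor sequence, or None where the anchor is all-gap inside the
    region.
    """

    start_col: int
    end_col: int
    anchor_id: str | None = None
    anchor_start: int | None = None
    anchor_end: int | None = None

    def __post_init__(self) -> None:
        if self.start_col >= self.end_col:
            raise ValueError("variable region must span at least one column")

    @property
    def n_columns(self) -> int:
        return self.end_col - self.start_col


@dataclass
class ClusterAssignment:
    """Cluster ids (contiguous from 0) for an ordered list of labels."""

    labels: list[str]
    cluster_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cluster_ids):
            raise ValueError("labels / cluster ids length mismatch")
        uniq = sorted(set(self.cluster_ids))
        if uniq != list(range(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_ids))

    def members(self, cluster_id: int) -> list[str]:
        return [l for l, c in zip(self.labels, self.cluster_ids) if c == cluster_id]

    def of(self, label: str) -> int:
        return self.cluster_ids[self.labels.index(label)]


# ---------------------------------------------------------------------------
# distances


def p_distance(a: str | ProteinSequence, b: str | ProteinSequence) -> float:
    """Fraction of mismatching residues over comparable columns.

    A column is comparable when both rows are ungapped and neither is 'X'.
    Raises :class:`NoComparableColumnsError` when nothing can be compared —
    an unalignable pair must never silently look identical.
    """
    ra = a.residues if isinstance(a, ProteinSequence) else a
    rb = b.residues if isinstance(b, ProteinSequence) else b
    if len(ra) != len(rb):
        raise ValueError("p_distance requires equal-length (aligned) sequences")
    comparable = 0
    mismatch = 0
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP or x == UNKNOWN or y == UNKNOWN:
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    if comparable == 0:
        raise NoComparableColumnsError("no comparable columns between sequences")
    return mismatch / comparable


def jukes_cantor_aa_distance(
    p: float, saturation: float = SATURATION_DISTANCE
) -> float:
    """20-state amino-acid Jukes-Cantor correction of a p-distance.

    ``d = -(19/20) ln(1 - (20/19) p)``; saturated inputs (p >= 19/20) return
    the configured sentinel so downstream clustering stays finite.
    """
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 19 / 20:
        return saturation
    return -(19 / 20) * math.log1p(-(20 / 19) * p)


def identity_percent(d: float) -> float:
    """identity (%) = (1 - sequence distance) * 100."""
    return (1.0 - d) * 100.0


def identity_to_distance(identity: float) -> float:
    return 1.0 - identity / 100.0


# ---------------------------------------------------------------------------
# alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def global_align(
    a: ProteinSequence | str, b: ProteinSequence | str
) -> MultipleAlignment:
    """Optimal global alignment (BLOSUM62, affine gaps 10/1), two gapped rows.

    The first optimal alignment reported by the dynamic program is taken,
    which fixes the tie-break and makes the result deterministic.
    """
    sa = a if isinstance(a, ProteinSequence) else ProteinSequence("a", a)
    sb = b if isinstance(b, ProteinSequence) else ProteinSequence("b", b)
    aligner = _make_aligner()
    aln = aligner.align(sa.residues, sb.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return MultipleAlignment(
        [ProteinSequence(sa.id, ga), ProteinSequence(sb.id, gb)]
    )


def aligned_pair_distance(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    metric: Literal["p", "jukes_cantor"] = "p",
    mode: Literal["aligned", "global_align"] = "aligned",
    saturation: float = SATURATION_DISTANCE,
) -> float:
    """Distance between two sequences, aligning first when requested."""
    if mode == "global_align":
        aln = global_align(a, b)
        p = p_distance(aln.rows[0], aln.rows[1])
    else:
        p = p_distance(a, b)
    if metric == "jukes_cantor":
        return jukes_cantor_aa_distance(p, saturation=saturation)
    if metric == "p":
        return p
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_distance_matrix(
    seqs: Sequence[ProteinSequence],
    metric: Literal["p", "jukes_cantor"] = "p",
    mode: Literal["aligned", "global_align"] = "aligned",
    saturation: float = SATURATION_DISTANCE,
) -> DistanceMatrix:
    """Symmetric distance matrix over sequences.

    `aligned` mode requires equal lengths (rows of an MSA or equal-length
    feature sequences); `global_align` aligns every pair first.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if mode == "aligned":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("aligned mode requires equal-length sequences")
    n = len(seqs)
    values = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = aligned_pair_distance(
                    seqs[i], seqs[j], metric=metric, mode=mode, saturation=saturation
                )
            except NoComparableColumnsError as exc:
                raise NoComparableColumnsError(
                    f"pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            if metric == "jukes_cantor" and d == saturation:
                saturated.append((ids[i], ids[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, saturated_pairs=saturated)


# ---------------------------------------------------------------------------
# clustering

_LINKAGES = ("ward", "single", "complete", "average")


def hierarchical_cluster(
    m: DistanceMatrix,
    linkage: Literal["ward", "single", "complete", "average"] = "ward",
    cut: float | None = None,
    cut_identity: float | None = None,
    n_clusters: int | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of a distance matrix with a flat cut.

    The cut is one of a raw distance (`cut`), a percent identity
    (`cut_identity`, converted via d = 1 - identity/100; members joining at
    identity >= the threshold share a group), or a target cluster count.
    Single linkage with a distance cut equals the transitive closure of the
    graph whose edges connect pairs at distance <= cut.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {_LINKAGES}")
    given = [x is not None for x in (cut, cut_identity, n_clusters)]
    if sum(given) != 1:
        raise ValueError("give exactly one of cut, cut_identity, n_clusters")
    Z = hierarchy.linkage(m.condensed(), method=linkage)
    if n_clusters is not None:
        raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        t = cut if cut is not None else identity_to_distance(cut_identity)
        raw = hierarchy.fcluster(Z, t=t, criterion="distance")
    # renumber contiguously from 0 in order of first appearance
    remap: dict[int, int] = {}
    ids = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap)
        ids.append(remap[c])
    return ClusterAssignment(list(m.labels), ids)


def silhouette_index(m: DistanceMatrix, labels: Sequence) -> float:
    """Mean silhouette over samples, computed from the distance matrix."""
    if len(labels) != m.n:
        raise ValueError("one label per matrix row required")
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)[1]
    return float(silhouette_score(m.values, codes, metric="precomputed"))


# ---------------------------------------------------------------------------
# conservation


def conservation_profile(
    msa: MultipleAlignment, decile: float = 0.10
) -> ConservationProfile:
    """Per-column modal-residue frequency plus the top-decile conserved sites.

    The score of a column is the frequency of its most common non-gap residue
    among non-gap rows (all-gap columns score 0).  Conserved sites are the
    ``ceil(decile * n_columns)`` best columns; ties at the boundary resolve to
    the lower column index.
    """
    if msa.n_rows < 3:
        raise ValueError("conservation profile needs at least three rows")
    ncol = msa.n_columns
    scores = np.zeros(ncol)
    for j in range(ncol):
        col = [c for c in msa.column(j) if c != GAP]
        if not col:
            continue
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        scores[j] = max(counts.values()) / len(col)
    k = max(1, math.ceil(decile * ncol))
    order = sorted(range(ncol), key=lambda j: (-scores[j], j))
    conserved = sorted(order[:k])
    return ConservationProfile(scores=scores, conserved_sites=conserved)


def partition_variable_regions(
    profile: ConservationProfile,
    msa: MultipleAlignment,
    anchor_id: str | None = None,
) -> list[VariableRegion]:
    """Variable regions between consecutive conserved sites.

    One region per consecutive conserved-site pair with at least one
    intervening column, expressed as half-open alignment columns and, when an
    anchor row is named, as a 1-based inclusive residue range on that anchor.
    """
    sites = profile.conserved_sites
    if len(sites) < 2:
        import warnings

        warnings.warn("fewer than two conserved sites; no variable regions")
        return []
    regions: list[VariableRegion] = []
    for left, right in zip(sites, sites[1:]):
        if right - left < 2:
            continue
        start, end = left + 1, right
        a_start = a_end = None
        if anchor_id is not None:
            positions = [
                p
                for j in range(start, end)
                if (p := msa.column_to_residue(anchor_id, j)) is not None
            ]
            if positions:
                a_start, a_end = positions[0], positions[-1]
        regions.append(
            VariableRegion(
                start_col=start,
                end_col=end,
                anchor_id=anchor_id,
                anchor_start=a_start,
                anchor_end=a_end,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[ProteinSequence]:
    from Bio import SeqIO

    return [
        ProteinSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), wrap):
                fh.write(s.residues[i : i + wrap] + "\n")
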