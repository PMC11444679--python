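"""Phylogeny-focused substrate prediction for NRPS adenylation domains.

Rather than placing every query A domain in a reference phylogeny — slow, and
confounded by overall species relatedness — each query's Amotif4-5 feature
sequence is compared against substrate-labelled reference clusters.  With X1
and X2 the Jukes-Cantor feature distances to the two nearest reference
clusters, the call is:

* rule 1 — X1 below the 0.7 threshold (50% identity), X2 not: the nearest
  cluster's substrate, unambiguous;
* rule 2a — both below 0.7 and relative difference (X2-X1)/X2 > 0.2: the
  nearest cluster's substrate;
* rule 2b — both below 0.7, relative difference <= 0.2: dual call carrying
  both substrates;
* rule 3 — both at or above 0.7: 'unknown'.

Chirality comes from the assembly line itself: a module whose A domain is
followed by an epimerization domain contributes a D-amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from pyomine.seqcore import (
    ClusterAssignment,
    DistanceMatrix,
    MultipleAlignment,
    ProteinSequence,
    aligned_pair_distance,
    hierarchical_cluster,
    pairwise_distance_matrix,
    silhouette_index,
)

#: substrates with experimentally confirmed reference A domains; OHOrn is an
#: umbrella for the three ornithine derivatives, which feature-sequence
#: comparison cannot tell apart
DEFAULT_SUBSTRATES = (
    "Ser", "Lys", "Thr", "Ala", "Gly", "Gln", "Arg", "Asp", "Glu", "Tyr",
    "Orn", "Rsc", "Dab", "OHAsp", "OHOrn",
)

CHROMOPHORE_MARKER = "Chr"


@dataclass
class ReferenceADomain:
    id: str
    substrate: str
    amotif45: ProteinSequence
    source: str = ""

    def __post_init__(self) -> None:
        if not self.substrate:
            raise ValueError("substrate label must be non-empty")


@dataclass
class ReferenceSet:
    """Substrate-labelled reference A domains grouped by substrate."""

    references: list[ReferenceADomain]

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("empty reference set")

    @property
    def substrates(self) -> list[str]:
        return sorted({r.substrate for r in self.references})

    def cluster_members(self, substrate: str) -> list[ReferenceADomain]:
        return [r for r in self.references if r.substrate == substrate]

    @property
    def substrate_clusters(self) -> ClusterAssignment:
        subs = self.substrates
        return ClusterAssignment(
            [r.id for r in self.references],
            [subs.index(r.substrate) for r in self.references],
        )

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        refs = [
            ReferenceADomain(
                id=row["id"],
                substrate=row["substrate"],
                amotif45=ProteinSequence(row["id"], row["amotif45_sequence"]),
                source=row.get("source", ""),
            )
            for row in df.to_dict("records")
        ]
        return cls(refs)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "id": r.id,
                    "substrate": r.substrate,
                    "amotif45_sequence": r.amotif45.residues,
                    "source": r.source,
                }
                for r in self.references
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SubstratePrediction:
    query_id: str
    x1: float
    x2: float
    substrate_a: str
    substrate_b: str
    call: str  # substrate, "A|B", or "unknown"
    rule: str  # 1 | 2a | 2b | 3

    def __post_init__(self) -> None:
        if self.x1 > self.x2:
            raise ValueError("X1 must not exceed X2")
        if self.x1 < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class PyoverdineStructure:
    strain_id: str
    residues: list[tuple[str, str]]  # (substrate call, 'L' | 'D')
    chromophore: str = CHROMOPHORE_MARKER
    flags: list[str] = field(default_factory=list)

    @property
    def calls(self) -> list[str]:
        return [c for c, _ in self.residues]

    @property
    def chiralities(self) -> list[str]:
        return [x for _, x in self.residues]


# ---------------------------------------------------------------------------


def feature_distance(
    query: ProteinSequence, ref: ProteinSequence, saturation: float = 5.0
) -> float:
    """Jukes-Cantor feature distance; equal-length pairs compare directly,
    unequal pairs are globally aligned first."""
    mode = "aligned" if len(query) == len(ref) else "global_align"
    return aligned_pair_distance(
        query, ref, metric="jukes_cantor", mode=mode, saturation=saturation
    )


def nearest_reference_clusters(
    query: ProteinSequence, refset: ReferenceSet, saturation: float = 5.0
) -> tuple[tuple[float, str], tuple[float, str]]:
    """((X1, substrate), (X2, substrate)) for the two nearest clusters.

    The query-to-cluster distance is the minimum over cluster members; ties
    rank alphabetically by substrate so the output never depends on reference
    order.
    """
    subs = refset.substrates
    if len(subs) < 2:
        raise ValueError("need at least two substrate clusters")
    per_cluster = []
    for sub in subs:
        d = min(
            feature_distance(query, r.amotif45, saturation=saturation)
            for r in refset.cluster_members(sub)
        )
        per_cluster.append((d, sub))
    per_cluster.sort(key=lambda t: (t[0], t[1]))
    return per_cluster[0], per_cluster[1]


def apply_decision_rules(
    x1: float,
    x2: float,
    substrate_a: str,
    substrate_b: str,
    query_id: str = "",
    threshold: float = 0.7,
    rel: float = 0.2,
) -> SubstratePrediction:
    """Map (X1, X2) to exactly one of the four decision rules.

    The relative difference is (X2 - X1) / X2, the gap relative to the
    farther cluster, which stays in [0, 1] and is well defined at X1 = 0.
    """
    if x1 < 0 or x2 < x1:
        raise ValueError("need 0 <= X1 <= X2")
    if x1 >= threshold:
        return SubstratePrediction(
            query_id, x1, x2, substrate_a, substrate_b, "unknown", "3"
        )
    if x2 >= threshold:
        return SubstratePrediction(
            query_id, x1, x2, substrate_a, substrate_b, substrate_a, "1"
        )
    rel_diff = 0.0 if x2 == 0 else (x2 - x1) / x2
    if rel_diff > rel:
        return SubstratePrediction(
            query_id, x1, x2, substrate_a, substrate_b, substrate_a, "2a"
        )
    dual = "|".join(sorted((substrate_a, substrate_b)))
    return SubstratePrediction(
        query_id, x1, x2, substrate_a, substrate_b, dual, "2b"
    )


def predict_substrate(
    query: ProteinSequence,
    refset: ReferenceSet,
    threshold: float = 0.7,
    rel: float = 0.2,
    saturation: float = 5.0,
) -> SubstratePrediction:
    (x1, sub_a), (x2, sub_b) = nearest_reference_clusters(
        query, refset, saturation=saturation
    )
    return apply_decision_rules(
        x1, x2, sub_a, sub_b, query_id=query.id, threshold=threshold, rel=rel
    )


def predict_structure(
    line,
    refset: ReferenceSet,
    threshold: float = 0.7,
    rel: float = 0.2,
) -> tuple[PyoverdineStructure, list[SubstratePrediction]]:
    """Predicted pyoverdine structure of a producer assembly line.

    One residue per Pep module in module order; chirality D where the module
    carries an epimerization domain; flagged A domains yield 'unknown' at
    their position but never abort the structure.
    """
    if line.qc_status != "producer":
        raise ValueError("structures are only predicted for producer lines")
    residues: list[tuple[str, str]] = []
    predictions: list[SubstratePrediction] = []
    flags: list[str] = []
    for m in line.pep_modules:
        if "A" not in m.domains:
            continue
        chirality = "D" if m.is_epimerized else "L"
        if m.a_domain is None or m.a_domain.amotif45 is None or m.a_domain.flagged:
            residues.append(("unknown", chirality))
            flags.append(f"module_{m.ordinal}_flagged")
            continue
        pred = predict_substrate(
            m.a_domain.amotif45, refset, threshold=threshold, rel=rel
        )
        predictions.append(pred)
        residues.append((pred.call, chirality))
    return (
        PyoverdineStructure(strain_id=line.strain_id, residues=residues, flags=flags),
        predictions,
    )


# ---------------------------------------------------------------------------
# validation harness

#: substrate pairs the feature-sequence approach cannot separate
INDISTINGUISHABLE_PAIRS = frozenset({frozenset({"Lys", "Orn"})})


def compare_structures(
    predicted: Sequence[str], observed: Sequence[str]
) -> dict:
    """Per-position comparison of predicted vs observed substrates.

    Counts matches, lysine/ornithine confusions (chemically near-identical
    substrates, reported separately from real errors), 'unknown' calls, and
    true mismatches.  A dual call counts as a match when it contains the
    observed substrate.
    """
    n = min(len(predicted), len(observed))
    overflow = abs(len(predicted) - len(observed))
    counts = {"match": 0, "indistinguishable": 0, "unknown_called": 0, "mismatch": 0}
    details = []
    for i in range(n):
        p, o = predicted[i], observed[i]
        options = set(p.split("|"))
        if o in options:
            cat = "match"
        elif p == "unknown":
            cat = "unknown_called"
        elif any(frozenset({q, o}) in INDISTINGUISHABLE_PAIRS for q in options):
            cat = "indistinguishable"
        else:
            cat = "mismatch"
        counts[cat] += 1
        details.append((i, p, o, cat))
    return {
        "counts": counts,
        "n_compared": n,
        "overflow": overflow,
        "accuracy": counts["match"] / n if n else float("nan"),
        "details": details,
    }


def flag_substrate_outliers(
    refset: ReferenceSet,
    metric: str = "jukes_cantor",
    linkage: str = "ward",
) -> list[tuple[str, str, str]]:
    """References whose label conflicts with their sequence cluster's majority.

    The references are re-clustered from their feature sequences alone (Ward
    on Jukes-Cantor distances, one cluster per distinct substrate); a member
    whose recorded substrate differs from its cluster's majority label is a
    candidate annotation error.
    """
    refs = sorted(refset.references, key=lambda r: r.id)
    m = pairwise_distance_matrix(
        [r.amotif45 for r in refs], metric=metric, mode="global_align"
        if len({len(r.amotif45) for r in refs}) > 1
        else "aligned",
    )
    relabeled = DistanceMatrix([r.id for r in refs], m.values)
    assign = hierarchical_cluster(
        relabeled, linkage=linkage, n_clusters=len(refset.substrates)
    )
    by_id = {r.id: r.substrate for r in refs}
    out: list[tuple[str, str, str]] = []
    for cid in range(assign.n_clusters):
        members = assign.members(cid)
        labels = [by_id[x] for x in members]
        majority = max(sorted(set(labels)), key=labels.count)
        for x in sorted(members):
            if by_id[x] != majority:
                out.append((x, majority, by_id[x]))
    return sorted(out)


# ---------------------------------------------------------------------------
# feature-window selection


def select_feature_window(
    aligned_refs: MultipleAlignment,
    substrates: Sequence[str],
    windows: dict[str, tuple[int, int]],
    metrics: Iterable[str] = ("jukes_cantor", "p"),
    linkages: Iterable[str] = ("ward", "complete", "average", "single"),
) -> dict:
    """Pick the (window, metric, linkage) that best separates substrates.

    Window and metric are chosen by the silhouette index of the
    substrate-labelled partition on the window's distance matrix; the linkage
    is then chosen by how well its tree, cut at the number of substrates,
    reproduces the substrate labels (adjusted Rand index).  Ties resolve in
    listed order.
    """
    from sklearn.metrics import adjusted_rand_score

    if len(set(substrates)) < 2:
        raise ValueError("need at least two substrates represented")
    rows: list[dict] = []
    best = None
    for wname, (start, end) in windows.items():
        sub_aln = aligned_refs.slice_columns(start, end)
        for metric in metrics:
            m = pairwise_distance_matrix(sub_aln.rows, metric=metric, mode="aligned")
            sil = silhouette_index(m, list(substrates))
            rows.append({"window": wname, "metric": metric, "silhouette": sil})
            if best is None or sil > best[0]:
                best = (sil, wname, metric, m)
    sil, wname, metric, m = best
    best_link = None
    for linkage in linkages:
        assign = hierarchical_cluster(
            m, linkage=linkage, n_clusters=len(set(substrates))
        )
        ari = adjusted_rand_score(list(substrates), assign.cluster_ids)
        if best_link is None or ari > best_link[0]:
            best_link = (ari, linkage)
    return {
        "window": wname,
        "metric": metric,
        "linkage": best_link[1],
        "silhouette": sil,
        "ari": best_link[0],
        "scores": pd.DataFrame(rows),
    }
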