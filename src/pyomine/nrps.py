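"""Pyoverdine NRPS assembly-line reconstruction and quality control.

Pyoverdine is built by two biosynthetic gene clusters: Flu (chromophore
synthetase, marked by an N-terminal co-enzyme A ligase) and Pep (peptide
synthetase, terminated by a thioesterase, TE).  Clusters are located by
six-frame translation of the genome — deliberately avoiding gene prediction,
which is unreliable on draft assemblies — followed by a profile-HMM scan for
condensation/adenylation anchors.  Ordering follows the biosynthetic logic:
Flu always precedes Pep, and the TE-bearing cluster closes the line.  A line
within 100 bp of a contig edge that lacks Flu or Pep is dismissed as likely
truncated.

Within each synthetase, modules are delimited by condensation (C) anchors and
the canonical A1-A10 adenylation motifs are located by short-profile scoring;
the substrate-informative Amotif4-5 feature sequence of each A domain spans
from the start of motif A4 to the start of motif A5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from pyomine import phmm as _phmm
from pyomine.seqcore import MultipleAlignment, ProteinSequence

# Short consensus templates anchoring each NRPS motif.  CAL marks the
# co-enzyme A ligase start of the Flu cluster; C delimits modules; A1-A10 are
# the adenylation core motifs; T, E and TE mark thiolation, epimerization and
# chain release.
MOTIF_TEMPLATES: dict[str, str] = {
    "CAL": "WQERNLAVKYW",
    "C": "MHHIISDGWSY",
    "A1": "LTYKELHEQAN",
    "A2": "LKAGGAYVPLD",
    "A3": "LAYTSGSTGKPKG",
    "A4": "FDQSVWEW",
    "A5": "NMYGPTEATVC",
    "A6": "GELHIGGAGVA",
    "A7": "YKTGDLVRWLP",
    "A8": "VKIRGFRIELGE",
    "A9": "KLPDYMVPSAF",
    "A10": "NGKVDRKALPA",
    "T": "DNFFELGGHSLL",
    "E": "SPIQHWFFDLP",
    "TE": "GWSAGGQLAYE",
}

#: canonical motif order inside one module (E and TE optional)
MODULE_MOTIF_ORDER = (
    "C", "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9", "A10", "T", "E", "TE",
)

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = "ACDEFGHIKLMNPQRSTVWY"
_AA_TO_I = {a: i for i, a in enumerate(_ALPHA)}
_B62_CORE = np.array(
    [[float(_B62[a, b]) for b in _ALPHA] for a in _ALPHA]
)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ADomainRecord:
    strain_id: str
    module_ordinal: int
    full_sequence: str
    amotif45: ProteinSequence | None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.amotif45 is not None and self.amotif45.residues not in self.full_sequence:
            raise ValueError("amotif45 must be a substring of the full A domain")


@dataclass
class NRPSModule:
    ordinal: int
    domains: set[str]
    motif_bounds: dict[str, tuple[int, int]]
    a_domain: ADomainRecord | None = None
    is_epimerized: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def incomplete(self) -> bool:
        return bool(self.flags)


@dataclass
class SynthetaseCluster:
    contig_id: str
    start: int  # forward-strand nt coords, 0-based half-open
    end: int
    strand: str
    protein: str
    role: str = "undetermined"  # Flu | Pep | undetermined
    has_TE: bool = False
    has_flu_marker: bool = False
    edge_distance_bp: int = 0
    modules: list[NRPSModule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.edge_distance_bp < 0:
            raise ValueError("edge distance cannot be negative")


@dataclass
class GenomeRecord:
    strain_id: str
    contigs: list[tuple[str, str]]  # (contig id, nucleotide sequence)

    def contig(self, cid: str) -> str:
        for c, s in self.contigs:
            if c == cid:
                return s
        raise KeyError(cid)


@dataclass
class NRPSAssemblyLine:
    strain_id: str
    clusters: list[SynthetaseCluster]
    qc_status: str = "producer"  # producer | non_producer | truncated
    review_flag: str | None = None

    @property
    def modules(self) -> list[NRPSModule]:
        return [m for c in self.clusters for m in c.modules]

    @property
    def pep_modules(self) -> list[NRPSModule]:
        pep = [m for c in self.clusters if c.role == "Pep" for m in c.modules]
        if pep:
            return pep
        # single-cluster genomes: the Flu/Pep boundary is undetermined, use
        # every A-bearing module downstream of the Flu marker
        return [m for c in self.clusters for m in c.modules]

    @property
    def n_a_domains(self) -> int:
        return sum(1 for m in self.modules if "A" in m.domains)

    @property
    def total_length_aa(self) -> int:
        return sum(len(c.protein) for c in self.clusters)


# ---------------------------------------------------------------------------
# motif scanning


def motif_scan(
    protein: str, template: str, min_fraction: float = 0.6
) -> list[tuple[int, float]]:
    """All window positions scoring >= min_fraction of the template self-score.

    Windows are scored by summed BLOSUM62 similarity against the template
    (a short-profile score); overlapping hits are reduced to local maxima.
    """
    w = len(template)
    n = len(protein)
    if n < w:
        return []
    t_idx = np.array([_AA_TO_I[c] for c in template])
    self_score = float(_B62_CORE[t_idx, t_idx].sum())
    seq_idx = np.array([_AA_TO_I.get(c, -1) for c in protein])
    scores_per_pos = np.where(
        seq_idx[None, :] >= 0, _B62_CORE[t_idx[:, None], seq_idx[None, :]], 0.0
    )
    # window score at i = sum_k scores_per_pos[k, i + k]
    windows = np.lib.stride_tricks.sliding_window_view(
        scores_per_pos, w, axis=1
    )  # (w, n-w+1, w)
    win_scores = np.einsum("kik->i", windows)
    threshold = min_fraction * self_score
    hits = [
        (int(i), float(s)) for i, s in enumerate(win_scores) if s >= threshold
    ]
    # keep local maxima among overlapping hits (greedy by score, then position)
    hits.sort(key=lambda h: (-h[1], h[0]))
    kept: list[tuple[int, float]] = []
    for pos, sc in hits:
        if all(abs(pos - kpos) >= w for kpos, _ in kept):
            kept.append((pos, sc))
    kept.sort()
    return kept


def find_motifs(
    protein: str | ProteinSequence, min_fraction: float = 0.6
) -> list[NRPSModule]:
    """Parse a synthetase protein into modules with motif boundaries.

    Modules are delimited by condensation (C) anchors; inside each module the
    remaining motifs are assigned greedily in canonical order, each search
    starting after the end of the previous motif.  A module missing its A4 or
    A5 anchor is flagged incomplete and its A domain is excluded from
    substrate prediction.
    """
    seq = protein.residues if isinstance(protein, ProteinSequence) else protein
    c_hits = motif_scan(seq, MOTIF_TEMPLATES["C"], min_fraction)
    if not c_hits:
        return []
    starts = [pos for pos, _ in c_hits]
    modules: list[NRPSModule] = []
    for ordinal, mstart in enumerate(starts):
        mend = starts[ordinal + 1] if ordinal + 1 < len(starts) else len(seq)
        body = seq[mstart:mend]
        bounds: dict[str, tuple[int, int]] = {}
        cursor = 0
        for name in MODULE_MOTIF_ORDER:
            tmpl = MOTIF_TEMPLATES[name]
            hits = motif_scan(body[cursor:], tmpl, min_fraction)
            if not hits:
                continue
            pos, _ = hits[0]
            start = mstart + cursor + pos
            bounds[name] = (start, start + len(tmpl))
            cursor = cursor + pos + len(tmpl)
        domains = {"C"}
        if all(f"A{k}" in bounds for k in (1, 3, 7, 10)):
            domains.add("A")
        if "T" in bounds:
            domains.add("T")
        if "E" in bounds:
            domains.add("E")
        if "TE" in bounds:
            domains.add("TE")
        flags = []
        a_rec = None
        if "A" in domains:
            if "A4" in bounds and "A5" in bounds:
                a45 = seq[bounds["A4"][0] : bounds["A5"][0]]
                a_rec = ADomainRecord(
                    strain_id="",
                    module_ordinal=ordinal,
                    full_sequence=body,
                    amotif45=ProteinSequence(f"module_{ordinal}", a45),
                )
            else:
                flags.append("missing_A4_or_A5_anchor")
                a_rec = ADomainRecord(
                    strain_id="",
                    module_ordinal=ordinal,
                    full_sequence=body,
                    amotif45=None,
                    flagged=True,
                )
        modules.append(
            NRPSModule(
                ordinal=ordinal,
                domains=domains,
                motif_bounds=bounds,
                a_domain=a_rec,
                is_epimerized="E" in bounds,
                flags=flags,
            )
        )
    return modules


# ---------------------------------------------------------------------------
# cluster location


def _nrps_scan_models() -> list[_phmm.ProfileHMM]:
    """Profile HMMs of the condensation/adenylation anchors used for scanning."""
    models = []
    for name in ("C", "A3", "A8"):
        tmpl = MOTIF_TEMPLATES[name]
        seed = MultipleAlignment(
            [ProteinSequence(f"{name}_{i}", tmpl) for i in range(4)]
        )
        models.append(_phmm.build_phmm(seed, name=f"nrps_{name}"))
    return models


_SCAN_MODELS: list[_phmm.ProfileHMM] | None = None


def _scan_models() -> list[_phmm.ProfileHMM]:
    global _SCAN_MODELS
    if _SCAN_MODELS is None:
        _SCAN_MODELS = _nrps_scan_models()
    return _SCAN_MODELS


def six_frame_segments(
    contig: str, min_len: int = 200
) -> list[tuple[int, int, str, str]]:
    """Stop-free translated segments >= min_len aa from all six frames.

    Returns (start, end, strand, peptide) with nt coordinates on the forward
    strand, 0-based half-open.
    """
    out = []
    L = len(contig)
    rc = str(Seq(contig).reverse_complement())
    for strand, seq in (("+", contig), ("-", rc)):
        for frame in range(3):
            usable = (len(seq) - frame) // 3 * 3
            if usable <= 0:
                continue
            pep = str(Seq(seq[frame : frame + usable]).translate())
            start_aa = 0
            for part in pep.split("*"):
                if len(part) >= min_len:
                    nt_a = frame + 3 * start_aa
                    nt_b = nt_a + 3 * len(part)
                    if strand == "+":
                        out.append((nt_a, nt_b, "+", part))
                    else:
                        out.append((L - nt_b, L - nt_a, "-", part))
                start_aa += len(part) + 1
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def locate_candidate_clusters(
    g: GenomeRecord,
    hints: Sequence[tuple[str, int, int]] | None = None,
    min_segment_aa: int = 200,
    merge_gap_bp: int = 2000,
    scan_gate_bits: float = 12.0,
) -> list[SynthetaseCluster]:
    """Candidate synthetase regions from six-frame translation (or hints).

    A translated segment counts as NRPS-positive when at least two of the
    condensation/adenylation anchor models score above the gate; overlapping
    or near-adjacent positive segments merge into one cluster.
    """
    clusters: list[SynthetaseCluster] = []
    models = _scan_models()
    for contig_id, contig in g.contigs:
        if hints is not None:
            regions = [
                (max(0, s), min(len(contig), e))
                for cid, s, e in hints
                if cid == contig_id
            ]
            segs = six_frame_segments(contig, min_len=min_segment_aa)
            for rs, re_ in regions:
                inside = [
                    seg for seg in segs if seg[0] >= rs - 10 and seg[1] <= re_ + 10
                ]
                if not inside:
                    continue
                best = max(inside, key=lambda t: len(t[3]))
                clusters.append(
                    _make_cluster(contig_id, contig, rs, re_, best[2], best[3])
                )
            continue
        positive = []
        for seg in six_frame_segments(contig, min_len=min_segment_aa):
            s, e, strand, pep = seg
            hits = _phmm.scan_domains(ProteinSequence("seg", pep), models)
            n_pass = sum(1 for h in hits if h.score > scan_gate_bits)
            if n_pass >= 2:
                positive.append(seg)
        # merge near-adjacent positive segments into clusters
        merged: list[list] = []
        for seg in positive:
            if merged and seg[0] - merged[-1][1] <= merge_gap_bp:
                merged[-1][1] = max(merged[-1][1], seg[1])
                merged[-1][3].append(seg)
            else:
                merged.append([seg[0], seg[1], seg[2], [seg]])
        for mstart, mend, strand, segs in merged:
            ordered = sorted(segs, key=lambda t: t[0], reverse=(strand == "-"))
            protein = "".join(t[3] for t in ordered)
            clusters.append(
                _make_cluster(contig_id, contig, mstart, mend, strand, protein)
            )
    return clusters


def _make_cluster(
    contig_id: str, contig: str, start: int, end: int, strand: str, protein: str
) -> SynthetaseCluster:
    edge = min(start, len(contig) - end)
    has_te = bool(motif_scan(protein, MOTIF_TEMPLATES["TE"]))
    has_cal = bool(motif_scan(protein, MOTIF_TEMPLATES["CAL"]))
    return SynthetaseCluster(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        protein=protein,
        has_TE=has_te,
        has_flu_marker=has_cal,
        edge_distance_bp=edge,
    )


# ---------------------------------------------------------------------------
# ordering and QC


def order_clusters(
    clusters: list[SynthetaseCluster],
) -> tuple[list[SynthetaseCluster], str | None]:
    """Assign Flu/Pep roles and biosynthetic order.

    Flu always precedes Pep; the TE-bearing cluster goes last.  With three
    clusters the non-Flu, non-TE cluster sits in the middle.  More than three
    clusters is outside the described biology and is flagged for manual
    review rather than silently ordered.
    """
    if len(clusters) > 3:
        return clusters, "more_than_three_clusters"
    if len(clusters) == 1:
        c = clusters[0]
        c.role = "undetermined"
        return [c], None
    flu = [c for c in clusters if c.has_flu_marker and not c.has_TE]
    te = [c for c in clusters if c.has_TE and c not in flu]
    rest = [c for c in clusters if c not in flu and c not in te]
    ordered: list[SynthetaseCluster] = []
    if flu:
        flu.sort(key=lambda c: (c.contig_id, c.start))
        for c in flu:
            c.role = "Flu"
        ordered.extend(flu)
    rest.sort(key=lambda c: (c.contig_id, c.start))
    for c in rest:
        c.role = "Flu" if not flu and not ordered else "Pep"
        ordered.append(c)
    te.sort(key=lambda c: (c.contig_id, c.start))
    for c in te:
        c.role = "Pep"
        ordered.append(c)
    if not ordered:
        ordered = clusters
    return ordered, None


def truncation_filter(
    clusters: list[SynthetaseCluster],
    g: GenomeRecord,
    edge_bp: int = 100,
) -> str:
    """QC verdict: producer, non_producer, or truncated.

    A line is dismissed as truncated only when a cluster sits within
    ``edge_bp`` of a contig edge AND the line lacks Flu or Pep — the
    conjunction guards against discarding complete lines that merely sit
    near an edge.
    """
    if not clusters:
        return "non_producer"
    has_flu = any(c.has_flu_marker for c in clusters)
    has_pep = any(c.has_TE for c in clusters)
    near_edge = any(c.edge_distance_bp < edge_bp for c in clusters)
    if near_edge and (not has_flu or not has_pep):
        return "truncated"
    if not has_flu or not has_pep:
        return "truncated"
    return "producer"


def build_assembly_line(
    g: GenomeRecord,
    hints: Sequence[tuple[str, int, int]] | None = None,
    edge_bp: int = 100,
) -> NRPSAssemblyLine:
    """Locate, order, QC and motif-parse the full assembly line of a genome."""
    clusters = locate_candidate_clusters(g, hints=hints)
    ordered, review = order_clusters(clusters)
    status = truncation_filter(ordered, g, edge_bp=edge_bp)
    if status == "producer":
        for c in ordered:
            c.modules = find_motifs(c.protein)
            for m in c.modules:
                if m.a_domain is not None:
                    m.a_domain.strain_id = g.strain_id
    return NRPSAssemblyLine(
        strain_id=g.strain_id, clusters=ordered, qc_status=status, review_flag=review
    )


def extract_a_domains(line: NRPSAssemblyLine) -> list[ADomainRecord]:
    """One record per A domain of a producer line, in module order."""
    if line.qc_status != "producer":
        raise ValueError("A domains are only extracted from producer lines")
    records = []
    for ordinal, m in enumerate(line.modules):
        if "A" not in m.domains or m.a_domain is None:
            continue
        rec = m.a_domain
        rec.strain_id = line.strain_id
        rec.module_ordinal = ordinal
        records.append(rec)
    return records


def assembly_stats(lines: Iterable[NRPSAssemblyLine]):
    """Per-strain table of synthetase length (aa) and A-domain count."""
    import pandas as pd

    rows = [
        {
            "strain": l.strain_id,
            "length_aa": l.total_length_aa,
            "n_a_domains": l.n_a_domains,
        }
        for l in lines
        if l.qc_status == "producer"
    ]
    return pd.DataFrame(rows, columns=["strain", "length_aa", "n_a_domains"])
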