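"""Synthetic fixtures: genomes, reference tables and ground truth.

The generator emulates the inputs of the real study at desk scale so that
every pipeline stage is testable without downloads:

* a substrate-labelled A-domain reference table (101 references across the
  13 experimentally confirmed substrates plus the two derivative labels,
  mirroring the published reference inventory), where each substrate owns a
  distinctive Amotif4-5 feature signature;
* a 35-sequence receptor reference panel (21 FpvA / 6 FpvB / 8 other
  TonB-dependent siderophore receptors, 809 aa each) laid out with fully
  conserved anchor columns flanking the discriminative R1/R2 regions and the
  four group-feature regions near the Plug domain, plus per-domain seed
  alignments for the STN/Plug/TonB profile HMMs;
* nucleotide genomes embedding complete Flu+Pep NRPS assembly lines built
  from the motif templates (with planted substrates and chirality), receptor
  genes at controlled distances from the Pep cluster, edge-truncation and
  non-producer cases;
* a ground-truth JSON recording every planted fact.

What the fixtures deliberately do not model: insertions/deletions within
feature regions, tailoring enzymes, real codon usage, and phylogenetic
autocorrelation of noise — see the methods note for the consequences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from pyomine import nrps as _nrps
from pyomine.seqcore import AMINO_ACIDS, MultipleAlignment, ProteinSequence, write_fasta
from pyomine.substrates import DEFAULT_SUBSTRATES

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_STOP = "TAA"

FEATURE_TAIL_LEN = 47  # Amotif4-5 = A4 anchor + substrate-specific tail


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; same spec + seed => same bytes."""

    n_strains: int = 5
    flu_modules: int = 2
    pep_module_range: tuple[int, int] = (4, 6)
    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES
    mutation_rate: float = 0.0  # point-mutation rate on planted instances
    truncation_fraction: float = 0.2
    nonproducer_fraction: float = 0.2
    three_cluster_fraction: float = 0.25
    epimerization_probability: float = 0.4
    n_adomain_refs: int = 101
    n_sources: int = 13
    reference_noise: float = 0.05
    n_receptor_groups: int = 5
    extra_fpva_fraction: float = 0.4
    seed: int = 1


# ---------------------------------------------------------------------------
# low-level helpers


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# A-domain references


def make_substrate_signatures(
    rng: np.random.Generator, substrates=DEFAULT_SUBSTRATES
) -> dict[str, str]:
    """One Amotif4-5 feature signature per substrate: the A4 anchor motif
    followed by a substrate-specific tail."""
    a4 = _nrps.MOTIF_TEMPLATES["A4"]
    return {sub: a4 + _rand_aa(rng, FEATURE_TAIL_LEN) for sub in substrates}


def make_adomain_references(
    rng: np.random.Generator, spec: FixtureSpec, signatures: dict[str, str]
) -> list[dict]:
    """Reference rows (id, substrate, amotif45_sequence, source).

    References carry small within-substrate variation around each signature;
    sources cycle through the known donor pyoverdines.
    """
    subs = list(spec.substrates)
    counts = {s: spec.n_adomain_refs // len(subs) for s in subs}
    for s in subs[: spec.n_adomain_refs % len(subs)]:
        counts[s] += 1
    rows = []
    k = 0
    for sub in subs:
        for _ in range(counts[sub]):
            k += 1
            rows.append(
                {
                    "id": f"ref{k:03d}",
                    "substrate": sub,
                    "amotif45_sequence": mutate_protein(
                        rng, signatures[sub], spec.reference_noise
                    ),
                    "source": f"PVD{(k - 1) % spec.n_sources + 1:02d}",
                }
            )
    return rows


def make_feature_window_fixture(
    rng: np.random.Generator,
    spec: FixtureSpec,
    signatures: dict[str, str],
    full_len: int = 200,
    window: tuple[int, int] = (80, 135),
) -> tuple[MultipleAlignment, list[str], dict[str, tuple[int, int]]]:
    """Full-length reference A domains where only a planted sub-window is
    substrate-informative.

    Outside the window, each reference carries its source lineage's scaffold,
    so full-sequence distances reflect phylogeny rather than substrate — the
    situation that motivates feature-window selection in the first place.
    """
    sig_len = len(next(iter(signatures.values())))
    if window[1] - window[0] != sig_len:
        raise ValueError("window width must equal the signature length")
    scaffolds = [_rand_aa(rng, full_len) for _ in range(spec.n_sources)]
    refs = make_adomain_references(rng, spec, signatures)
    rows, labels = [], []
    for r in refs:
        src = int(r["source"][3:]) - 1
        base = list(mutate_protein(rng, scaffolds[src], spec.reference_noise))
        base[window[0] : window[1]] = list(r["amotif45_sequence"])
        rows.append(ProteinSequence(r["id"], "".join(base)))
        labels.append(r["substrate"])
    windows = {
        "full": (0, full_len),
        "amotif3-6": (max(0, window[0] - 25), min(full_len, window[1] + 25)),
        "amotif4-5": window,
    }
    return MultipleAlignment(rows), labels, windows


# ---------------------------------------------------------------------------
# synthetase construction


def _linker(rng: np.random.Generator, n: int = 8) -> str:
    return _rand_aa(rng, n)


def build_module(
    rng: np.random.Generator,
    feature: str,
    epimerized: bool,
    terminal: bool,
) -> str:
    """One NRPS module: C + A1..A3 + [feature = A4..] + A5..A10 + T (+E) (+TE)."""
    t = _nrps.MOTIF_TEMPLATES
    parts = [t["C"], _linker(rng), t["A1"], _linker(rng), t["A2"], _linker(rng),
             t["A3"], _linker(rng), feature, t["A5"], _linker(rng), t["A6"],
             _linker(rng), t["A7"], _linker(rng), t["A8"], _linker(rng), t["A9"],
             _linker(rng), t["A10"], _linker(rng), t["T"]]
    if epimerized:
        parts += [_linker(rng), t["E"]]
    if terminal:
        parts += [_linker(rng), t["TE"]]
    return "".join(parts)


def build_flu_protein(rng: np.random.Generator, spec: FixtureSpec,
                      signatures: dict[str, str]) -> str:
    subs = list(spec.substrates)
    parts = [_nrps.MOTIF_TEMPLATES["CAL"], _linker(rng)]
    for _ in range(spec.flu_modules):
        sub = subs[rng.integers(len(subs))]
        feature = mutate_protein(rng, signatures[sub], spec.mutation_rate)
        parts.append(build_module(rng, feature, epimerized=False, terminal=False))
    return "".join(parts)


def build_pep_protein(
    rng: np.random.Generator,
    spec: FixtureSpec,
    signatures: dict[str, str],
    n_modules: int,
) -> tuple[str, list[dict]]:
    """Pep synthetase plus per-module ground truth (substrate, chirality,
    planted amotif45)."""
    return _build_pep_part(rng, spec, signatures, n_modules, terminal=True)


# ---------------------------------------------------------------------------
# receptor scaffold

RECEPTOR_LEN = 809
_DOMAIN_BLOCKS = {"STN": (10, 50), "Plug": (100, 180), "TonB": (510, 660)}
_R2_REGION = (59, 86)
_R1_REGION = (258, 309)
_GROUP_REGIONS = ((340, 372), (380, 412), (420, 452), (460, 492))
_BOUNDARY_ANCHORS = (
    58, 86, 257, 309, 339, 372, 379, 412, 419, 452, 459, 492,
)


def _anchor_columns() -> list[int]:
    """Exactly ceil(0.10 * 809) = 81 fully conserved anchor columns."""
    import math

    k = math.ceil(0.10 * RECEPTOR_LEN)
    forbidden = set(_BOUNDARY_ANCHORS)
    for a, b in (_R2_REGION, _R1_REGION, *_GROUP_REGIONS):
        forbidden.update(range(a, b))
    anchors = list(_BOUNDARY_ANCHORS)
    for pos in range(2, RECEPTOR_LEN, 7):
        if len(anchors) == k:
            break
        if pos not in forbidden:
            anchors.append(pos)
            forbidden.add(pos)
    if len(anchors) != k:
        raise RuntimeError("anchor layout under-filled")
    return sorted(anchors)


@dataclass
class ReceptorScaffold:
    """Templates from which every reference and planted receptor is composed."""

    anchors: list[int]
    anchor_residues: dict[int, str]
    domain_templates: dict[str, str]
    class_templates: dict[str, dict[str, str]]  # class -> {R1, R2}
    group_templates: list[str]  # per-group concatenated G-region content
    linker_cols: list[int]
    linker_template: str  # shared scaffold outside domains/regions/anchors

    @property
    def group_cols(self) -> list[int]:
        return [j for a, b in _GROUP_REGIONS for j in range(a, b)]


def make_receptor_scaffold(
    rng: np.random.Generator, n_groups: int
) -> ReceptorScaffold:
    anchors = _anchor_columns()
    anchor_res = {j: _rand_aa(rng, 1) for j in anchors}
    domain_templates = {
        name: _rand_aa(rng, b - a) for name, (a, b) in _DOMAIN_BLOCKS.items()
    }
    r1_len = _R1_REGION[1] - _R1_REGION[0]
    r2_len = _R2_REGION[1] - _R2_REGION[0]
    fpva_r1 = _rand_aa(rng, r1_len)
    covered = set(anchors)
    for a, b in _DOMAIN_BLOCKS.values():
        covered.update(range(a, b))
    for a, b in (_R2_REGION, _R1_REGION, *_GROUP_REGIONS):
        covered.update(range(a, b))
    linker_cols = [j for j in range(RECEPTOR_LEN) if j not in covered]
    linker_template = _rand_aa(rng, len(linker_cols))
    class_templates = {
        "FpvA": {
            "R1": fpva_r1,
            "R2": _rand_aa(rng, r2_len),
        },
        "FpvB": {
            # FpvB shares the Fpv R1 signature (diverged), but has its own R2
            "R1": mutate_protein(rng, fpva_r1, 0.10),
            "R2": _rand_aa(rng, r2_len),
        },
        "other": {
            "R1": _rand_aa(rng, r1_len),
            "R2": _rand_aa(rng, r2_len),
        },
    }
    n_gcols = sum(b - a for a, b in _GROUP_REGIONS)
    group_templates = [_rand_aa(rng, n_gcols) for _ in range(n_groups)]
    return ReceptorScaffold(
        anchors=anchors,
        anchor_residues=anchor_res,
        domain_templates=domain_templates,
        class_templates=class_templates,
        group_templates=group_templates,
        linker_cols=linker_cols,
        linker_template=linker_template,
    )


def compose_receptor(
    rng: np.random.Generator,
    scaffold: ReceptorScaffold,
    receptor_class: str,
    group: int | None,
    noise: float,
    r1_noise: float | None = None,
    r2_noise: float | None = None,
) -> str:
    """One receptor sequence of length 809 from the scaffold templates.

    `r1_noise`/`r2_noise` override the within-class variation of the R1/R2
    regions (the reference panel shows R1 more class-conserved than R2);
    they default to the overall noise rate.
    """
    seq = list(_rand_aa(rng, RECEPTOR_LEN))
    tpl = scaffold.class_templates[receptor_class]
    for name, (a, b) in _DOMAIN_BLOCKS.items():
        seq[a:b] = scaffold.domain_templates[name]
    for j, ch in zip(scaffold.linker_cols, scaffold.linker_template):
        seq[j] = ch
    if receptor_class == "FpvA" and group is not None:
        gcontent = scaffold.group_templates[group]
        for j, ch in zip(scaffold.group_cols, gcontent):
            seq[j] = ch
    else:
        for j in scaffold.group_cols:
            seq[j] = _rand_aa(rng, 1)
    out = list(mutate_protein(rng, "".join(seq), noise))
    out[_R1_REGION[0] : _R1_REGION[1]] = mutate_protein(
        rng, tpl["R1"], noise if r1_noise is None else r1_noise
    )
    out[_R2_REGION[0] : _R2_REGION[1]] = mutate_protein(
        rng, tpl["R2"], noise if r2_noise is None else r2_noise
    )
    # anchor columns are invariant by construction, even under noise
    for j in scaffold.anchors:
        out[j] = scaffold.anchor_residues[j]
    return "".join(out)


def make_receptor_references(
    rng: np.random.Generator, spec: FixtureSpec, scaffold: ReceptorScaffold
) -> list[dict]:
    """The 21 FpvA / 6 FpvB / 8 other reference receptors, with group labels
    for the FpvA rows.  Non-anchor columns are guaranteed non-unanimous so
    the conserved-site discovery recovers exactly the anchor layout."""
    rows = []
    group_sizes = [5, 4, 4, 4, 4][: spec.n_receptor_groups]
    while len(group_sizes) < spec.n_receptor_groups:
        group_sizes.append(0)
    # R1 is more class-conserved than R2 across the panel, mirroring the
    # empirical ordering of the two identification-score peaks
    r1_noise = 0.6 * spec.reference_noise
    r2_noise = 1.6 * spec.reference_noise
    k = 0
    for g, size in enumerate(group_sizes):
        for _ in range(size):
            k += 1
            rows.append(
                {
                    "id": f"FpvA_ref{k:02d}",
                    "class": "FpvA",
                    "group": g,
                    "sequence": compose_receptor(
                        rng, scaffold, "FpvA", g, spec.reference_noise,
                        r1_noise=r1_noise, r2_noise=r2_noise,
                    ),
                }
            )
    for i in range(6):
        rows.append(
            {
                "id": f"FpvB_ref{i + 1:02d}",
                "class": "FpvB",
                "group": None,
                "sequence": compose_receptor(
                    rng, scaffold, "FpvB", None, spec.reference_noise,
                    r1_noise=r1_noise, r2_noise=r2_noise,
                ),
            }
        )
    for i in range(8):
        rows.append(
            {
                "id": f"other_ref{i + 1:02d}",
                "class": "other",
                "group": None,
                "sequence": compose_receptor(
                    rng, scaffold, "other", None, spec.reference_noise,
                    r1_noise=r1_noise, r2_noise=r2_noise,
                ),
            }
        )
    _demote_unanimous_columns(rows, scaffold)
    return rows


def _demote_unanimous_columns(rows: list[dict], scaffold: ReceptorScaffold) -> None:
    """Force every non-anchor column of the reference panel to vary.

    Shared domain blocks can end up unanimous by chance; two designated rows
    get a deterministic substitution there so that the fully conserved
    columns are exactly the designed anchors.
    """
    anchors = set(scaffold.anchors)
    seqs = [list(r["sequence"]) for r in rows]
    for j in range(RECEPTOR_LEN):
        if j in anchors:
            continue
        col = {s[j] for s in seqs}
        if len(col) == 1:
            base = seqs[0][j]
            i1 = AMINO_ACIDS.index(base)
            seqs[1][j] = AMINO_ACIDS[(i1 + 1) % 20]
            seqs[len(seqs) // 2][j] = AMINO_ACIDS[(i1 + 2) % 20]
    for r, s in zip(rows, seqs):
        r["sequence"] = "".join(s)


def make_domain_seed_alignments(
    rng: np.random.Generator, scaffold: ReceptorScaffold, n_rows: int = 6,
    noise: float = 0.05,
) -> dict[str, MultipleAlignment]:
    """Per-domain seed alignments for the STN/Plug/TonB profile HMMs."""
    out = {}
    for name, tpl in scaffold.domain_templates.items():
        rows = [
            ProteinSequence(f"{name}_seed{i + 1}", mutate_protein(rng, tpl, noise))
            for i in range(n_rows)
        ]
        out[name] = MultipleAlignment(rows)
    return out


# ---------------------------------------------------------------------------
# genome assembly


class _ContigBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0

    def add_dna(self, seq: str) -> None:
        self.parts.append(seq)
        self.length += len(seq)

    def add_gene(self, protein: str) -> tuple[int, int]:
        """Insert stop + CDS + stop; returns CDS nt coords (0-based half-open)."""
        self.add_dna(_STOP)
        start = self.length
        self.add_dna(reverse_translate(protein))
        end = self.length
        self.add_dna(_STOP)
        return start, end

    def sequence(self) -> str:
        return "".join(self.parts)


@dataclass
class Fixtures:
    spec: FixtureSpec
    genomes: list  # list[_nrps.GenomeRecord]
    adomain_refs: list[dict]
    receptor_refs: list[dict]
    domain_seeds: dict[str, MultipleAlignment]
    scaffold: ReceptorScaffold
    signatures: dict[str, str]
    phylo_identity: dict[str, dict[str, float]]
    clades: dict[str, str]
    ground_truth: dict

    def write(self, outdir) -> dict[str, str]:
        """Write every artifact as text; returns SHA-256 of each file."""
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        import pandas as pd

        for g in self.genomes:
            with open(outdir / "genomes" / f"{g.strain_id}.fasta", "w") as fh:
                for cid, seq in g.contigs:
                    fh.write(f">{cid}\n")
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")
        pd.DataFrame(self.adomain_refs)[
            ["id", "substrate", "amotif45_sequence", "source"]
        ].to_csv(outdir / "ref_adomains.tsv", sep="\t", index=False)
        write_fasta(
            [ProteinSequence(r["id"], r["sequence"]) for r in self.receptor_refs],
            outdir / "ref_receptors.fasta",
        )
        pd.DataFrame(
            [
                {
                    "id": r["id"],
                    "class": r["class"],
                    "group": "" if r["group"] is None else r["group"],
                }
                for r in self.receptor_refs
            ]
        ).to_csv(outdir / "ref_receptors.tsv", sep="\t", index=False)
        for name, aln in self.domain_seeds.items():
            write_fasta(aln.rows, outdir / f"seed_{name}.fasta")
        strains = sorted(self.phylo_identity)
        pd.DataFrame(
            [[self.phylo_identity[a][b] for b in strains] for a in strains],
            index=strains,
            columns=strains,
        ).to_csv(outdir / "phylo_identity.tsv", sep="\t")
        pd.DataFrame(
            sorted(self.clades.items()), columns=["strain", "clade"]
        ).to_csv(outdir / "clades.tsv", sep="\t", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        digests = {}
        for p in sorted(outdir.rglob("*")):
            if p.is_file():
                digests[str(p.relative_to(outdir))] = hashlib.sha256(
                    p.read_bytes()
                ).hexdigest()
        return digests


def generate_fixtures(spec: FixtureSpec) -> Fixtures:
    """Deterministically build the full fixture bundle for a spec."""
    rng = np.random.default_rng(spec.seed)
    signatures = make_substrate_signatures(rng, spec.substrates)
    adomain_refs = make_adomain_references(rng, spec, signatures)
    scaffold = make_receptor_scaffold(rng, spec.n_receptor_groups)
    receptor_refs = make_receptor_references(rng, spec, scaffold)
    domain_seeds = make_domain_seed_alignments(rng, scaffold)

    n = spec.n_strains
    n_trunc = round(spec.truncation_fraction * n)
    n_nonprod = round(spec.nonproducer_fraction * n)
    statuses = (
        ["producer"] * (n - n_trunc - n_nonprod)
        + ["truncated"] * n_trunc
        + ["non_producer"] * n_nonprod
    )
    genomes = []
    truth_strains = {}
    group_truth: dict[str, int] = {}
    feature_blocks: dict[str, str] = {}
    producer_idx = 0
    for i in range(n):
        sid = f"S{i + 1:02d}"
        status = statuses[i]
        g, st_truth = _build_strain(
            rng, spec, sid, status, signatures, scaffold,
            three_cluster=(status == "producer" and producer_idx == 1),
            with_rejects=(status == "producer" and producer_idx == 0),
        )
        if status == "producer":
            producer_idx += 1
        genomes.append(g)
        truth_strains[sid] = st_truth
        for r in st_truth["receptors"]:
            if r["class"] == "FpvA":
                group_truth[r["id"]] = r["group"]
                feature_blocks[r["id"]] = r["feature_blocks"]

    strains = [g.strain_id for g in genomes]
    phylo = {a: {} for a in strains}
    for ai, a in enumerate(strains):
        for bi, b in enumerate(strains):
            if ai == bi:
                phylo[a][b] = 100.0
            elif ai < bi:
                phylo[a][b] = float(np.round(70 + 20 * rng.random(), 2))
            else:
                phylo[a][b] = phylo[b][a]
    clades = {s: ("cladeA" if i % 2 == 0 else "cladeB") for i, s in enumerate(strains)}

    ground_truth = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
        },
        "strains": truth_strains,
        "receptor_groups": group_truth,
        "feature_blocks": feature_blocks,
        "reference": {
            "n_adomain_refs": len(adomain_refs),
            "substrates": sorted({r["substrate"] for r in adomain_refs}),
            "receptor_composition": {
                "FpvA": sum(1 for r in receptor_refs if r["class"] == "FpvA"),
                "FpvB": sum(1 for r in receptor_refs if r["class"] == "FpvB"),
                "other": sum(1 for r in receptor_refs if r["class"] == "other"),
            },
            "receptor_mean_length": float(
                np.mean([len(r["sequence"]) for r in receptor_refs])
            ),
        },
    }
    return Fixtures(
        spec=spec,
        genomes=genomes,
        adomain_refs=adomain_refs,
        receptor_refs=receptor_refs,
        domain_seeds=domain_seeds,
        scaffold=scaffold,
        signatures=signatures,
        phylo_identity=phylo,
        clades=clades,
        ground_truth=ground_truth,
    )


def _feature_blocks_of(seq: str, scaffold: ReceptorScaffold) -> str:
    return "".join(seq[a:b] for a, b in _GROUP_REGIONS)


def _build_strain(
    rng: np.random.Generator,
    spec: FixtureSpec,
    sid: str,
    status: str,
    signatures: dict[str, str],
    scaffold: ReceptorScaffold,
    three_cluster: bool,
    with_rejects: bool,
):
    cb = _ContigBuilder()
    contig_id = f"{sid}_c1"
    clusters_truth = []
    receptors_truth = []
    pep_truth: list[dict] = []
    pep_coords = None

    cb.add_dna(_rand_dna(rng, int(rng.integers(1200, 2000))))
    if status == "producer":
        flu = build_flu_protein(rng, spec, signatures)
        fs, fe = cb.add_gene(flu)
        clusters_truth.append(
            {"contig": contig_id, "start": fs, "end": fe, "role": "Flu",
             "has_TE": False, "length_aa": len(flu)}
        )
        cb.add_dna(_rand_dna(rng, int(rng.integers(3000, 5000))))
        n_mod = int(rng.integers(spec.pep_module_range[0], spec.pep_module_range[1] + 1))
        if three_cluster:
            n_a = max(1, n_mod // 2)
            p1, t1 = _build_pep_part(rng, spec, signatures, n_a, terminal=False)
            p2, t2 = _build_pep_part(rng, spec, signatures, n_mod - n_a, terminal=True)
            s1, e1 = cb.add_gene(p1)
            cb.add_dna(_rand_dna(rng, int(rng.integers(3000, 5000))))
            s2, e2 = cb.add_gene(p2)
            clusters_truth.append(
                {"contig": contig_id, "start": s1, "end": e1, "role": "Pep",
                 "has_TE": False, "length_aa": len(p1)}
            )
            clusters_truth.append(
                {"contig": contig_id, "start": s2, "end": e2, "role": "Pep",
                 "has_TE": True, "length_aa": len(p2)}
            )
            pep_truth = t1 + t2
            pep_coords = (contig_id, s1, e2)
        else:
            pep, pep_truth = build_pep_protein(rng, spec, signatures, n_mod)
            ps, pe = cb.add_gene(pep)
            clusters_truth.append(
                {"contig": contig_id, "start": ps, "end": pe, "role": "Pep",
                 "has_TE": True, "length_aa": len(pep)}
            )
            pep_coords = (contig_id, ps, pe)
    elif status == "truncated":
        # TE-bearing cluster near the contig edge, Flu absent
        pep, _ = build_pep_protein(
            rng, spec, signatures, int(rng.integers(*spec.pep_module_range))
        )
        ps, pe = cb.add_gene(pep)
        clusters_truth.append(
            {"contig": contig_id, "start": ps, "end": pe, "role": "Pep",
             "has_TE": True, "length_aa": len(pep)}
        )

    # receptors
    def plant_receptor(kind: str, group: int | None, gap: int, note: str = ""):
        cb.add_dna(_rand_dna(rng, gap))
        protein = compose_receptor(rng, scaffold, kind if kind != "other" else "other",
                                   group, spec.mutation_rate)
        if note == "short":
            protein = protein[:740]
        elif note == "corrupt_plug":
            a, b = _DOMAIN_BLOCKS["Plug"]
            protein = protein[:a] + _rand_aa(rng, b - a) + protein[b:]
        rs, re_ = cb.add_gene(protein)
        rid = f"{sid}_r{len(receptors_truth) + 1}"
        rec = {
            "id": rid, "contig": contig_id, "start": rs, "end": re_,
            "class": kind if not note else "rejected",
            "group": group, "length": len(protein), "note": note,
        }
        if pep_coords is not None:
            pc, pstart, pend = pep_coords
            d = max(0, pstart - re_) if re_ <= pstart else max(0, rs - pend)
            rec["dist_to_pep"] = int(d)
            rec["proximate"] = bool(d <= 20000)
        else:
            rec["dist_to_pep"] = None
            rec["proximate"] = False
        if kind == "FpvA" and not note:
            rec["feature_blocks"] = _feature_blocks_of(protein, scaffold)
        receptors_truth.append(rec)

    if status != "truncated":
        if status == "producer":
            g1 = int(rng.integers(spec.n_receptor_groups))
            plant_receptor("FpvA", g1, int(rng.integers(4000, 12000)))
            if rng.random() < spec.extra_fpva_fraction:
                g2 = int((g1 + 1 + rng.integers(spec.n_receptor_groups - 1))
                         % spec.n_receptor_groups)
                plant_receptor("FpvA", g2, int(rng.integers(1000, 4000)))
            plant_receptor("FpvB", None, int(rng.integers(22000, 26000)))
            plant_receptor("other", None, int(rng.integers(3000, 6000)))
            if with_rejects:
                plant_receptor("FpvA", 0, 2000, note="short")
                plant_receptor("FpvA", 0, 2000, note="corrupt_plug")
        else:
            plant_receptor("other", None, int(rng.integers(3000, 6000)))

    if status == "truncated":
        cb.add_dna(_rand_dna(rng, 50))  # cluster ends within 100 bp of the edge
    else:
        cb.add_dna(_rand_dna(rng, int(rng.integers(1200, 2000))))

    contigs = [(contig_id, cb.sequence())]
    if status == "producer":
        contigs.append((f"{sid}_c2", _rand_dna(rng, int(rng.integers(2000, 4000)))))

    qc = {"producer": "producer", "truncated": "truncated",
          "non_producer": "non_producer"}[status]
    truth = {
        "qc_status": qc,
        "clusters": clusters_truth,
        "n_clusters": len(clusters_truth),
        "pep_modules": pep_truth,
        "structure": [(m["substrate"], m["chirality"]) for m in pep_truth],
        "n_pep_a_domains": len(pep_truth),
        "receptors": receptors_truth,
    }
    return _nrps.GenomeRecord(sid, contigs), truth


def _build_pep_part(rng, spec, signatures, n_modules, terminal):
    subs = list(spec.substrates)
    parts, truth = [], []
    for i in range(n_modules):
        sub = subs[rng.integers(len(subs))]
        feature = mutate_protein(rng, signatures[sub], spec.mutation_rate)
        epim = bool(rng.random() < spec.epimerization_probability)
        is_last = terminal and i == n_modules - 1
        parts.append(build_module(rng, feature, epimerized=epim, terminal=is_last))
        truth.append({"substrate": sub, "chirality": "D" if epim else "L",
                      "amotif45": feature})
    return "".join(parts), truth
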