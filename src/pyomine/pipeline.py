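"""End-to-end orchestration: mine -> QC -> predict -> receptors -> group.

The pipeline consumes genome FASTA plus the two reference tables (substrate-
labelled A domains; class-labelled receptor panel with domain seed
alignments) and emits per-strain QC verdicts, substrate predictions and
pyoverdine structures, receptor classifications with R1/R2 scores, feature-
sequence groups, Pep-proximity and per-clade diversity.  Every gate decision
is logged; per-genome failures are isolated so one broken assembly never
aborts a batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pyomine import nrps as _nrps
from pyomine import phmm as _phmm
from pyomine import receptors as _rec
from pyomine import substrates as _sub
from pyomine.config import PipelineConfig
from pyomine.seqcore import (
    MultipleAlignment,
    ProteinSequence,
    conservation_profile,
    global_align,
    p_distance,
    partition_variable_regions,
    read_fasta,
)


@dataclass
class StrainManifest:
    strain_id: str
    qc_status: str
    producer: bool
    representative: bool = True
    redundancy_cluster: int | None = None


# ---------------------------------------------------------------------------
# dereplication


def dereplicate(
    strain_info: dict[str, dict],
    phylo_identity: dict[str, dict[str, float]],
    synthetase_identity: dict[tuple[str, str], float] | None = None,
    cut: float = 95.0,
) -> list[StrainManifest]:
    """One representative per redundancy cluster.

    Non-producers cluster on phylogenetic identity alone; producers require
    BOTH phylogenetic and synthetase identity above the cut.  The
    representative is the most integrative genome: fewest contigs, ties by
    longest assembly, then lexicographic id.
    """
    strains = sorted(strain_info)
    for a in strains:
        if a not in phylo_identity:
            raise KeyError(f"missing phylogenetic distances for {a!r}")
    synthetase_identity = synthetase_identity or {}

    def linked(a: str, b: str) -> bool:
        pa, pb = strain_info[a]["producer"], strain_info[b]["producer"]
        if pa != pb:
            return False
        if phylo_identity[a][b] <= cut:
            return False
        if pa:  # producers additionally need synthetase similarity
            s = synthetase_identity.get((a, b), synthetase_identity.get((b, a)))
            if s is None or s <= cut:
                return False
        return True

    # transitive closure
    cluster_of = {a: i for i, a in enumerate(strains)}

    def find(x):
        while cluster_of[x] != cluster_of[strains[cluster_of[x]]]:
            cluster_of[x] = cluster_of[strains[cluster_of[x]]]
        return cluster_of[x]

    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            if linked(a, b):
                ra, rb = find(a), find(b)
                if ra != rb:
                    cluster_of[strains[max(ra, rb)]] = min(ra, rb)
    roots = {a: find(a) for a in strains}
    remap: dict[int, int] = {}
    manifests = []
    by_root: dict[int, list[str]] = {}
    for a in strains:
        by_root.setdefault(roots[a], []).append(a)
    for root in sorted(by_root):
        cid = remap.setdefault(root, len(remap))
        members = by_root[root]
        rep = min(
            members,
            key=lambda s: (
                strain_info[s].get("n_contigs", 1),
                -strain_info[s].get("assembly_length", 0),
                s,
            ),
        )
        for s in members:
            manifests.append(
                StrainManifest(
                    strain_id=s,
                    qc_status=strain_info[s].get("qc_status", ""),
                    producer=strain_info[s]["producer"],
                    representative=(s == rep),
                    redundancy_cluster=cid,
                )
            )
    manifests.sort(key=lambda m: m.strain_id)
    return manifests


# ---------------------------------------------------------------------------
# receptor reference processing


@dataclass
class ReceptorReferenceBundle:
    msa: MultipleAlignment
    classes: dict[str, str]  # id -> FpvA | FpvB | other
    anchor: ProteinSequence  # ungapped anchor row (first FpvA)
    r1_region: object
    r2_region: object
    group_regions: list
    domain_models: dict[str, _phmm.ProfileHMM]
    region_models: dict[str, _phmm.ProfileHMM]


def prepare_receptor_references(
    ref_seqs: list[ProteinSequence],
    classes: dict[str, str],
    domain_seeds: dict[str, MultipleAlignment],
    config: PipelineConfig,
) -> ReceptorReferenceBundle:
    """Discover R1/R2 and the group-feature regions from the labelled panel.

    Conserved sites (top decile) partition the reference alignment into
    variable regions; the two regions with the highest FpvA identification
    scores become R1 and R2, and pHMMs are built from the FpvA rows (R1) and
    FpvB rows (R2).  The four most group-discriminative regions, ordered by
    alignment coordinate, define the grouping feature sequence.
    """
    msa = MultipleAlignment(ref_seqs)
    fpva_ids = sorted(i for i, c in classes.items() if c == "FpvA")
    anchor_id = fpva_ids[0]
    profile = conservation_profile(msa, decile=config.conserved_decile)
    regions = partition_variable_regions(profile, msa, anchor_id=anchor_id)
    labels = {i: classes[i] == "FpvA" for i in classes}
    cards = _rec.rank_regions(msa, regions, labels)
    r1_region, r2_region = cards[0].region, cards[1].region

    # group labels for region ranking: whole-gene grouping of the FpvA rows
    fpva_seqs = {i: msa.row(i).residues.replace("-", "") for i in fpva_ids}
    whole_groups = _rec.group_receptors(
        fpva_seqs,
        identity_threshold=config.whole_gene_identity,
        linkage=config.receptor_group_linkage,
    )
    groups = {i: whole_groups.group_of(i) for i in fpva_ids}
    fpva_msa = MultipleAlignment([msa.row(i) for i in fpva_ids])
    candidate_regions = [
        r for r in regions if r is not r1_region and r is not r2_region
    ]
    ranked = _rec.rank_regions_by_group(fpva_msa, candidate_regions, groups)
    group_regions = sorted((r for r, _ in ranked[:4]), key=lambda r: r.start_col)

    domain_models = {
        name: _phmm.build_phmm(aln, name=name) for name, aln in domain_seeds.items()
    }
    r1_rows = MultipleAlignment(
        [msa.row(i) for i in fpva_ids]
    ).slice_columns(r1_region.start_col, r1_region.end_col)
    fpvb_ids = sorted(i for i, c in classes.items() if c == "FpvB")
    r2_rows = MultipleAlignment(
        [msa.row(i) for i in fpvb_ids]
    ).slice_columns(r2_region.start_col, r2_region.end_col)
    region_models = {
        "R1": _phmm.build_phmm(r1_rows, name="R1_FpvA"),
        "R2": _phmm.build_phmm(r2_rows, name="R2_FpvB"),
    }
    return ReceptorReferenceBundle(
        msa=msa,
        classes=classes,
        anchor=msa.row(anchor_id).ungapped(),
        r1_region=r1_region,
        r2_region=r2_region,
        group_regions=group_regions,
        domain_models=domain_models,
        region_models=region_models,
    )


# ---------------------------------------------------------------------------
# per-genome work


def mine_receptors(
    genome: _nrps.GenomeRecord,
    bundle: ReceptorReferenceBundle,
    config: PipelineConfig,
) -> list[tuple[_rec.ReceptorCandidate, _rec.ReceptorClassification]]:
    """Enumerate ORF candidates, score and classify them."""
    out = []
    for contig_id, contig in genome.contigs:
        for start, end, strand, pep in _nrps.six_frame_segments(
            contig, min_len=config.min_orf_aa
        ):
            cand = _rec.ReceptorCandidate(
                strain_id=genome.strain_id,
                candidate_id=f"{genome.strain_id}:{contig_id}:{start}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                protein=pep,
            )
            _rec.score_candidate(cand, bundle.domain_models, bundle.region_models)
            cls = _rec.classify_receptor(
                cand,
                r1_gate=config.r1_gate,
                r2_gate=config.r2_gate,
                min_len=config.receptor_min_len,
                max_len=config.receptor_max_len,
                stn_gate=config.stn_gate,
                plug_gate=config.plug_gate,
                tonb_gate=config.tonb_gate,
            )
            out.append((cand, cls))
    out.sort(key=lambda t: (t[0].contig_id, t[0].start))
    return out


@dataclass
class PipelineResult:
    manifests: list[StrainManifest] = field(default_factory=list)
    lines: dict[str, _nrps.NRPSAssemblyLine] = field(default_factory=dict)
    structures: dict[str, _sub.PyoverdineStructure] = field(default_factory=dict)
    predictions: dict[str, list[_sub.SubstratePrediction]] = field(default_factory=dict)
    receptor_calls: dict[str, list] = field(default_factory=dict)
    receptor_features: dict[str, str] = field(default_factory=dict)
    receptor_groups: _rec.ReceptorGroupAssignment | None = None
    proximity: dict[str, tuple[float, bool]] = field(default_factory=dict)
    diversity: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def run_pipeline(
    config: PipelineConfig,
    genomes: list[_nrps.GenomeRecord],
    refset: _sub.ReferenceSet,
    receptor_refs: list[ProteinSequence],
    receptor_classes: dict[str, str],
    domain_seeds: dict[str, MultipleAlignment],
    clades: dict[str, str] | None = None,
    outdir=None,
) -> PipelineResult:
    """Run every stage over a batch of genomes.

    Deterministic for fixed inputs: re-running writes byte-identical outputs.
    """
    if not genomes:
        raise ValueError("no genomes to process")
    res = PipelineResult()
    bundle = prepare_receptor_references(
        receptor_refs, receptor_classes, domain_seeds, config
    )
    res.log.append(
        f"R1 region cols [{bundle.r1_region.start_col},{bundle.r1_region.end_col}); "
        f"R2 region cols [{bundle.r2_region.start_col},{bundle.r2_region.end_col})"
    )
    res.log.append(
        "group feature regions: "
        + ", ".join(
            f"[{r.start_col},{r.end_col})" for r in bundle.group_regions
        )
    )

    for g in sorted(genomes, key=lambda g: g.strain_id):
        sid = g.strain_id
        try:
            line = _nrps.build_assembly_line(g, edge_bp=config.edge_bp)
            res.lines[sid] = line
            res.log.append(f"{sid}: qc={line.qc_status}")
            if line.qc_status == "producer":
                structure, preds = _sub.predict_structure(
                    line,
                    refset,
                    threshold=config.substrate_threshold,
                    rel=config.relative_difference,
                )
                res.structures[sid] = structure
                res.predictions[sid] = preds
            calls = mine_receptors(g, bundle, config)
            res.receptor_calls[sid] = calls
            for cand, cls in calls:
                res.log.append(
                    f"{sid}: candidate {cand.candidate_id} -> {cls.receptor_class}"
                    f" ({'; '.join(cls.trace)})"
                )
            # Pep proximity
            pep_clusters = [
                c for c in line.clusters if c.role == "Pep"
            ] if sid in res.lines else []
            for cand, cls in calls:
                if cls.receptor_class == "rejected":
                    continue
                if pep_clusters:
                    best = min(
                        (
                            _rec.pep_proximity(
                                (cand.contig_id, cand.start, cand.end),
                                (c.contig_id, c.start, c.end),
                                window_bp=config.pep_window_bp,
                            )
                            for c in pep_clusters
                        ),
                        key=lambda t: t[0],
                    )
                else:
                    best = (float("inf"), False)
                res.proximity[cand.candidate_id] = best
            # feature sequences for annotated FpvAs
            for cand, cls in calls:
                if cls.receptor_class != "FpvA":
                    continue
                feat, flagged = _rec.extract_feature_sequence(
                    ProteinSequence(cand.candidate_id, cand.protein),
                    bundle.group_regions,
                    bundle.anchor,
                )
                if flagged:
                    res.log.append(f"{sid}: feature extraction flagged "
                                   f"{cand.candidate_id}")
                res.receptor_features[cand.candidate_id] = feat
        except Exception as exc:  # per-genome isolation
            res.errors[sid] = f"{type(exc).__name__}: {exc}"
            res.log.append(f"{sid}: FAILED {res.errors[sid]}")

    if res.receptor_features:
        res.receptor_groups = _rec.group_receptors(
            res.receptor_features,
            identity_threshold=config.feature_identity,
            linkage=config.receptor_group_linkage,
        )

    # per-clade Shannon diversity of receptor groups
    if clades and res.receptor_groups is not None:
        by_clade: dict[str, dict[int, int]] = {}
        for rid in res.receptor_features:
            sid = rid.split(":", 1)[0]
            clade = clades.get(sid)
            if clade is None:
                continue
            grp = res.receptor_groups.group_of(rid)
            by_clade.setdefault(clade, {})
            by_clade[clade][grp] = by_clade[clade].get(grp, 0) + 1
        for clade in sorted(by_clade):
            res.diversity[clade] = _rec.shannon_diversity(
                sorted(by_clade[clade].values())
            )

    res.manifests = [
        StrainManifest(
            strain_id=sid,
            qc_status=line.qc_status,
            producer=line.qc_status == "producer",
        )
        for sid, line in sorted(res.lines.items())
    ]
    if outdir is not None:
        write_results(res, outdir)
    return res


def synthetase_identity_matrix(
    lines: dict[str, _nrps.NRPSAssemblyLine]
) -> dict[tuple[str, str], float]:
    """Whole-synthetase percent identity between producer pairs (global
    alignment of the concatenated cluster proteins)."""
    producers = sorted(s for s, l in lines.items() if l.qc_status == "producer")
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(producers):
        for b in producers[i + 1 :]:
            pa = "".join(c.protein for c in lines[a].clusters)
            pb = "".join(c.protein for c in lines[b].clusters)
            aln = global_align(ProteinSequence(a, pa), ProteinSequence(b, pb))
            d = p_distance(aln.rows[0], aln.rows[1])
            out[(a, b)] = (1.0 - d) * 100.0
    return out


# ---------------------------------------------------------------------------
# output writing


def write_results(res: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "strain": m.strain_id,
                "qc_status": m.qc_status,
                "producer": m.producer,
            }
            for m in res.manifests
        ]
    ).to_csv(outdir / "qc.tsv", sep="\t", index=False)

    pred_rows = []
    for sid in sorted(res.predictions):
        for k, p in enumerate(res.predictions[sid]):
            pred_rows.append(
                {
                    "strain": sid,
                    "module": k,
                    "X1": round(p.x1, 6),
                    "X2": round(p.x2, 6),
                    "rule": p.rule,
                    "call": p.call,
                }
            )
    pd.DataFrame(
        pred_rows, columns=["strain", "module", "X1", "X2", "rule", "call"]
    ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    structures = {
        sid: {
            "chromophore": s.chromophore,
            "residues": [list(r) for r in s.residues],
            "flags": s.flags,
        }
        for sid, s in sorted(res.structures.items())
    }
    with open(outdir / "structures.json", "w") as fh:
        json.dump(structures, fh, indent=1, sort_keys=True)

    rec_rows = []
    for sid in sorted(res.receptor_calls):
        for cand, cls in res.receptor_calls[sid]:
            d, prox = res.proximity.get(cand.candidate_id, (float("nan"), False))
            rec_rows.append(
                {
                    "strain": sid,
                    "candidate": cand.candidate_id,
                    "contig": cand.contig_id,
                    "start": cand.start,
                    "end": cand.end,
                    "length": cand.length,
                    "STN": round(cand.domain_scores.get("STN", float("nan")), 2),
                    "Plug": round(cand.domain_scores.get("Plug", float("nan")), 2),
                    "TonB": round(cand.domain_scores.get("TonB", float("nan")), 2),
                    "R1": round(cand.region_scores.get("R1", float("nan")), 2),
                    "R2": round(cand.region_scores.get("R2", float("nan")), 2),
                    "class": cls.receptor_class,
                    "dist_to_pep": d,
                    "proximate": prox,
                    "trace": " | ".join(cls.trace),
                }
            )
    pd.DataFrame(rec_rows).to_csv(outdir / "receptors.tsv", sep="\t", index=False)

    with open(outdir / "receptor_features.fasta", "w") as fh:
        for rid in sorted(res.receptor_features):
            fh.write(f">{rid}\n{res.receptor_features[rid]}\n")

    group_rows = []
    if res.receptor_groups is not None:
        for rid in sorted(res.receptor_features):
            group_rows.append(
                {"receptor": rid, "group": res.receptor_groups.group_of(rid)}
            )
    pd.DataFrame(group_rows, columns=["receptor", "group"]).to_csv(
        outdir / "receptor_groups.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [{"clade": c, "shannon_entropy_nats": round(h, 6)}
         for c, h in sorted(res.diversity.items())],
        columns=["clade", "shannon_entropy_nats"],
    ).to_csv(outdir / "diversity.tsv", sep="\t", index=False)

    # cluster/domain annotations as GFF3
    with open(outdir / "clusters.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for sid in sorted(res.lines):
            line = res.lines[sid]
            for c in line.clusters:
                fh.write(
                    f"{c.contig_id}\tpyomine\tNRPS_cluster\t{c.start + 1}\t{c.end}"
                    f"\t.\t{c.strand}\t.\tID={sid}_{c.role};role={c.role};"
                    f"TE={c.has_TE}\n"
                )

    lines_json = {}
    for sid in sorted(res.lines):
        line = res.lines[sid]
        lines_json[sid] = {
            "qc_status": line.qc_status,
            "clusters": [
                {
                    "contig": c.contig_id,
                    "start": c.start,
                    "end": c.end,
                    "role": c.role,
                    "has_TE": c.has_TE,
                    "length_aa": len(c.protein),
                    "n_modules": len(c.modules),
                }
                for c in line.clusters
            ],
            "n_a_domains": line.n_a_domains,
        }
    with open(outdir / "assembly_lines.json", "w") as fh:
        json.dump(lines_json, fh, indent=1, sort_keys=True)

    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(res.log) + "\n")


# ---------------------------------------------------------------------------
# file-based entry point


def load_inputs(input_dir):
    """Load a fixture-layout input directory (genomes/ + reference tables)."""
    input_dir = Path(input_dir)
    genome_dir = input_dir / "genomes"
    genomes = []
    for p in sorted(genome_dir.glob("*.fasta")):
        contigs = [(s.id, s.residues) for s in read_fasta(p)]
        genomes.append(_nrps.GenomeRecord(p.stem, contigs))
    refset = _sub.ReferenceSet.from_tsv(input_dir / "ref_adomains.tsv")
    receptor_refs = read_fasta(input_dir / "ref_receptors.fasta")
    classes_df = pd.read_csv(input_dir / "ref_receptors.tsv", sep="\t", dtype=str)
    receptor_classes = dict(zip(classes_df["id"], classes_df["class"]))
    domain_seeds = {
        name: MultipleAlignment(read_fasta(input_dir / f"seed_{name}.fasta"))
        for name in ("STN", "Plug", "TonB")
    }
    clades = None
    clade_path = input_dir / "clades.tsv"
    if clade_path.exists():
        cdf = pd.read_csv(clade_path, sep="\t", dtype=str)
        clades = dict(zip(cdf["strain"], cdf["clade"]))
    return genomes, refset, receptor_refs, receptor_classes, domain_seeds, clades
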