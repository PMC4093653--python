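"""End-to-end pipeline: simulate -> detect -> classify -> library -> reports.

Each stage writes its outputs plus a JSON manifest (parameters, input
hashes, result counts) under the run directory; re-running with unchanged
parameters reuses cached stage outputs.  A recovery report scores
predictions against the simulator's truth records (element-level precision
and recall at +-3 bp boundary tolerance, exact-TSD rate, and the Rand
index of the family partition).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import est as est_mod
from . import families as fam_mod
from .classify import (ClassifiedTE, classify_candidate, find_mite_like,
                       locate_element, rules_with_cacta_motif)
from .homology import (DomainHit, default_queries, extract_flanks,
                       query_superfamily_map, search_genomes, hits_to_frame)
from .ltr import DetectConfig, LTRCandidate, find_direct_repeat_pairs, \
    inspect_all, ltr_identity_report
from .orfs import ORFAnnotation, annotations_frame, classify_layout, \
    find_orfs, layout_census
from .phylo import neighbor_joining, rt_distances, write_newick
from .sequences import GenomeSeq, gff3_line, read_fasta, write_fasta, \
    write_gff3
from .simulate import SimConfig, TruthRecord, write_simulation

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "ltr", "homology", "classify", "families", "est",
           "orf", "phylo")


@dataclass
class PipelineConfig:
    out_dir: str = "beante_run"
    genome_fasta: str | None = None      # skip simulation when provided
    est_fasta: str | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    sim: dict = field(default_factory=dict)
    min_ltr_len: int = 50
    min_internal: int = 50
    homology_evalue: float = 1e-20
    flank: int = 10_000
    family_identity: float = 70.0
    family_coverage: float = 80.0
    est_evalue: float = 1e-5
    min_orf_aa: int = 150
    window: int = 100_000
    cacta_three_prime: str = "ATGTG"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("min_ltr_len", "min_internal", "flank", "min_orf_aa",
                     "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("homology_evalue", "est_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            stages = {s: True for s in _STAGES}
            stages.update(data["stages"])
            data["stages"] = stages
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_cached(stage_dir: Path, params: dict) -> bool:
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    try:
        data = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    if data.get("params") != json.loads(json.dumps(params)):
        return False
    return all((stage_dir / f).exists() for f in data.get("outputs", []))


def _write_stage_manifest(stage_dir: Path, params: dict,
                          counts: dict, outputs: list[str]) -> dict:
    manifest = dict(
        params=params, counts=counts, outputs=outputs,
        hashes={f: _sha256(stage_dir / f) for f in outputs},
    )
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}
    rules = rules_with_cacta_motif(config.cacta_three_prime)
    queries = default_queries()
    qmap = query_superfamily_map(queries)

    # ---- genome (simulated or provided) -------------------------------
    truth: list[TruthRecord] = []
    ests: list[tuple[str, str, str]] = []
    if config.genome_fasta:
        genomes = read_fasta(config.genome_fasta)
        manifest["stages"]["simulate"] = {"skipped": "external genome"}
        if config.est_fasta:
            ests = [
                (g.seq_id, g.residues, "") for g in
                read_fasta(config.est_fasta)
            ]
    elif config.stages.get("simulate", True):
        sim_dir = out / "simulate"
        sim_cfg = SimConfig(**{
            "rng_seed": config.rng_seed,
            "cacta_three_prime": config.cacta_three_prime,
            **config.sim,
        })
        genomes, truth, ests = write_simulation(sim_cfg, sim_dir)
        manifest["stages"]["simulate"] = _write_stage_manifest(
            sim_dir, dataclasses.asdict(sim_cfg),
            {"n_elements": len(truth), "n_ests": len(ests)},
            ["genome.fa", "truth.gff3", "truth.tsv", "ests.fa"],
        )
    else:
        raise ValueError(
            "stage-dependency error: no genome (simulation disabled and "
            "no genome_fasta)"
        )

    # ---- LTR detection -------------------------------------------------
    ltr_cands: list[LTRCandidate] = []
    if config.stages.get("ltr", True):
        ltr_dir = out / "ltr"
        ltr_dir.mkdir(exist_ok=True)
        det = DetectConfig(min_ltr_len=config.min_ltr_len,
                           min_internal=config.min_internal)
        for genome in genomes:
            cands = find_direct_repeat_pairs(genome, det)
            ltr_cands.extend(inspect_all(genome, cands, det))
        _write_ltr_outputs(ltr_dir, ltr_cands)
        manifest["stages"]["ltr"] = _write_stage_manifest(
            ltr_dir, dataclasses.asdict(det),
            {"n_candidates": len(ltr_cands),
             "n_accepted": sum(
                 1 for c in ltr_cands if c.status == "accepted")},
            ["ltr.gff3", "ltr_report.tsv"],
        )

    # ---- homology scan --------------------------------------------------
    hits: list[DomainHit] = []
    if config.stages.get("homology", True):
        hom_dir = out / "homology"
        hom_dir.mkdir(exist_ok=True)
        hits = search_genomes(genomes, queries,
                              evalue_cutoff=config.homology_evalue,
                              flank=config.flank)
        hits_to_frame(hits).to_csv(hom_dir / "hits.tsv", sep="\t",
                                   index=False)
        flank_records = []
        by_seq = {g.seq_id: g for g in genomes}
        for h in hits:
            flank_records.extend(
                extract_flanks(by_seq[h.seq_id], [h], config.flank)
            )
        write_fasta(flank_records, hom_dir / "flanks.fa")
        manifest["stages"]["homology"] = _write_stage_manifest(
            hom_dir,
            {"evalue": config.homology_evalue, "flank": config.flank},
            {"n_hits": len(hits)}, ["hits.tsv", "flanks.fa"],
        )

    # ---- classification -------------------------------------------------
    elements: list[ClassifiedTE] = []
    if config.stages.get("classify", True):
        if not config.stages.get("ltr", True) and not hits:
            raise ValueError(
                "stage-dependency error: classify requires ltr and/or "
                "homology outputs"
            )
        cls_dir = out / "classify"
        cls_dir.mkdir(exist_ok=True)
        by_seq = {g.seq_id: g for g in genomes}
        elements = classify_all(genomes, ltr_cands, hits, qmap, rules)
        _write_element_outputs(cls_dir, elements, by_seq)
        manifest["stages"]["classify"] = _write_stage_manifest(
            cls_dir, {"cacta_three_prime": config.cacta_three_prime},
            {"n_elements": len(elements)},
            ["elements.gff3", "elements.fa"],
        )

    # ---- family clustering & library ------------------------------------
    families: list[fam_mod.TEFamily] = []
    library = None
    sequences: dict[str, str] = {}
    if config.stages.get("families", True) and elements:
        fam_dir = out / "families"
        fam_dir.mkdir(exist_ok=True)
        by_seq = {g.seq_id: g for g in genomes}
        sequences = {
            e.element_id: by_seq[e.seq_id].slice(*e.span) for e in elements
        }
        families = fam_mod.cluster_families(
            elements, sequences,
            identity_threshold=config.family_identity,
            coverage_threshold=config.family_coverage,
        )
        elem_map = {e.element_id: e for e in elements}
        library = fam_mod.build_library(families, elem_map, sequences)
        write_fasta(library.records, fam_dir / "library.fa")
        fam_mod.library_summary_frame(library).to_csv(
            fam_dir / "summary.tsv", sep="\t", index=False
        )
        dist_frames = [
            fam_mod.distribution_profile(f, elem_map, genomes,
                                         config.window).assign(
                family_id=f.family_id)
            for f in families
        ]
        pd.concat(dist_frames).to_csv(fam_dir / "distribution.tsv",
                                      sep="\t", index=False)
        manifest["stages"]["families"] = _write_stage_manifest(
            fam_dir,
            {"identity": config.family_identity,
             "coverage": config.family_coverage},
            {"n_families": len(families),
             "library_bp": library.total_bp},
            ["library.fa", "summary.tsv", "distribution.tsv"],
        )

    # ---- EST expression --------------------------------------------------
    if config.stages.get("est", True) and library is not None and ests:
        est_dir = out / "est"
        est_dir.mkdir(exist_ok=True)
        assignments = est_mod.map_ests(ests, library,
                                       evalue_cutoff=config.est_evalue)
        n_te = sum(1 for a in assignments if a.superfamily)
        pd.DataFrame([dataclasses.asdict(a) for a in assignments]).to_csv(
            est_dir / "assignments.tsv", sep="\t", index=False
        )
        if n_te:
            summary = est_mod.summarize_est_hits(assignments, n_te)
            est_mod.summary_frame(summary).to_csv(
                est_dir / "est_summary.tsv", sep="\t", index=False
            )
        manifest["stages"]["est"] = _write_stage_manifest(
            est_dir, {"evalue": config.est_evalue},
            {"n_ests": len(assignments), "n_te_ests": n_te},
            ["assignments.tsv"] + (["est_summary.tsv"] if n_te else []),
        )
    elif not config.stages.get("est", True):
        manifest["stages"]["est"] = {"skipped": "stage disabled"}

    # ---- ORF layout -------------------------------------------------------
    annotations: list[ORFAnnotation] = []
    if config.stages.get("orf", True) and ltr_cands:
        orf_dir = out / "orf"
        orf_dir.mkdir(exist_ok=True)
        by_seq = {g.seq_id: g for g in genomes}
        sf_by_span = {
            e.span: e.superfamily for e in elements
            if e.superfamily in ("Ty1-copia", "Ty3-gypsy",
                                 "LTR-unclassified")
        }
        for cand in ltr_cands:
            if cand.status != "accepted":
                continue
            ann = annotate_ltr_element(
                by_seq[cand.seq_id], cand, hits, config.min_orf_aa,
                superfamily=sf_by_span.get(cand.element_span, ""),
            )
            annotations.append(ann)
        annotations_frame(annotations).to_csv(
            orf_dir / "orf_annotations.tsv", sep="\t", index=False
        )
        layout_census(annotations).to_csv(
            orf_dir / "layout_census.tsv", sep="\t", index=False
        )
        manifest["stages"]["orf"] = _write_stage_manifest(
            orf_dir, {"min_orf_aa": config.min_orf_aa},
            {"n_annotated": len(annotations)},
            ["orf_annotations.tsv", "layout_census.tsv"],
        )

    # ---- RT phylogeny -----------------------------------------------------
    if config.stages.get("phylo", True) and hits:
        peptides = rt_peptides(genomes, hits, qmap)
        if len(peptides) >= 3:
            phy_dir = out / "phylo"
            phy_dir.mkdir(exist_ok=True)
            dist = rt_distances(peptides)
            tree = neighbor_joining(dist)
            write_newick(tree, phy_dir / "rt_tree.nwk")
            dist.to_phylip(phy_dir / "rt_distances.phy")
            manifest["stages"]["phylo"] = _write_stage_manifest(
                phy_dir, {}, {"n_leaves": len(peptides)},
                ["rt_tree.nwk", "rt_distances.phy"],
            )

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _write_ltr_outputs(ltr_dir: Path, cands: Sequence[LTRCandidate]) -> None:
    lines = []
    for i, c in enumerate(cands):
        attrs = {
            "ID": f"LTRTE{i + 1:04d}", "status": c.status or "raw",
            "TSD": c.tsd or "-", "ltr_identity": f"{c.ltr_identity:.2f}",
        }
        lines.append(gff3_line(
            c.seq_id, "beante", "LTR_retrotransposon",
            c.element_span[0], c.element_span[1], strand="+",
            attributes=attrs,
        ))
        for tag, span in (("five_prime", c.left_ltr),
                          ("three_prime", c.right_ltr)):
            lines.append(gff3_line(
                c.seq_id, "beante", "long_terminal_repeat",
                span[0], span[1], strand="+",
                attributes={"Parent": f"LTRTE{i + 1:04d}", "end": tag},
            ))
    write_gff3(lines, ltr_dir / "ltr.gff3")
    report = ltr_identity_report(
        [c for c in cands if c.status == "accepted"]
    )
    report.to_csv(ltr_dir / "ltr_report.tsv", sep="\t", index=False)


def _write_element_outputs(
    cls_dir: Path, elements: Sequence[ClassifiedTE],
    by_seq: Mapping[str, GenomeSeq],
) -> None:
    lines = []
    records = []
    for e in elements:
        lines.append(gff3_line(
            e.seq_id, "beante", "transposable_element",
            e.span[0], e.span[1], strand=e.strand,
            attributes={
                "ID": e.element_id, "superfamily": e.superfamily,
                "te_class": str(e.te_class), "TSD": e.tsd or "-",
                "evidence": " ".join(sorted(e.evidence)) or "-",
                "complete": str(e.complete),
            },
        ))
        records.append(
            (e.element_id, by_seq[e.seq_id].slice(*e.span),
             f"{e.superfamily} {e.seq_id}:{e.span[0]}-{e.span[1]}")
        )
    write_gff3(lines, cls_dir / "elements.gff3")
    write_fasta(records, cls_dir / "elements.fa")


def classify_all(
    genomes: Sequence[GenomeSeq],
    ltr_cands: Sequence[LTRCandidate],
    hits: Sequence[DomainHit],
    qmap: Mapping[str, str],
    rules,
) -> list[ClassifiedTE]:
    """Combine LTR, homology and MITE evidence into one element set.

    Priority on overlap: accepted LTR elements, then homology-located
    elements, then MITE-like structural candidates.
    """
    by_seq = {g.seq_id: g for g in genomes}
    elements: list[ClassifiedTE] = []

    def overlaps_any(seq_id: str, span: tuple[int, int]) -> bool:
        return any(
            e.seq_id == seq_id and span[0] < e.span[1] and e.span[0] < span[1]
            for e in elements
        )

    for cand in ltr_cands:
        if cand.status != "accepted":
            continue
        inside = [
            h for h in hits
            if h.seq_id == cand.seq_id
            and h.genome_span[0] >= cand.element_span[0]
            and h.genome_span[1] <= cand.element_span[1]
        ]
        sfs = {qmap.get(h.query_id, "") for h in inside}
        if "Ty1-copia" in sfs:
            sf = "Ty1-copia"
        elif "Ty3-gypsy" in sfs:
            sf = "Ty3-gypsy"
        else:
            sf = "LTR-unclassified"
        evidence = {"tsd"}
        if cand.has_tg_ca:
            evidence.add("terminal_motif")
        if inside:
            evidence.add("domain_homology")
        strand = inside[0].strand if inside else "+"
        elements.append(ClassifiedTE(
            element_id="", seq_id=cand.seq_id, span=cand.element_span,
            strand=strand, te_class=1, superfamily=sf, tsd=cand.tsd,
            evidence=evidence, complete=True,
        ))

    for hit in sorted(hits, key=lambda h: -h.bit_score):
        if overlaps_any(hit.seq_id, hit.genome_span):
            continue
        located = locate_element(by_seq[hit.seq_id], hit, qmap, rules)
        if overlaps_any(hit.seq_id, located.span):
            continue
        elements.append(located)

    for genome in genomes:
        for span in find_mite_like(genome, rules=rules):
            if overlaps_any(genome.seq_id, span):
                continue
            mite = classify_candidate(
                genome, span,
                [h for h in hits if h.seq_id == genome.seq_id],
                rules=rules, query_superfamilies=qmap,
            )
            if not overlaps_any(genome.seq_id, mite.span):
                elements.append(mite)

    elements.sort(key=lambda e: (e.seq_id, e.span))
    for i, e in enumerate(elements):
        e.element_id = f"EL{i + 1:04d}"
    return elements


def annotate_ltr_element(
    genome: GenomeSeq, cand: LTRCandidate, hits: Sequence[DomainHit],
    min_orf_aa: int = 150, superfamily: str = "",
) -> ORFAnnotation:
    """Call ORFs on an accepted element's internal region and classify."""
    es, ee = cand.element_span
    internal = genome.slice(cand.left_ltr[1], cand.right_ltr[0])
    offset = cand.left_ltr[1] - es
    orfs = [
        dataclasses.replace(
            o, span=(o.span[0] + offset, o.span[1] + offset)
        )
        for o in find_orfs(internal, min_orf_aa)
    ]
    rt_hits = [
        h for h in hits
        if h.seq_id == cand.seq_id
        and h.genome_span[0] >= es and h.genome_span[1] <= ee
    ]
    return classify_layout(cand, orfs, rt_hits, superfamily=superfamily)


def rt_peptides(
    genomes: Sequence[GenomeSeq], hits: Sequence[DomainHit],
    qmap: Mapping[str, str],
) -> dict[str, str]:
    """Translate each RT-domain hit region into a labeled peptide."""
    from Bio.Seq import Seq

    by_seq = {g.seq_id: g for g in genomes}
    peptides: dict[str, str] = {}
    for h in hits:
        sf = qmap.get(h.query_id, "")
        if sf not in ("Ty1-copia", "Ty3-gypsy", "LINE"):
            continue
        nt = by_seq[h.seq_id].slice(*h.genome_span)
        if h.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        pep = str(Seq(nt).translate()).replace("*", "X")
        if len(pep) < 50:
            continue
        label = f"{h.seq_id}_{h.genome_span[0]}_{sf}".replace(" ", "_")
        peptides[label] = pep
    return peptides


# ---------------------------------------------------------------------------
# recovery scoring

def rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Plain Rand index between two partitions given as label sequences."""
    if len(labels_a) != len(labels_b):
        raise ValueError("partitions must label the same items")
    n = len(labels_a)
    if n < 2:
        return 1.0
    agree = 0
    for i, j in combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        agree += same_a == same_b
    return agree / (n * (n - 1) / 2)


def recovery_report(
    predicted: Sequence[ClassifiedTE],
    truth: Sequence[TruthRecord],
    predicted_families: Mapping[str, str] | None = None,
    boundary_tol: int = 3,
) -> dict:
    """Element-level precision/recall per superfamily at +-tol boundaries.

    A predicted element matches a truth record when both boundaries are
    within ``boundary_tol`` bp on the same sequence.  Also reports the
    exact-TSD rate over matches and, when ``predicted_families`` maps
    matched element ids to family ids, the Rand index against the planted
    family partition.
    """
    matches: list[tuple[ClassifiedTE, TruthRecord]] = []
    used: set[str] = set()
    for rec in truth:
        for p in predicted:
            if p.element_id in used or p.seq_id != rec.seq_id:
                continue
            if (abs(p.span[0] - rec.span[0]) <= boundary_tol
                    and abs(p.span[1] - rec.span[1]) <= boundary_tol):
                matches.append((p, rec))
                used.add(p.element_id)
                break
    per_sf: dict[str, dict] = {}
    for rec in truth:
        d = per_sf.setdefault(rec.superfamily, dict(
            n_truth=0, n_matched=0, n_sf_correct=0, n_tsd_exact=0))
        d["n_truth"] += 1
    for p, rec in matches:
        d = per_sf[rec.superfamily]
        d["n_matched"] += 1
        if p.superfamily == rec.superfamily:
            d["n_sf_correct"] += 1
        if p.tsd == rec.tsd:
            d["n_tsd_exact"] += 1
    n_matched = len(matches)
    report = dict(
        n_truth=len(truth),
        n_predicted=len(predicted),
        n_matched=n_matched,
        recall=n_matched / len(truth) if truth else 1.0,
        precision=n_matched / len(predicted) if predicted else 1.0,
        tsd_exact_rate=(
            sum(1 for p, r in matches if p.tsd == r.tsd) / n_matched
            if n_matched else 0.0
        ),
        per_superfamily=per_sf,
    )
    if predicted_families is not None and matches:
        truth_labels = [r.family_label for _p, r in matches]
        pred_labels = [
            predicted_families.get(p.element_id, p.element_id)
            for p, _r in matches
        ]
        report["family_rand_index"] = rand_index(truth_labels, pred_labels)
    return report
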