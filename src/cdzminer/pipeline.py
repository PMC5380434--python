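"""Orchestration of the Cdz-like system discovery procedure.

The scan proceeds exactly as the published search, with user-supplied
genomes standing in for the public databases: (1) locate type I
secretion system (T1SS) anchor loci by profile-scoring annotated CDS
against reference ABC-transporter/adaptor alignments (or take user
anchor coordinates); (2) cut 10 kb windows around each locus; (3)
enumerate all candidate ORFs of 60-200 residues in six frames; (4) run
an iterative profile-HMM search seeded from the toxin alignment, where
each round's accepted hits - bit score above a calibrated threshold
AND a passing glycine-zipper classifier verdict - are aligned back
into the seed and the model rebuilt (two rebuild rounds by default);
(5) assign accepted toxins to their nearest anchor within 10 kb,
dropping orphans, and report per-cluster toxin counts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import MinerConfig, OrfParams
from .gzfilter import FeatureVerdict, classify_toxin
from .orfscan import OrfCall, enumerate_orfs
from .profilehmm import BuiltinEngine, Msa
from .seqio import Feature, GenomeRecord, Window, extract_window, write_fasta, write_gff3

__all__ = [
    "AnchorLocus",
    "ToxinCall",
    "SearchState",
    "ClusterCall",
    "ScanResult",
    "find_anchors",
    "run_iterative_search",
    "assemble_clusters",
    "summarize",
    "scan",
]


@dataclass
class AnchorLocus:
    """A T1SS-like locus: one or more anchor genes within 5 kb."""

    contig_id: str
    genes: List[Feature]
    scores: Dict[str, float] = field(default_factory=dict)  # gene id -> bits

    @property
    def span(self) -> Tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))

    @property
    def id(self) -> str:
        s = self.span
        return f"{self.contig_id}:{s[0]}-{s[1]}"


@dataclass
class ToxinCall:
    """An accepted candidate toxin ORF."""

    orf: OrfCall
    bits: float
    verdict: FeatureVerdict
    iteration: int

    @property
    def feature(self) -> Feature:
        return self.orf.feature


@dataclass
class SearchState:
    """State of the iterative profile search after the last round."""

    iteration: int
    msa: Msa
    model: object
    accepted: Dict[str, ToxinCall]
    threshold_bits: float
    accepted_per_iteration: List[int] = field(default_factory=list)


@dataclass
class ClusterCall:
    """An anchor locus with its assigned toxin candidates."""

    anchor: AnchorLocus
    toxins: List[ToxinCall]
    distances: List[int]
    adjacent: List[bool]
    cluster_id: str = ""

    @property
    def toxin_count_class(self) -> str:
        n = len(self.toxins)
        return {1: "1", 2: "2"}.get(n, "3+")


@dataclass
class ScanResult:
    anchors: List[AnchorLocus]
    state: SearchState
    clusters: List[ClusterCall]
    dropped: List[ToxinCall]
    config: MinerConfig


class MissingAnnotationError(ValueError):
    pass


def _translate_cds(genome: GenomeRecord, feat: Feature) -> str:
    from .orfscan import _translate  # same codon conventions as the ORF scan

    from .seqio import revcomp

    nt = genome.sequence[feat.start : feat.end]
    if feat.strand == "-":
        nt = revcomp(nt)
    if len(nt) % 3:
        nt = nt[: len(nt) - len(nt) % 3]
    prot = _translate(nt, table=11)
    return prot[:-1] if prot.endswith("*") else prot


def _group_loci(genes: List[Tuple[Feature, float]], group_nt: int) -> List[AnchorLocus]:
    loci: List[AnchorLocus] = []
    by_contig: Dict[str, List[Tuple[Feature, float]]] = {}
    for g, s in genes:
        by_contig.setdefault(g.contig_id, []).append((g, s))
    for contig in sorted(by_contig):
        items = sorted(by_contig[contig], key=lambda t: t[0].start)
        cur: List[Tuple[Feature, float]] = []
        for item in items:
            if cur and item[0].start - max(f.end for f, _ in cur) > group_nt:
                loci.append(
                    AnchorLocus(contig, [f for f, _ in cur], {f.id: s for f, s in cur})
                )
                cur = []
            cur.append(item)
        if cur:
            loci.append(
                AnchorLocus(contig, [f for f, _ in cur], {f.id: s for f, s in cur})
            )
    return loci


def find_anchors(
    genomes: Sequence[GenomeRecord],
    t1ss_refs: Optional[Dict[str, Msa]] = None,
    user_bed: Optional[Sequence[Feature]] = None,
    config: Optional[MinerConfig] = None,
    engine=None,
    six_frame: bool = False,
) -> List[AnchorLocus]:
    """Locate T1SS anchor loci.

    Annotated CDS are profile-scored against each reference alignment
    in ``t1ss_refs``; genes above the calibrated bit threshold of any
    reference profile are grouped into loci by 5 kb proximity.  A user
    BED bypasses scoring entirely.  Unannotated genomes raise unless
    ``six_frame`` is set, in which case large ORFs (200-900 residues)
    are enumerated and scored as anchor candidates (slower).
    """
    cfg = config or MinerConfig()
    if user_bed is not None:
        return _group_loci([(f, float("nan")) for f in user_bed], cfg.pipeline.anchor_group_nt)
    if not t1ss_refs:
        raise ValueError("need t1ss_refs reference alignments or a user anchor BED")
    engine = engine or BuiltinEngine(cfg.hmm.gap_threshold, cfg.hmm.pseudocount_weight)

    candidates: List[Tuple[Feature, str, GenomeRecord]] = []  # (feature, protein, genome)
    for genome in genomes:
        cds = [f for f in genome.features if f.kind == "CDS"]
        if not cds:
            if not six_frame:
                raise MissingAnnotationError(
                    f"genome {genome.id} has no CDS annotation and no anchor BED was "
                    "given; re-run with six_frame=True to score large ORFs "
                    f"({cfg.pipeline.anchor_min_res}-{cfg.pipeline.anchor_max_res} aa) "
                    "as anchors (slower)"
                )
            params = OrfParams(
                min_res=cfg.pipeline.anchor_min_res, max_res=cfg.pipeline.anchor_max_res
            )
            for orf in enumerate_orfs(genome.sequence, params, contig_id=genome.id):
                candidates.append((orf.feature, orf.protein, genome))
        else:
            for f in cds:
                candidates.append((f, _translate_cds(genome, f), genome))

    hits: List[Tuple[Feature, float]] = []
    lengths = sorted({len(p) for _, p, _ in candidates}) or [400]
    models = []
    for i, (name, msa) in enumerate(sorted(t1ss_refs.items())):
        model = engine.build(msa)
        thr = engine.calibrate(
            model,
            max(cfg.hmm.n_random // 2, 100),
            lengths,
            cfg.hmm.calibration_seed + 1000 + i,
            cfg.hmm.alpha,
        )
        models.append((model, thr))
    if candidates:
        proteins = [p for _, p, _ in candidates]
        best = np.full(len(proteins), -np.inf)
        passing = np.zeros(len(proteins), dtype=bool)
        for model, thr in models:
            scores = engine.score(model, proteins)
            passing |= scores >= thr
            best = np.maximum(best, scores)
        for (feat, _p, _g), ok, b in zip(candidates, passing, best):
            if ok:
                hits.append((feat, float(b)))
    return _group_loci(hits, cfg.pipeline.anchor_group_nt)


def _candidate_orfs(
    genomes: Sequence[GenomeRecord],
    anchors: Sequence[AnchorLocus],
    cfg: MinerConfig,
    whole_genome: bool = False,
) -> List[OrfCall]:
    by_id = {g.id: g for g in genomes}
    seen: Dict[str, OrfCall] = {}
    if whole_genome:
        for g in genomes:
            for orf in enumerate_orfs(g.sequence, cfg.orf, contig_id=g.id):
                seen.setdefault(orf.id, orf)
        return list(seen.values())
    for locus in anchors:
        genome = by_id.get(locus.contig_id)
        if genome is None:
            continue
        s = locus.span
        probe = Feature(
            id=locus.id, kind="anchor", contig_id=locus.contig_id,
            start=s[0], end=s[1], strand="+",
        )
        win, seq = extract_window(genome, probe, cfg.pipeline.flank_nt)
        for orf in enumerate_orfs(seq, cfg.orf, contig_id=genome.id, offset=win.start):
            seen.setdefault(orf.id, orf)
    return list(seen.values())


def run_iterative_search(
    orfs: Sequence[OrfCall],
    seed_msa: Msa,
    config: Optional[MinerConfig] = None,
    engine=None,
    n_iter: Optional[int] = None,
) -> SearchState:
    """Iterative (jackhmmer-style) profile search over candidate ORFs.

    Round 0 scores every candidate with the model built from the seed
    alignment; hits above the calibrated bit threshold whose classifier
    verdict passes are aligned back into the alignment, the model is
    rebuilt, and scoring repeats - ``n_iter`` rebuild rounds (default
    2), stopping early when a round adds nothing.  The between-round
    filter applies the full classifier verdict.  Deterministic for a
    fixed configuration.
    """
    cfg = config or MinerConfig()
    n_iter = cfg.pipeline.n_iter if n_iter is None else n_iter
    engine = engine or BuiltinEngine(cfg.hmm.gap_threshold, cfg.hmm.pseudocount_weight)

    proteins = [o.protein for o in orfs]
    length_pool = sorted({len(p) for p in proteins}) or [80]
    member_names = list(seed_msa.names)
    member_seqs = [r.replace("-", "") for r in seed_msa.rows]

    msa = seed_msa
    model = engine.build(msa)
    accepted: Dict[str, ToxinCall] = {}
    accepted_per_iteration: List[int] = []
    threshold = 0.0
    t = 0
    while True:
        threshold = engine.calibrate(
            model, cfg.hmm.n_random, length_pool, cfg.hmm.calibration_seed + t, cfg.hmm.alpha
        )
        scores = engine.score(model, proteins) if proteins else np.array([])
        new = 0
        for orf, bits in zip(orfs, scores):
            if orf.id in accepted or not np.isfinite(bits) or bits < threshold:
                continue
            verdict = classify_toxin(orf.protein, cfg.classifier)
            if verdict.overall:
                accepted[orf.id] = ToxinCall(orf=orf, bits=float(bits), verdict=verdict, iteration=t)
                member_names.append(orf.id)
                member_seqs.append(orf.protein)
                new += 1
        accepted_per_iteration.append(len(accepted))
        if t >= n_iter or (new == 0 and t > 0):
            break
        if new == 0 and t == 0 and n_iter > 0:
            break
        rows = [engine.align(model, s) for s in member_seqs]
        try:
            msa = Msa(names=list(member_names), rows=rows)
            model = engine.build(msa)
        except Exception:
            break  # keep the state of the last completed round
        t += 1
    return SearchState(
        iteration=t,
        msa=msa,
        model=model,
        accepted=accepted,
        threshold_bits=threshold,
        accepted_per_iteration=accepted_per_iteration,
    )


def _dedupe(calls: Sequence[ToxinCall]) -> List[ToxinCall]:
    """One call per gene: nested start choices share a (contig, strand,
    stop codon); keep the highest-scoring, longest one."""
    best: Dict[Tuple[str, str, int], ToxinCall] = {}
    for c in calls:
        key = (c.orf.contig_id, c.orf.strand, c.orf.stop_pos)
        prev = best.get(key)
        if (
            prev is None
            or (c.bits, c.orf.end - c.orf.start) > (prev.bits, prev.orf.end - prev.orf.start)
        ):
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.orf.contig_id, c.orf.start))


def _gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def assemble_clusters(
    accepted: Sequence[ToxinCall],
    anchors: Sequence[AnchorLocus],
    flank_nt: int = 10_000,
    adjacency_gap: int = 500,
) -> Tuple[List[ClusterCall], List[ToxinCall]]:
    """Assign each accepted toxin to its nearest anchor within ``flank_nt``.

    Toxins with no anchor in range are dropped (returned separately).
    Returns ``(clusters, dropped)``; clusters carry anchor-toxin
    distances, an adjacency flag per consecutive toxin pair
    (gap < ``adjacency_gap``), and the 1/2/3+ toxin-count class.
    """
    calls = _dedupe(accepted)
    assigned: Dict[int, List[Tuple[ToxinCall, int]]] = {}
    dropped: List[ToxinCall] = []
    for call in calls:
        best = None  # (distance, span start, locus id, index) - deterministic ties
        for i, locus in enumerate(anchors):
            if locus.contig_id != call.orf.contig_id:
                continue
            d = _gap((call.orf.start, call.orf.end), locus.span)
            key = (d, locus.span[0], locus.id, i)
            if d <= flank_nt and (best is None or key < best):
                best = key
        if best is None:
            dropped.append(call)
        else:
            assigned.setdefault(best[3], []).append((call, best[0]))
    clusters: List[ClusterCall] = []
    for i in sorted(assigned):
        pairs = sorted(assigned[i], key=lambda t: t[0].orf.start)
        toxins = [c for c, _ in pairs]
        distances = [d for _, d in pairs]
        adjacent = [
            _gap((a.orf.start, a.orf.end), (b.orf.start, b.orf.end)) < adjacency_gap
            for a, b in zip(toxins, toxins[1:])
        ]
        clusters.append(
            ClusterCall(
                anchor=anchors[i],
                toxins=toxins,
                distances=distances,
                adjacent=adjacent,
                cluster_id=f"cluster_{anchors[i].id}",
            )
        )
    return clusters, dropped


def summarize(
    clusters: Sequence[ClusterCall], taxonomy_map: Optional[Dict[str, str]] = None
) -> Dict[str, pd.DataFrame]:
    """Report tables: per-cluster rows, toxin-count-class percentages,
    per-taxon cluster counts (ids missing from the map -> 'unassigned')."""
    rows = []
    for cl in clusters:
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "contig": cl.anchor.contig_id,
                "anchor_start": cl.anchor.span[0],
                "anchor_end": cl.anchor.span[1],
                "n_toxins": len(cl.toxins),
                "toxin_count_class": cl.toxin_count_class,
                "toxin_ids": ",".join(t.orf.id for t in cl.toxins),
                "max_distance_nt": max(cl.distances) if cl.distances else 0,
                "any_adjacent": any(cl.adjacent),
            }
        )
    per_cluster = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "contig", "anchor_start", "anchor_end", "n_toxins",
            "toxin_count_class", "toxin_ids", "max_distance_nt", "any_adjacent",
        ],
    )
    if len(per_cluster):
        counts = per_cluster["toxin_count_class"].value_counts()
        class_dist = pd.DataFrame(
            {
                "toxin_count_class": counts.index,
                "n_clusters": counts.values,
                "percent": 100.0 * counts.values / counts.values.sum(),
            }
        ).sort_values("toxin_count_class", ignore_index=True)
    else:
        class_dist = pd.DataFrame(columns=["toxin_count_class", "n_clusters", "percent"])
    tax_rows: Dict[str, int] = {}
    for cl in clusters:
        taxon = (taxonomy_map or {}).get(cl.anchor.contig_id, "unassigned")
        tax_rows[taxon] = tax_rows.get(taxon, 0) + 1
    per_taxon = pd.DataFrame(
        sorted(tax_rows.items()), columns=["taxon", "n_clusters"]
    )
    return {"per_cluster": per_cluster, "class_distribution": class_dist, "per_taxon": per_taxon}


def scan(
    genomes: Sequence[GenomeRecord],
    seed_msa: Msa,
    t1ss_refs: Optional[Dict[str, Msa]] = None,
    user_bed: Optional[Sequence[Feature]] = None,
    config: Optional[MinerConfig] = None,
    engine=None,
    taxonomy_map: Optional[Dict[str, str]] = None,
    whole_genome_orfs: bool = False,
) -> ScanResult:
    """The full discovery pipeline over a genome collection.

    ``whole_genome_orfs`` scans all six-frame ORFs of every contig
    instead of only anchor windows; orphan hits are then removed by the
    anchor-context rule in cluster assembly (useful for measuring what
    the context filter contributes).
    """
    cfg = config or MinerConfig()
    anchors = find_anchors(genomes, t1ss_refs, user_bed, cfg, engine)
    orfs = _candidate_orfs(genomes, anchors, cfg, whole_genome=whole_genome_orfs)
    state = run_iterative_search(orfs, seed_msa, cfg, engine)
    clusters, dropped = assemble_clusters(
        list(state.accepted.values()),
        anchors,
        cfg.pipeline.flank_nt if cfg.pipeline.require_anchor_context else 10**12,
        cfg.pipeline.adjacency_gap_nt,
    )
    return ScanResult(anchors=anchors, state=state, clusters=clusters, dropped=dropped, config=cfg)


def write_scan_outputs(result: ScanResult, out_dir) -> None:
    """Write clusters.gff3, toxins.faa, report.tsv, summary.tsv, run.log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(result.clusters, out / "clusters.gff3")
    proteins = []
    for cl in result.clusters:
        for t in cl.toxins:
            mature = (
                t.orf.protein[t.verdict.leader.cleavage_index :]
                if t.verdict.leader
                else t.orf.protein
            )
            proteins.append((t.orf.id, t.orf.protein, f"cluster={cl.cluster_id} PASS"))
            proteins.append((t.orf.id + "|mature", mature, f"cluster={cl.cluster_id}"))
    write_fasta(proteins, out / "toxins.faa")
    verdict_rows = []
    for cl in result.clusters:
        for t in cl.toxins:
            row = {"orf_id": t.orf.id, "bits": t.bits, "iteration": t.iteration,
                   "cluster_id": cl.cluster_id}
            row.update(t.verdict.as_dict())
            verdict_rows.append(row)
    for t in result.dropped:
        row = {"orf_id": t.orf.id, "bits": t.bits, "iteration": t.iteration,
               "cluster_id": "dropped_no_anchor"}
        row.update(t.verdict.as_dict())
        verdict_rows.append(row)
    pd.DataFrame(verdict_rows).to_csv(out / "report.tsv", sep="\t", index=False)
    tables = summarize(result.clusters)
    tables["class_distribution"].to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "run.log", "w") as fh:
        fh.write("cdzminer scan\n")
        fh.write(f"anchors: {len(result.anchors)}\n")
        fh.write(f"accepted toxins: {len(result.state.accepted)}\n")
        fh.write(f"clusters: {len(result.clusters)}\n")
        fh.write(f"dropped (no anchor in range): {len(result.dropped)}\n")
        fh.write(f"iterations used: {result.state.iteration}\n")
        fh.write(f"final bit threshold: {result.state.threshold_bits:.2f}\n")
        fh.write("config:\n")
        import yaml

        fh.write(yaml.safe_dump(result.config.to_dict(), sort_keys=False))
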