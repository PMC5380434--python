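"""Synthetic genomes with planted Cdz-like clusters and ground truth.

The generator emulates the genomic signature the discovery pipeline
mines for: a two-gene type I secretion operon (ABC-transporter-like +
membrane-fusion-adaptor-like genes) with one to three small toxin genes
within 10 kb, each toxin a leader + glycine-zipper + charged-tail
protein, plus decoy genes that each violate exactly one classifier rule
(interrupted zipper, over-long protein, missing G[G/A/S] leader end,
hydrophobic over-long tail) and a classifier-passing decoy placed far
from any secretion system.  A four-row noisy seed alignment of the
planted toxin family and reference alignments for the two anchor
protein families are emitted alongside, so the whole pipeline runs
offline.  Everything is driven by one integer seed and is bit-identical
across repeat runs.

Construction rules that keep truth labels deterministic:

* reverse translation never uses GTG/TTG (and M never occurs inside a
  planted protein), so planted genes contain no nested in-frame start;
* the residue after each zipper anchor is drawn from {V,I,L,F} - never
  A/G/S - so no accidental G[G/A/S] leader signal arises in a zipper;
* intergenic spacers carry a palindromic stop cassette (stops in all
  six frames) at least every 150 nt, suppressing long spurious ORFs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .config import AMINO_ACIDS
from .gzfilter import classify_toxin, composition_stats
from .profilehmm import Msa
from .seqio import Feature, GenomeRecord, revcomp, write_fasta

__all__ = [
    "SynthParams",
    "TruthRecord",
    "SynthResult",
    "DECOY_CLASSES",
    "make_toxin_protein",
    "make_decoy",
    "generate",
]

DECOY_CLASSES = (
    "decoy_interrupted",
    "decoy_bad_length",
    "decoy_no_leader",
    "decoy_no_tail",
    "decoy_no_anchor",
)

# stop codons in all six frames; its own reverse complement
_STOP_CASSETTE = "TTAATTAATTAA"

_LEADER_ALPHA = "AVILF"
_SHOULDER_ALPHA = "AVI"
_X1_ALPHA = "VILF"  # residue right after a zipper anchor: no A/G/S here
_X23_ALPHA = "AVILF"
_X23_W = np.array([0.35, 0.25, 0.20, 0.10, 0.10])
_TAIL_FIRST = "DEKR"
_TAIL_ALPHA = "DEKRSTNQ"

# sense codons of the bacterial code, GTG/TTG withheld (see module docstring)
_CODONS: Dict[str, List[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA"],
}
_STOP_CODONS = ["TAA", "TAG", "TGA"]


@dataclass
class SynthParams:
    """Study conditions of the synthetic benchmark."""

    seed: int = 1
    n_genomes: int = 20
    contig_len_nt: int = 120_000
    n_true_clusters: int = 1
    toxins_per_cluster: Tuple[float, float, float] = (0.81, 0.14, 0.05)  # P(1),P(2),P(3)
    decoy_spec: Dict[str, int] = field(
        default_factory=lambda: {c: 1 for c in DECOY_CLASSES}
    )
    leader_len: Tuple[int, int] = (12, 30)
    zipper_anchors: Tuple[int, int] = (4, 8)
    target_len: Tuple[int, int] = (68, 110)
    tail_len: Tuple[int, int] = (4, 12)
    gc_background: float = 0.55
    mut_rate_member: float = 0.12
    mut_rate_seed: float = 0.08
    anchor_mut_rate: float = 0.10
    abc_len: int = 520
    adaptor_len: int = 440

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_true_clusters < 0:
            raise ValueError("counts must be non-negative (>=1 genome)")
        if any(v < 0 for v in self.decoy_spec.values()):
            raise ValueError("decoy counts must be >= 0")
        unknown = set(self.decoy_spec) - set(DECOY_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth annotation of one planted element."""

    genome_id: str
    element_id: str
    kind: str  # anchor_gene | true_toxin | decoy_*
    start: int
    end: int
    strand: str
    protein: str


@dataclass
class SynthResult:
    genomes: List[GenomeRecord]
    truth: List[TruthRecord]
    seed_msa: Msa
    t1ss_refs: Dict[str, Msa]
    params: SynthParams

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])


# ---------------------------------------------------------------------------
# protein architectures


def _choice(rng: np.random.Generator, alphabet: str, weights=None) -> str:
    idx = rng.choice(len(alphabet), p=weights)
    return alphabet[int(idx)]


def _toxin_architecture(
    rng: np.random.Generator,
    params: SynthParams,
    *,
    target_len: Optional[Tuple[int, int]] = None,
    leader_len: Optional[Tuple[int, int]] = None,
    n_anchors: Optional[Tuple[int, int]] = None,
    tail_len: Optional[Tuple[int, int]] = None,
    shoulder: bool = True,
) -> List[Tuple[str, str]]:
    """A toxin blueprint: list of (allowed alphabet, chosen residue).

    Positions with a single-letter alphabet are structurally fixed
    (initiator M, leader-end G, zipper anchors); the rest may vary
    within their class when family members are drawn.
    """
    lead_lo, lead_hi = leader_len or params.leader_len
    k_lo, k_hi = n_anchors or params.zipper_anchors
    t_lo, t_hi = tail_len or params.tail_len
    tgt_lo, tgt_hi = target_len or params.target_len

    llen = int(rng.integers(lead_lo, lead_hi + 1))
    k = int(rng.integers(k_lo, k_hi + 1))
    tlen = int(rng.integers(t_lo, t_hi + 1))
    zspan = 4 * (k - 1) + 1
    base = 1 + llen + zspan + tlen
    tgt = int(rng.integers(max(tgt_lo, base), max(tgt_hi, base) + 1))
    shoulder_len = max(0, tgt - base) if shoulder else 0

    arch: List[Tuple[str, str]] = [("M", "M")]
    for _ in range(llen - 3):
        arch.append((_LEADER_ALPHA, _choice(rng, _LEADER_ALPHA)))
    arch.append(("G", "G"))
    arch.append(("GAS", _choice(rng, "GAS")))
    for _ in range(shoulder_len):
        arch.append((_SHOULDER_ALPHA, _choice(rng, _SHOULDER_ALPHA)))
    for a in range(k):
        arch.append(("G", "G"))
        if a < k - 1:
            arch.append((_X1_ALPHA, _choice(rng, _X1_ALPHA)))
            for _ in range(2):
                arch.append((_X23_ALPHA, _choice(rng, _X23_ALPHA, _X23_W)))
    arch.append((_TAIL_FIRST, _choice(rng, _TAIL_FIRST)))
    for _ in range(tlen - 1):
        arch.append((_TAIL_ALPHA, _choice(rng, _TAIL_ALPHA)))
    return arch


def _arch_protein(arch: Sequence[Tuple[str, str]]) -> str:
    return "".join(res for _, res in arch)


def _arch_annotations(arch) -> dict:
    protein = _arch_protein(arch)
    # leader ends after the GAS position (index of 'GAS' alphabet + 1)
    gas_idx = next(i for i, (alpha, _) in enumerate(arch) if alpha == "GAS")
    anchors = [i for i, (alpha, _) in enumerate(arch) if alpha == "G" and i > gas_idx]
    return {
        "cleavage_index": gas_idx + 1,
        "zipper_anchors": anchors,  # indices in the full protein
        "length": len(protein),
    }


def _mutate_member(rng: np.random.Generator, arch, rate: float) -> List[Tuple[str, str]]:
    out = []
    for alpha, res in arch:
        if len(alpha) > 1 and rng.random() < rate:
            res = _choice(rng, alpha)
        out.append((alpha, res))
    return out


def make_toxin_protein(rng: np.random.Generator, params: Optional[SynthParams] = None):
    """Draw one classifier-passing toxin protein.

    Returns ``(protein, annotations)``.  The construction guarantees the
    four-part classifier passes and the mature {G,A,V,I} fraction is at
    least 0.6; a rejection loop enforces both exactly.
    """
    params = params or SynthParams()
    for _ in range(60):
        arch = _toxin_architecture(rng, params)
        protein = _arch_protein(arch)
        ann = _arch_annotations(arch)
        mature = protein[ann["cleavage_index"] :]
        frac = composition_stats(mature)["small_hydrophobic"]
        if frac >= 0.6 and classify_toxin(protein).overall:
            ann["small_hydrophobic_frac"] = frac
            ann["arch"] = arch
            return protein, ann
    raise RuntimeError("could not draw a passing toxin in 60 attempts")  # pragma: no cover


def make_decoy(rng: np.random.Generator, violation_class: str, params: Optional[SynthParams] = None):
    """Draw a decoy violating exactly one classifier rule.

    ``decoy_no_anchor`` is a fully valid toxin (its defect is genomic
    placement, applied by :func:`generate`).
    """
    params = params or SynthParams()
    if violation_class not in DECOY_CLASSES:
        raise ValueError(f"unknown decoy class {violation_class!r}")

    if violation_class == "decoy_no_anchor":
        protein, ann = make_toxin_protein(rng, params)
        return protein, ann

    if violation_class == "decoy_interrupted":
        # needs two >=3-anchor halves so only the interruption rule fails
        arch = _toxin_architecture(rng, params, n_anchors=(6, 8))
        ann = _arch_annotations(arch)
        anchors = ann["zipper_anchors"]
        mid_anchor = anchors[len(anchors) // 2 - 1]
        pos = mid_anchor + 2  # an x2 position between anchors
        arch = list(arch)
        arch[pos] = ("PC", _choice(rng, "PC"))
        protein = _arch_protein(arch)
        v = classify_toxin(protein)
        assert not v.zipper_uninterrupted and v.length_ok and not v.overall
        ann["arch"] = arch
        return protein, ann

    if violation_class == "decoy_bad_length":
        arch = _toxin_architecture(rng, params, target_len=(155, 195))
        protein = _arch_protein(arch)
        ann = _arch_annotations(arch)
        v = classify_toxin(protein)
        assert not v.length_ok and v.zipper_count_ok and not v.overall
        ann["arch"] = arch
        return protein, ann

    if violation_class == "decoy_no_leader":
        protein, ann = make_toxin_protein(rng, params)
        arch = list(ann["arch"])
        gas_idx = next(i for i, (alpha, _) in enumerate(arch) if alpha == "GAS")
        arch[gas_idx - 1] = ("F", "F")  # destroy the G of G[G/A/S]
        if arch[gas_idx][1] == "G":
            arch[gas_idx] = ("A", "A")  # a trailing G would re-create a G[GA] pair
        protein = _arch_protein(arch)
        v = classify_toxin(protein)
        assert v.leader is None and not v.overall
        ann["arch"] = arch
        ann["cleavage_index"] = None
        return protein, ann

    # decoy_no_tail: hydrophobic 25-residue tail, no shoulder so the
    # zipper still starts at the mature terminus (flank rule intact)
    for _ in range(60):
        arch = _toxin_architecture(
            rng, params, leader_len=(17, 30), n_anchors=(5, 8), shoulder=False
        )
        ann = _arch_annotations(arch)
        tail_first = ann["zipper_anchors"][-1] + 1
        arch = arch[:tail_first] + [
            (_SHOULDER_ALPHA, _choice(rng, _SHOULDER_ALPHA)) for _ in range(25)
        ]
        protein = _arch_protein(arch)
        v = classify_toxin(protein)
        if v.length_ok and not v.cterm_ok and not v.overall and v.flank_ok:
            ann["arch"] = arch
            ann["length"] = len(protein)
            return protein, ann
    raise RuntimeError("could not draw a no-tail decoy")  # pragma: no cover


# ---------------------------------------------------------------------------
# nucleotide assembly


def _codon_weights(gc: float) -> Dict[str, np.ndarray]:
    pb = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    out = {}
    for aa, codons in _CODONS.items():
        w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def _reverse_translate(rng, protein: str, weights: Dict[str, np.ndarray]) -> str:
    parts = []
    for i, aa in enumerate(protein):
        if i == 0:
            parts.append("ATG")  # planted genes always start ATG
            continue
        codons = _CODONS[aa]
        parts.append(codons[int(rng.choice(len(codons), p=weights[aa]))])
    stop_w = np.array([0.5, 0.25, 0.25])
    parts.append(_STOP_CODONS[int(rng.choice(3, p=stop_w))])
    return "".join(parts)


def _random_dna(rng, n: int, gc: float) -> str:
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join("GCAT"[int(i)] for i in rng.choice(4, size=n, p=p))


def _intergenic(rng, n: int, gc: float) -> str:
    """Random spacer with the six-frame stop cassette every <=138 nt."""
    if n <= 0:
        return ""
    out = []
    remaining = n
    while remaining > 0:
        chunk = min(remaining, 138)
        if remaining > len(_STOP_CASSETTE) + chunk:
            out.append(_random_dna(rng, chunk, gc))
            out.append(_STOP_CASSETTE)
            remaining -= chunk + len(_STOP_CASSETTE)
        else:
            out.append(_random_dna(rng, remaining, gc))
            remaining = 0
    return "".join(out)[:n]


def _random_protein(rng, n: int) -> str:
    idx = rng.integers(0, 20, size=n)
    return "M" + "".join(AMINO_ACIDS[int(i)] for i in idx[1:])


def _mutate_protein(rng, protein: str, rate: float) -> str:
    out = [protein[0]]
    for aa in protein[1:]:
        if rng.random() < rate:
            out.append(AMINO_ACIDS[int(rng.integers(0, 20))])
        else:
            out.append(aa)
    return "".join(out)


@dataclass
class _Placed:
    element_id: str
    kind: str
    start: int
    end: int
    strand: str
    protein: str
    product: str


def _required_length(params: SynthParams) -> int:
    per_cluster = 2 * 2200 + 400 + 2 * 12_000  # operon + window both sides
    return params.n_true_clusters * (per_cluster + 10_000) + 35_000


def generate(params: Optional[SynthParams] = None, out_dir=None) -> SynthResult:
    """Generate the synthetic genome set, truth table and seed alignment.

    With ``out_dir`` set, writes ``genomes/*.fasta``, ``genomes/*.gbk``,
    ``truth.tsv``, ``seed_msa.afa``, ``t1ss_abc.afa``, ``t1ss_adaptor.afa``
    and a ``params.yaml`` echo.  Bit-identical for a fixed seed.
    """
    params = params or SynthParams()
    need = _required_length(params)
    if params.n_true_clusters > 0 and params.contig_len_nt < need:
        raise ValueError(
            f"contig_len_nt={params.contig_len_nt} too short for "
            f"{params.n_true_clusters} cluster(s); need >= {need}"
        )
    rng = np.random.default_rng(params.seed)
    weights = _codon_weights(params.gc_background)

    # one toxin family and two anchor reference families per run
    family_arch = _family_arch(rng, params)
    abc_ref = _random_protein(rng, params.abc_len)
    adaptor_ref = _random_protein(rng, params.adaptor_len)

    seed_rows = [
        _arch_protein(_mutate_member(rng, family_arch, params.mut_rate_seed))
        for _ in range(4)
    ]
    seed_msa = Msa(names=[f"seed{i+1}" for i in range(4)], rows=seed_rows)
    t1ss_refs = {
        "abc": Msa(
            names=[f"abc_ref{i+1}" for i in range(4)],
            rows=[_mutate_protein(rng, abc_ref, 0.05) for _ in range(4)],
        ),
        "adaptor": Msa(
            names=[f"adaptor_ref{i+1}" for i in range(4)],
            rows=[_mutate_protein(rng, adaptor_ref, 0.05) for _ in range(4)],
        ),
    }

    genomes: List[GenomeRecord] = []
    truth: List[TruthRecord] = []
    for g in range(params.n_genomes):
        gid = f"synthG{g+1:03d}"
        placed = _build_genome_layout(
            rng, params, gid, family_arch, abc_ref, adaptor_ref
        )
        seq, feats = _assemble_contig(rng, params, placed, weights)
        genomes.append(
            GenomeRecord(id=gid, description="synthetic contig", sequence=seq, features=feats)
        )
        for p in placed:
            truth.append(
                TruthRecord(
                    genome_id=gid,
                    element_id=p.element_id,
                    kind=p.kind,
                    start=p.start,
                    end=p.end,
                    strand=p.strand,
                    protein=p.protein,
                )
            )

    result = SynthResult(
        genomes=genomes, truth=truth, seed_msa=seed_msa, t1ss_refs=t1ss_refs, params=params
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _family_arch(rng, params):
    # family blueprint is itself a valid toxin
    for _ in range(60):
        arch = _toxin_architecture(rng, params)
        protein = _arch_protein(arch)
        ann = _arch_annotations(arch)
        mature = protein[ann["cleavage_index"] :]
        if (
            composition_stats(mature)["small_hydrophobic"] >= 0.65
            and classify_toxin(protein).overall
        ):
            return arch
    raise RuntimeError("family blueprint rejection loop exhausted")  # pragma: no cover


def _draw_member(rng, params, family_arch):
    for _ in range(60):
        arch = _mutate_member(rng, family_arch, params.mut_rate_member)
        protein = _arch_protein(arch)
        ann = _arch_annotations(arch)
        mature = protein[ann["cleavage_index"] :]
        if (
            composition_stats(mature)["small_hydrophobic"] >= 0.6
            and classify_toxin(protein).overall
        ):
            return protein, ann
    raise RuntimeError("member rejection loop exhausted")  # pragma: no cover


def _build_genome_layout(rng, params, gid, family_arch, abc_ref, adaptor_ref):
    """Choose coordinates for every planted element of one genome."""
    placed: List[_Placed] = []
    L = params.contig_len_nt
    n_cl = params.n_true_clusters
    centers = [
        int(L * (i + 1) / (n_cl + 1) + rng.integers(-3000, 3001)) for i in range(n_cl)
    ]
    tox_i = 0
    for ci, center in enumerate(centers):
        strand = "+" if rng.random() < 0.5 else "-"
        abc_prot = _mutate_protein(rng, abc_ref, params.anchor_mut_rate)
        ada_prot = _mutate_protein(rng, adaptor_ref, params.anchor_mut_rate)
        abc_nt = 3 * (len(abc_prot) + 1)
        ada_nt = 3 * (len(ada_prot) + 1)
        gap = int(rng.integers(60, 200))
        a_start = center - (abc_nt + gap + ada_nt) // 2
        placed.append(
            _Placed(f"{gid}_anchorA_c{ci+1}", "anchor_gene", a_start, a_start + abc_nt,
                    strand, abc_prot, "T1SS ABC transporter (synthetic)")
        )
        b_start = a_start + abc_nt + gap
        placed.append(
            _Placed(f"{gid}_anchorB_c{ci+1}", "anchor_gene", b_start, b_start + ada_nt,
                    strand, ada_prot, "T1SS membrane fusion adaptor (synthetic)")
        )
        span = (a_start, b_start + ada_nt)

        # window elements: true toxins + in-window decoys
        n_tox = 1 + int(rng.choice(3, p=np.array(params.toxins_per_cluster)))
        window_elems = []
        for _ in range(n_tox):
            tox_i += 1
            prot, _ann = _draw_member(rng, params, family_arch)
            window_elems.append((f"{gid}_toxin{tox_i}", "true_toxin", prot))
        for cls in DECOY_CLASSES:
            if cls == "decoy_no_anchor":
                continue
            for d in range(params.decoy_spec.get(cls, 0)):
                prot, _ann = make_decoy(rng, cls, params)
                window_elems.append((f"{gid}_{cls}{d+1}_c{ci+1}", cls, prot))
        order = rng.permutation(len(window_elems))
        left_cur, right_cur = span[0], span[1]
        for rank, idx in enumerate(order):
            eid, kind, prot = window_elems[int(idx)]
            nt_len = 3 * (len(prot) + 1)
            gap = int(rng.integers(300, 900))
            estrand = "+" if rng.random() < 0.5 else "-"
            if rank % 2 == 0:  # left of the operon
                end = left_cur - gap
                start = end - nt_len
                left_cur = start
            else:
                start = right_cur + gap
                end = start + nt_len
                right_cur = end
            placed.append(_Placed(eid, kind, start, end, estrand, prot, kind))
        # sanity: window elements must sit within 9.5 kb of the span
        assert span[0] - left_cur <= 9_500 and right_cur - span[1] <= 9_500

    # far-from-anchor decoys, >= 15 kb from every anchor span
    n_far = params.decoy_spec.get("decoy_no_anchor", 0) * max(n_cl, 1)
    far_cur = 3_000
    first_span_start = min((p.start for p in placed), default=L)
    for d in range(n_far):
        prot, _ann = make_decoy(rng, "decoy_no_anchor", params)
        nt_len = 3 * (len(prot) + 1)
        start = far_cur + int(rng.integers(0, 1500))
        end = start + nt_len
        if end > first_span_start - 15_000:
            raise ValueError("contig too short to place far decoys 15 kb from anchors")
        estrand = "+" if rng.random() < 0.5 else "-"
        placed.append(_Placed(f"{gid}_decoy_no_anchor{d+1}", "decoy_no_anchor",
                              start, end, estrand, prot, "decoy_no_anchor"))
        far_cur = end + 1_000
    placed.sort(key=lambda p: p.start)
    for a, b in zip(placed, placed[1:]):
        if a.end > b.start:
            raise AssertionError("planted elements overlap")  # pragma: no cover
    return placed


def _assemble_contig(rng, params, placed, weights):
    seq_parts = []
    feats = []
    cursor = 0
    for i, p in enumerate(placed):
        spacer = _intergenic(rng, p.start - cursor, params.gc_background)
        # seal the reading frame: an in-frame stop flush against each gene
        # end prevents chance upstream starts from extending a planted ORF
        # beyond its truth interval (and past its designed leader)
        if i > 0 and placed[i - 1].strand == "-" and len(spacer) >= 3:
            spacer = "TTA" + spacer[3:]  # revcomp stop for the previous - gene
        if p.strand == "+" and len(spacer) >= 3:
            spacer = spacer[:-3] + "TAA"
        seq_parts.append(spacer)
        gene = _reverse_translate(rng, p.protein, weights)
        assert len(gene) == p.end - p.start
        if p.strand == "-":
            gene = revcomp(gene)
        seq_parts.append(gene)
        cursor = p.end
        feats.append(
            Feature(
                id=p.element_id,
                kind="CDS",
                contig_id=p.element_id.split("_")[0],
                start=p.start,
                end=p.end,
                strand=p.strand,
                product=p.product,
            )
        )
    last = _intergenic(rng, params.contig_len_nt - cursor, params.gc_background)
    if placed and placed[-1].strand == "-" and len(last) >= 3:
        last = "TTA" + last[3:]
    seq_parts.append(last)
    return "".join(seq_parts), feats


def _write_outputs(result: SynthResult, out: Path) -> None:
    gdir = out / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for g in result.genomes:
        write_fasta([(g.id, g.sequence, g.description)], gdir / f"{g.id}.fasta")
        rec = SeqRecord(Seq(g.sequence), id=g.id, description=g.description)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["date"] = "01-JAN-2000"  # fixed: outputs are byte-stable
        for f in g.features:
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                    type="CDS",
                    qualifiers={"locus_tag": [f.id], "product": [f.product]},
                )
            )
        with open(gdir / f"{g.id}.gbk", "w") as fh:
            SeqIO.write([rec], fh, "genbank")
    result.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
    write_fasta(
        list(zip(result.seed_msa.names, result.seed_msa.rows)), out / "seed_msa.afa"
    )
    for key, msa in result.t1ss_refs.items():
        write_fasta(list(zip(msa.names, msa.rows)), out / f"t1ss_{key}.afa")
    with open(out / "params.yaml", "w") as fh:
        d = dataclasses.asdict(result.params)
        yaml.safe_dump(d, fh, sort_keys=False)
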