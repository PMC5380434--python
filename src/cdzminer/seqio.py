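"""Sequence and annotation I/O.

All coordinates inside the package are 0-based half-open intervals on
linear contigs; GenBank (1-based inclusive) and GFF3 (1-based inclusive)
are converted at this boundary and nowhere else.  Parsing of FASTA and
GenBank flat files is delegated to Biopython; the thin wrappers here
enforce the package's coordinate and alphabet conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Feature",
    "Window",
    "EmptyInputError",
    "FastaParseError",
    "read_fasta",
    "read_genbank",
    "read_bed",
    "extract_window",
    "revcomp",
    "write_fasta",
    "write_gff3",
    "read_gff3",
]

_IUPAC_DNA = set("ACGTUNRYSWKMBDHV")
_NON_ACGT = str.maketrans({c: "N" for c in "URYSWKMBDHV"})


class EmptyInputError(ValueError):
    """Raised when a sequence file contains no records."""


class FastaParseError(ValueError):
    """Raised on malformed FASTA content; the message names the line."""


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a contig (0-based half-open)."""

    id: str
    kind: str  # "CDS" | "anchor" | "toxin_candidate" | "other"
    contig_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    product: str = ""
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.id}: bad interval [{self.start},{self.end})")
        if self.kind == "CDS" and self.strand not in "+-":
            raise ValueError(f"CDS feature {self.id} lacks a strand")

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A contig with its sequence and any parsed features."""

    id: str
    description: str
    sequence: str
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome record {self.id} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Window:
    """An anchor-centred slice of a contig, clipped to contig bounds."""

    contig_id: str
    start: int
    end: int
    anchor_ref: str

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


def _clean_dna(seq: str, *, path: str, line_of: dict) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC_DNA
    if bad:
        ch = sorted(bad)[0]
        line = line_of.get(ch, "?")
        raise FastaParseError(f"{path}: non-IUPAC character {ch!r} (line {line})")
    # ambiguity codes are kept only as N internally; U -> T
    return seq.replace("U", "T").translate(_NON_ACGT)


def read_fasta(path) -> list:
    """Read a nucleotide FASTA into :class:`GenomeRecord` objects.

    Sequences are uppercased and IUPAC ambiguity codes collapsed to N.
    An empty file raises :class:`EmptyInputError`; any non-IUPAC
    character raises :class:`FastaParseError` naming the line.
    """
    path = str(path)
    # map of first line containing each unusual character, for error messages
    line_of: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            for ch in set(line.strip().upper()) - set("ACGT"):
                line_of.setdefault(ch, i)
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=_clean_dna(str(rec.seq), path=path, line_of=line_of),
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def read_genbank(path) -> list:
    """Read a GenBank flat file; CDS coordinates become 0-based half-open.

    Biopython already exposes GenBank locations half-open; compound
    (``join``) locations are recorded as one spanning interval carrying
    a ``"join"`` flag.
    """
    path = str(path)
    records = []
    for rec in SeqIO.parse(path, "genbank"):
        feats = []
        n = 0
        for f in rec.features:
            if f.type != "CDS":
                continue
            n += 1
            flags = frozenset({"join"}) if len(f.location.parts) > 1 else frozenset()
            fid = (
                f.qualifiers.get("locus_tag", [None])[0]
                or f.qualifiers.get("protein_id", [None])[0]
                or f"{rec.id}_CDS{n}"
            )
            feats.append(
                Feature(
                    id=fid,
                    kind="CDS",
                    contig_id=rec.id,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand="+" if f.location.strand >= 0 else "-",
                    product=f.qualifiers.get("product", [""])[0],
                    flags=flags,
                )
            )
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=str(rec.seq).upper(),
                features=feats,
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: no GenBank records found")
    return records


def read_bed(path) -> list:
    """Read user-supplied anchor intervals from BED (0-based half-open)."""
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: need >=3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"anchor{i}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            feats.append(
                Feature(
                    id=name,
                    kind="anchor",
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return feats


def extract_window(genome: GenomeRecord, anchor: Feature, flank_nt: int = 10_000):
    """Slice ``flank_nt`` on each side of an anchor, clipped to the contig.

    Returns ``(Window, subsequence)``.  Raises :class:`KeyError` if the
    anchor names a different contig.
    """
    if flank_nt <= 0:
        raise ValueError("flank_nt must be positive")
    if anchor.contig_id != genome.id:
        raise KeyError(
            f"anchor {anchor.id} is on contig {anchor.contig_id!r}, not {genome.id!r}"
        )
    start = max(0, anchor.start - flank_nt)
    end = min(len(genome), anchor.end + flank_nt)
    win = Window(contig_id=genome.id, start=start, end=end, anchor_ref=anchor.id)
    return win, genome.sequence[start:end]


def revcomp(dna: str) -> str:
    """Reverse complement (IUPAC-aware, via Biopython)."""
    return str(Seq(dna).reverse_complement())


def write_fasta(records: Iterable, path) -> None:
    """Write ``(id, sequence)`` pairs or objects with .id/.sequence as FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec[0], rec[1]
            desc = rec[2] if len(rec) > 2 else ""
        else:
            rid, seq, desc = rec.id, rec.sequence, getattr(rec, "description", "")
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def _gff3_row(feat: Feature, ftype: str, attrs: dict) -> str:
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join(
        [
            feat.contig_id,
            "cdzminer",
            ftype,
            str(feat.start + 1),  # GFF3 is 1-based inclusive
            str(feat.end),
            ".",
            feat.strand,
            ".",
            attr_s,
        ]
    )


def write_gff3(clusters: Sequence, path) -> None:
    """Write cluster calls as GFF3 (anchor genes + toxin candidates).

    ``clusters`` is duck-typed: each element exposes ``cluster_id``,
    ``anchor.genes`` (Features) and ``toxins`` (objects with a
    ``feature`` Feature).  An empty list yields a valid header-only file.
    """
    lines = ["##gff-version 3"]
    for cl in clusters:
        cid = cl.cluster_id
        for gene in cl.anchor.genes:
            lines.append(
                _gff3_row(gene, "gene", {"ID": gene.id, "cluster_id": cid, "role": "t1ss_anchor"})
            )
        for tox in cl.toxins:
            feat = tox.feature
            lines.append(
                _gff3_row(
                    feat,
                    "gene",
                    {"ID": feat.id, "cluster_id": cid, "role": "toxin_candidate"},
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> list:
    """Read back a cdzminer GFF3 into plain Features (for round-trips)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, _src, _type, start, end, _score, strand, _phase, attrs = line.split("\t")
            kv = dict(p.split("=", 1) for p in attrs.split(";") if p)
            kind = "anchor" if kv.get("role") == "t1ss_anchor" else "toxin_candidate"
            feats.append(
                Feature(
                    id=kv.get("ID", "?"),
                    kind=kind,
                    contig_id=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    product=kv.get("cluster_id", ""),
                )
            )
    return feats
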