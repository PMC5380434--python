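"""Six-frame enumeration of candidate ORFs inside anchor windows.

The discovery procedure translates *all possible* ORFs of 60-200
residues around each type I secretion system anchor, so the scan here
reports every start->stop pair (nested starts individually) on both
strands, restricted to ORFs fully contained in the window.  Translation
uses the bacterial genetic code (table 11); the initiator codon is
rendered as M regardless of whether it is ATG, GTG or TTG, and codons
containing N translate to X and never count as stops.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from Bio.Seq import Seq

from .config import OrfParams
from .seqio import Feature, revcomp

__all__ = ["OrfCall", "enumerate_orfs", "orfs_to_fasta_records"]

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfCall:
    """A translated candidate ORF; the nt interval includes the stop codon."""

    contig_id: str
    start: int
    end: int  # 0-based half-open, stop codon included
    strand: str
    frame: int  # 0-2 on its own strand
    protein: str
    start_codon: str

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}:{self.strand}"

    @property
    def stop_pos(self) -> int:
        """Contig coordinate identifying the stop codon (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def feature(self) -> Feature:
        return Feature(
            id=self.id,
            kind="toxin_candidate",
            contig_id=self.contig_id,
            start=self.start,
            end=self.end,
            strand=self.strand,
        )


def _translate(codons_nt: str, table: int) -> str:
    prot = str(Seq(codons_nt).translate(table=table))
    # the initiator is methionine whatever the start codon
    return "M" + prot[1:] if prot else prot


def _scan_strand(seq: str, strand: str, params: OrfParams, contig_id: str, offset: int, seqlen: int) -> List[OrfCall]:
    calls: List[OrfCall] = []
    starts = set(params.start_codons)
    for frame in range(3):
        open_starts: List[int] = []  # codon start positions since last stop
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                chosen: Optional[int] = None
                for s in open_starts:
                    n_res = (pos - s) // 3
                    if params.min_res <= n_res <= params.max_res:
                        if params.all_starts:
                            calls.append(
                                _make_call(seq, s, pos + 3, strand, frame, params, contig_id, offset, seqlen)
                            )
                        elif chosen is None:
                            chosen = s  # earliest qualifying start = longest ORF
                if chosen is not None and not params.all_starts:
                    calls.append(
                        _make_call(seq, chosen, pos + 3, strand, frame, params, contig_id, offset, seqlen)
                    )
                open_starts = []
            elif codon in starts:
                open_starts.append(pos)
    return calls


def _make_call(seq, s, e, strand, frame, params, contig_id, offset, seqlen) -> OrfCall:
    protein = _translate(seq[s : e - 3], params.table)
    if strand == "+":
        start, end = offset + s, offset + e
    else:  # mirror through the window
        start, end = offset + seqlen - e, offset + seqlen - s
    return OrfCall(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        protein=protein,
        start_codon=seq[s : s + 3],
    )


def enumerate_orfs(
    window_seq: str,
    params: Optional[OrfParams] = None,
    *,
    contig_id: str = "window",
    offset: int = 0,
) -> List[OrfCall]:
    """Enumerate candidate ORFs in all six frames of ``window_seq``.

    Every start codon whose first in-frame stop lies inside the window
    and whose translated length (stop excluded) is within
    ``[min_res, max_res]`` yields one call; with ``all_starts=False``
    only the longest qualifying ORF per (strand, stop) is kept.
    ``offset`` shifts reported coordinates into contig space.  Output
    order is deterministic: contig position, then strand (+ before -).
    """
    params = params or OrfParams()
    window_seq = window_seq.upper()
    n = len(window_seq)
    calls = _scan_strand(window_seq, "+", params, contig_id, offset, n)
    calls += _scan_strand(revcomp(window_seq), "-", params, contig_id, offset, n)
    calls.sort(key=lambda c: (c.start, c.strand == "-", c.end))
    return calls


def orfs_to_fasta_records(orfs) -> List[Tuple[str, str]]:
    """(header, protein) pairs with headers encoding contig:start-end:strand."""
    return [(orf.id, orf.protein) for orf in orfs]
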