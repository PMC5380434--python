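"""Rule-based classifier for Cdz-like glycine-zipper toxins.

A candidate toxin must satisfy, jointly:

(i)   full translated length of 60-151 residues;
(ii)  an N-terminal secretion leader ending in the dipeptide G[G/A/S],
      cleaved 10-35 residues in (mature form = everything after it);
(iii) one or two glycine-zipper motifs - glycine anchors at exact
      period 4 (GxxxGxxxG...) with no proline, cysteine or charged
      residue at the intervening positions - flanked, but never
      interrupted, by a proline or charged residue;
(iv)  a short, charged/polar C-terminal tail after the last zipper.

Candidates whose pre-tail mature region carries dense spans of
polar/charged residues are also filtered out.  Each criterion is a pure
boolean computed independently; the overall verdict is their
conjunction, so tightening any single threshold can only shrink the set
of passing sequences.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .config import ClassifierParams, ResidueClasses

__all__ = [
    "LeaderCall",
    "ZipperMotif",
    "FeatureVerdict",
    "detect_leader",
    "find_zippers",
    "find_interrupted_runs",
    "check_flanks",
    "check_cterm",
    "check_polar_spans",
    "classify_toxin",
    "composition_stats",
]


@dataclass(frozen=True)
class LeaderCall:
    """A leader-peptide cleavage point; the mature protein starts here."""

    cleavage_index: int
    dipeptide: str  # 'G' followed by one of G/A/S


@dataclass(frozen=True)
class ZipperMotif:
    """Glycine anchors at exact period 4, indices relative to the mature form."""

    anchors: tuple  # residue indices
    interrupted: bool = False

    @property
    def span(self):
        return (self.anchors[0], self.anchors[-1])

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class FeatureVerdict:
    """Per-criterion record of the toxin classifier."""

    length_ok: bool
    leader: Optional[LeaderCall]
    zippers: List[ZipperMotif]
    zipper_count_ok: bool
    zipper_uninterrupted: bool
    flank_ok: bool
    cterm_ok: bool
    polar_span_ok: bool

    @property
    def overall(self) -> bool:
        return (
            self.length_ok
            and self.leader is not None
            and self.zipper_count_ok
            and self.zipper_uninterrupted
            and self.flank_ok
            and self.cterm_ok
            and self.polar_span_ok
        )

    def as_dict(self) -> dict:
        return {
            "length_ok": self.length_ok,
            "leader_ok": self.leader is not None,
            "zipper_count_ok": self.zipper_count_ok,
            "zipper_uninterrupted": self.zipper_uninterrupted,
            "flank_ok": self.flank_ok,
            "cterm_ok": self.cterm_ok,
            "polar_span_ok": self.polar_span_ok,
            "overall": self.overall,
        }


def detect_leader(protein: str, min_leader: int = 10, max_leader: int = 35) -> Optional[LeaderCall]:
    """First cleavage point i in [min_leader, max_leader] with
    protein[i-2] == 'G' and protein[i-1] in {G, A, S}; None if absent."""
    hi = min(max_leader, len(protein))
    for i in range(min_leader, hi + 1):
        if i < 2:
            continue
        if protein[i - 2] == "G" and protein[i - 1] in "GAS":
            return LeaderCall(cleavage_index=i, dipeptide=protein[i - 2 : i])
    return None


def _period4_runs(mature: str, anchor_set, min_anchors: int) -> List[tuple]:
    """Maximal chains of anchor residues at exact period 4 (any intervening)."""
    n = len(mature)
    runs = []
    anchors = [i for i, c in enumerate(mature) if c in anchor_set]
    anchor_pos = set(anchors)
    seen = set()
    for a in anchors:
        if a in seen:
            continue
        chain = [a]
        nxt = a + 4
        while nxt < n and nxt in anchor_pos:
            chain.append(nxt)
            seen.add(nxt)
            nxt += 4
        if len(chain) >= min_anchors and (a - 4) not in anchor_pos:
            runs.append(tuple(chain))
    return runs


def find_zippers(
    mature: str, classes: Optional[ResidueClasses] = None, min_anchors: int = 3
) -> List[ZipperMotif]:
    """Maximal uninterrupted glycine-zipper motifs in the mature protein.

    A motif is a maximal chain of >= ``min_anchors`` anchor residues at
    exact period 4 whose intervening positions carry no forbidden
    residue (P, C, charged).  An interruption splits a chain: the clean
    maximal sub-chains on either side are reported if long enough.
    """
    classes = classes or ResidueClasses()
    n = len(mature)
    motifs: List[ZipperMotif] = []
    # chains at period 4 with clean gaps only
    anchor_pos = {i for i, c in enumerate(mature) if c in classes.zipper_anchor}

    def gap_clean(a: int) -> bool:
        return all(mature[a + k] not in classes.forbidden_in_zipper for k in (1, 2, 3))

    starts = sorted(anchor_pos)
    used = set()
    for a in starts:
        if a in used:
            continue
        # is a clean chain extending left? then not maximal from here
        if (a - 4) in anchor_pos and gap_clean(a - 4):
            continue
        chain = [a]
        cur = a
        while (cur + 4) in anchor_pos and cur + 4 < n and gap_clean(cur):
            cur += 4
            chain.append(cur)
            used.add(cur)
        if len(chain) >= min_anchors:
            motifs.append(ZipperMotif(anchors=tuple(chain)))
    motifs.sort(key=lambda m: m.anchors[0])
    return motifs


def find_interrupted_runs(
    mature: str, classes: Optional[ResidueClasses] = None, min_anchors: int = 3
) -> List[tuple]:
    """Period-4 anchor chains of zipper size that carry a forbidden
    residue (P/C/charged) at an intervening position - interrupted
    zippers, which disqualify a candidate."""
    classes = classes or ResidueClasses()
    bad = []
    for chain in _period4_runs(mature, classes.zipper_anchor, min_anchors):
        for a in chain[:-1]:
            if any(mature[a + k] in classes.forbidden_in_zipper for k in (1, 2, 3)):
                bad.append(chain)
                break
    return bad


def check_flanks(
    mature: str,
    motif: ZipperMotif,
    classes: Optional[ResidueClasses] = None,
    flank_window: int = 3,
) -> bool:
    """True iff a proline or charged residue lies within ``flank_window``
    residues of either motif end, or the motif end coincides with a
    sequence terminus."""
    classes = classes or ResidueClasses()
    flankers = classes.charged | {"P"}
    first, last = motif.span
    if first - flank_window <= 0 or last + flank_window >= len(mature) - 1:
        return True
    before = mature[max(0, first - flank_window) : first]
    after = mature[last + 1 : last + 1 + flank_window]
    return any(c in flankers for c in before) or any(c in flankers for c in after)


def check_cterm(
    mature: str,
    motifs: List[ZipperMotif],
    classes: Optional[ResidueClasses] = None,
    max_tail: int = 20,
    min_charged_polar_frac: float = 0.4,
) -> bool:
    """Short charged/polar C-terminal region after the last zipper anchor."""
    if not motifs:
        raise ValueError("check_cterm needs at least one zipper motif")
    classes = classes or ResidueClasses()
    last_anchor = motifs[-1].anchors[-1]
    tail = mature[last_anchor + 1 :]
    if not tail:
        return True
    if len(tail) > max_tail:
        return False
    frac = sum(c in classes.charged or c in classes.polar for c in tail) / len(tail)
    return frac >= min_charged_polar_frac


def check_polar_spans(
    mature: str,
    window: int = 6,
    max_charged_polar: int = 4,
    classes: Optional[ResidueClasses] = None,
    tail_start: Optional[int] = None,
) -> bool:
    """False iff any length-``window`` window of the pre-tail mature
    region holds more than ``max_charged_polar`` charged+polar residues."""
    classes = classes or ResidueClasses()
    region = mature if tail_start is None else mature[:tail_start]
    hot = classes.charged | classes.polar
    flags = [c in hot for c in region]
    for i in range(0, len(flags) - window + 1):
        if sum(flags[i : i + window]) > max_charged_polar:
            return False
    return True


def classify_toxin(protein: str, params: Optional[ClassifierParams] = None) -> FeatureVerdict:
    """Evaluate the full four-part toxin classifier on a translated ORF.

    The length band applies to the full protein (leader included); all
    other criteria apply to the mature form.  When no leader is found
    the remaining criteria are evaluated on the full protein so the
    verdict still reports which other rules the sequence would meet.
    """
    p = params or ClassifierParams()
    cls = p.classes
    length_ok = p.min_len <= len(protein) <= p.max_len
    leader = (
        detect_leader(protein, p.min_leader, p.max_leader)
        if len(protein) > p.max_leader or len(protein) > p.min_leader
        else None
    )
    mature = protein[leader.cleavage_index :] if leader else protein
    zippers = find_zippers(mature, cls, p.min_anchors)
    zipper_count_ok = 1 <= len(zippers) <= p.max_motifs
    interrupted = find_interrupted_runs(mature, cls, p.min_anchors)
    zipper_uninterrupted = not interrupted
    if zippers:
        if p.require_flank:
            flank_ok = all(
                check_flanks(mature, m, cls, p.flank_window) for m in zippers
            )
        else:
            flank_ok = True
        cterm_ok = check_cterm(mature, zippers, cls, p.max_tail, p.min_charged_polar_frac)
        tail_start = zippers[-1].anchors[-1] + 1
    else:
        flank_ok = False
        cterm_ok = False
        tail_start = None
    polar_span_ok = check_polar_spans(
        mature, p.polar_span_window, p.polar_span_max, cls, tail_start
    )
    return FeatureVerdict(
        length_ok=length_ok,
        leader=leader,
        zippers=zippers,
        zipper_count_ok=zipper_count_ok,
        zipper_uninterrupted=zipper_uninterrupted,
        flank_ok=flank_ok,
        cterm_ok=cterm_ok,
        polar_span_ok=polar_span_ok,
    )


def composition_stats(
    protein: str,
    classes: Optional[ResidueClasses] = None,
    mature_only: bool = False,
    leader_bounds=(10, 35),
) -> dict:
    """Fractions of small-hydrophobic, charged and polar residues.

    With ``mature_only`` the leader is removed first via
    :func:`detect_leader`; a missing leader is an error naming the
    sequence.
    """
    classes = classes or ResidueClasses()
    seq = protein
    if mature_only:
        call = detect_leader(protein, *leader_bounds)
        if call is None:
            raise ValueError(
                f"no G[G/A/S] leader found in {protein[:20]}...; cannot take mature form"
            )
        seq = protein[call.cleavage_index :]
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    return {
        "small_hydrophobic": sum(c in classes.small_hydrophobic for c in seq) / n,
        "charged": sum(c in classes.charged for c in seq) / n,
        "polar": sum(c in classes.polar for c in seq) / n,
        "length": n,
    }
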