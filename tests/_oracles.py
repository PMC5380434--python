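"""Independent brute-force oracles used by the test suite.

Each oracle recomputes an operation's result by the most literal means
available (exhaustive enumeration, regex scanning, direct counting) and
stays independent of the library code paths it checks.
"""
from __future__ import annotations

import math
import re
from typing import List, Tuple

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# six-frame ORF enumeration


def brute_orfs(
    seq: str,
    min_res: int,
    max_res: int,
    starts=("ATG", "GTG", "TTG"),
    all_starts: bool = True,
) -> set:
    """Set of (start, end, strand) ORF intervals (stop included) found by
    chopping each frame's codon string at stops and scanning segments."""
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            stop_idx = [i for i, c in enumerate(codons) if c in _STOPS]
            prev = -1
            for si in stop_idx:
                segment = range(prev + 1, si)
                found = []
                for ci in segment:
                    if codons[ci] in starts:
                        n_res = si - ci
                        if min_res <= n_res <= max_res:
                            found.append(ci)
                keep = found if all_starts else found[:1]
                for ci in keep:
                    a = frame + 3 * ci
                    b = frame + 3 * si + 3
                    if strand == "+":
                        out.add((a, b, "+"))
                    else:
                        out.add((n - b, n - a, "-"))
                prev = si
    return out


# ---------------------------------------------------------------------------
# classifier rules


def brute_leader(protein: str, lo: int = 10, hi: int = 35):
    for i in range(lo, min(hi, len(protein)) + 1):
        if i >= 2 and protein[i - 2] == "G" and protein[i - 1] in "GAS":
            return i
    return None


def brute_zippers(mature: str, min_anchors: int = 3) -> set:
    """Maximal clean period-4 G runs via regex with overlap lookahead."""
    pat = re.compile(r"(?=(G(?:[^PCDEKR]{3}G)+))")
    cands = {}
    for m in pat.finditer(mature):
        s = m.start()
        cands[s] = max(cands.get(s, 0), len(m.group(1)))
    keep = set()
    for s, l in cands.items():
        if (l - 1) // 4 + 1 < min_anchors:
            continue
        parent = cands.get(s - 4)
        if parent is not None and parent >= l + 4:
            continue  # sub-run of a longer clean run
        anchors = tuple(range(s, s + l, 4))
        keep.add(anchors)
    return keep


def brute_polar_spans_ok(region: str, window: int = 6, max_cp: int = 4) -> bool:
    hot = set("DEKRSTNQHY")
    for i in range(0, len(region) - window + 1):
        if sum(c in hot for c in region[i : i + window]) > max_cp:
            return False
    return True


def brute_tail_ok(tail: str, max_tail: int = 20, min_frac: float = 0.4) -> bool:
    if not tail:
        return True
    if len(tail) > max_tail:
        return False
    return sum(c in set("DEKRSTNQHY") for c in tail) / len(tail) >= min_frac


# ---------------------------------------------------------------------------
# consensus combiner


def brute_consensus(matrix: List[List[bool]], k_min: int) -> Tuple[tuple, tuple]:
    n = len(matrix[0])
    support = tuple(sum(row[i] for row in matrix) for i in range(n))
    flagged = [s >= k_min for s in support]
    intervals = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return tuple(intervals), support


# ---------------------------------------------------------------------------
# profile-HMM path enumeration (tiny models only)


def enumerate_paths_score(hmm, seq: str, aggregate: str) -> float:
    """log2 score by explicit enumeration of every glocal state path.

    ``aggregate`` is 'sum' (forward) or 'max' (Viterbi).  Tractable for
    L <= 3 and sequences of length <= 4.
    """
    L, n = hmm.L, len(seq)
    lo = hmm.emission_log_odds(seq)

    def lg(x: float) -> float:
        return math.log2(x) if x > 0 else -math.inf

    terms: List[float] = []

    def trans(last, st, node):
        if last[0] == "B":
            return lg(hmm.t_bm) if st == "M" else lg(hmm.t_bd)
        j = node - 1  # arrays are indexed by source node - 1
        if last[0] == "M":
            return lg(hmm.t_mm[j - 1]) if st == "M" else lg(hmm.t_md[j - 1])
        if last[0] == "I":
            return lg(hmm.t_im[j - 1]) if st == "M" else -math.inf
        return lg(hmm.t_dm[j - 1]) if st == "M" else lg(hmm.t_dd[j - 1])

    def cover(node, i, logp, last):
        if node == L + 1:
            terms.append(logp)
            return
        for st in ("M", "D"):
            lp = trans(last, st, node)
            if lp == -math.inf:
                continue
            if st == "M":
                if i >= n:
                    continue
                after_insert(node, i + 1, logp + lp + lo[i, node - 1], ("M", node))
            else:
                after_insert(node, i, logp + lp, ("D", node))

    def after_insert(node, i, logp, last):
        if node >= L:
            cover(node + 1, i, logp, last)
            return
        cover(node + 1, i, logp, last)
        if last[0] in ("M", "I") and i < n:
            lp = lg(hmm.t_mi[node - 1]) if last[0] == "M" else lg(hmm.t_ii[node - 1])
            if lp > -math.inf:
                after_insert(node, i + 1, logp + lp, ("I", node))

    for entry in range(n + 1):
        cover(1, entry, 0.0, ("B", 0))
    if not terms:
        return -math.inf
    if aggregate == "max":
        return max(terms)
    m = max(terms)
    return m + math.log2(sum(2 ** (t - m) for t in terms))
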