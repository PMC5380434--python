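"""Aggregation-propensity consensus over pluggable per-residue predictors.

External aggregation predictors (AmylPred 2, WALZ, MetAmyl, PASTA 2.0,
...) are consumed as pre-exported boolean per-residue tracks; a residue
is called aggregation-prone when at least ``k_min`` (default 3) of the
tracks agree, and flagged residues are merged into maximal intervals.
A simple hydropathy-window predictor is built in so the combiner can be
exercised without any external tool.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "PredictorTrack",
    "ConsensusCall",
    "consensus",
    "hydrophobic_window_predictor",
    "read_tracks",
    "write_tracks",
    "KYTE_DOOLITTLE",
]

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PredictorTrack:
    """One predictor's boolean call per residue of one protein."""

    predictor_name: str
    seq_id: str
    calls: tuple

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class ConsensusCall:
    """Maximal aggregation-prone intervals (0-based half-open) + support."""

    intervals: tuple  # of (start, end)
    support: tuple  # per-residue count of agreeing predictors


def consensus(tracks: Sequence[PredictorTrack], k_min: int = 3) -> ConsensusCall:
    """Residue flagged iff >= ``k_min`` tracks call it; merged maximally.

    Track order never changes the result.  Unequal track lengths raise
    a ValueError naming the offending tracks.
    """
    if len(tracks) < k_min:
        raise ValueError(f"need at least k_min={k_min} tracks, got {len(tracks)}")
    lengths = {len(t) for t in tracks}
    if len(lengths) > 1:
        names = ", ".join(f"{t.predictor_name}({len(t)})" for t in tracks)
        raise ValueError(f"tracks have unequal lengths: {names}")
    mat = np.array([t.calls for t in tracks], dtype=bool)
    support = mat.sum(axis=0)
    flagged = support >= k_min
    intervals: List[Tuple[int, int]] = []
    start = None
    for i, f in enumerate(flagged):
        if f and start is None:
            start = i
        elif not f and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(flagged)))
    return ConsensusCall(intervals=tuple(intervals), support=tuple(int(s) for s in support))


def hydrophobic_window_predictor(
    protein: str, window: int = 7, cutoff: float = 1.5, name: str = "hydropathy"
) -> PredictorTrack:
    """Mean Kyte-Doolittle hydropathy in a centred window vs a cutoff.

    Edges use truncated windows.  ``window`` must be odd.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    vals = [KYTE_DOOLITTLE.get(c, 0.0) for c in protein]
    calls = []
    n = len(vals)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        calls.append(sum(vals[lo:hi]) / (hi - lo) >= cutoff)
    return PredictorTrack(predictor_name=name, seq_id="", calls=tuple(calls))


def read_tracks(path) -> List[PredictorTrack]:
    """Read per-residue tracks from TSV: predictor, seq id, 0/1 string."""
    tracks = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {i}: expected 3 TSV columns, got {len(parts)}")
            name, sid, bits = parts
            if not bits or set(bits) - {"0", "1"}:
                raise ValueError(f"{path}: line {i}: calls must be a nonempty 0/1 string")
            tracks.append(
                PredictorTrack(
                    predictor_name=name, seq_id=sid, calls=tuple(c == "1" for c in bits)
                )
            )
    return tracks


def write_tracks(tracks: Sequence[PredictorTrack], path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            bits = "".join("1" if c else "0" for c in t.calls)
            fh.write(f"{t.predictor_name}\t{t.seq_id}\t{bits}\n")
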