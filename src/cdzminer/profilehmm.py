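"""Profile hidden Markov models over protein alphabets.

This is the scoring engine behind the iterative toxin search: a
match/insert/delete profile is estimated from a seed alignment and
candidate proteins are scored in bits (log2 odds against a background
residue model).  Scoring is *glocal* - global in the model, local in
the sequence - so a hit's secretion leader and tail outside the zipper
core carry no penalty.

Model structure (per match node j = 1..L):

* match state ``M_j`` with its own 20-way emission distribution;
* insert state ``I_j`` (j < L) emitting background residues;
* mute delete state ``D_j``.

Transitions follow the usual profile topology: ``M->{M,I,D}``,
``I->{M,I}``, ``D->{M,D}``, entry ``B->{M1,D1}``, exit from ``M_L``/
``D_L``.  All scores are log2; the forward score sums over paths and
entry/exit points, the Viterbi score maximises, so forward >= Viterbi
always.  Residues outside the 20-letter alphabet (X and friends) score
as background (0 bits) everywhere.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO

from .config import AMINO_ACIDS

__all__ = [
    "Msa",
    "ProfileHmm",
    "HmmHit",
    "ModelBuildError",
    "read_msa",
    "build_profile",
    "score_forward",
    "score_viterbi",
    "align_viterbi",
    "calibrate_threshold",
    "sample_background_sequence",
    "write_hmmer3",
    "BuiltinEngine",
    "PyhmmerEngine",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG_INF = -np.inf

# Default background amino-acid frequencies (Swiss-Prot-like composition).
_BACKGROUND = np.array(
    [
        0.0787945,  # A
        0.0151600,  # C
        0.0535222,  # D
        0.0668298,  # E
        0.0397062,  # F
        0.0695071,  # G
        0.0229198,  # H
        0.0590092,  # I
        0.0594422,  # K
        0.0963728,  # L
        0.0237718,  # M
        0.0414386,  # N
        0.0482904,  # P
        0.0395639,  # Q
        0.0540978,  # R
        0.0683364,  # S
        0.0540687,  # T
        0.0673417,  # V
        0.0114135,  # W
        0.0304133,  # Y
    ]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()


class ModelBuildError(ValueError):
    """Raised when a profile cannot be estimated from an alignment."""


@dataclass
class Msa:
    """A protein multiple alignment ('-' gaps), rows all the same length."""

    names: List[str]
    rows: List[str]
    match_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in count")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(widths)}")
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def compute_match_mask(self, gap_threshold: float = 0.5) -> np.ndarray:
        """Columns whose gap fraction is <= ``gap_threshold`` are match columns."""
        cols = np.array([[c == "-" for c in row] for row in self.rows])
        gap_frac = cols.mean(axis=0)
        return gap_frac <= gap_threshold

    def project_to_match(self, mask: np.ndarray) -> "Msa":
        idx = np.flatnonzero(mask)
        return Msa(
            names=list(self.names),
            rows=["".join(row[i] for i in idx) for row in self.rows],
            match_mask=np.ones(len(idx), dtype=bool),
        )

    def appended(self, names: Sequence[str], rows: Sequence[str]) -> "Msa":
        return Msa(names=list(self.names) + list(names), rows=list(self.rows) + list(rows))


def read_msa(path, fmt: Optional[str] = None) -> Msa:
    """Read an aligned FASTA or Stockholm seed alignment."""
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Msa(names=[r.id for r in aln], rows=[str(r.seq) for r in aln])


@dataclass
class ProfileHmm:
    """A profile HMM with probabilities estimated from a seed alignment."""

    L: int
    match_emit: np.ndarray  # (L, 20)
    insert_emit: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    # per-node transition probabilities; index j refers to node j+1
    t_mm: np.ndarray  # (L-1,) M_j -> M_{j+1}
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    t_bm: float  # B -> M_1
    t_bd: float  # B -> D_1
    pseudocount_weight: float = 1.0
    match_mask: Optional[np.ndarray] = None
    # cached log2 quantities
    _lo: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore"):
            self._lo = np.log2(self.match_emit) - np.log2(self.background)[None, :]

    def emission_log_odds(self, protein: str) -> np.ndarray:
        """(n, L) log2-odds of each residue under each match state."""
        n = len(protein)
        out = np.zeros((n, self.L))
        for i, aa in enumerate(protein):
            k = _AA_INDEX.get(aa)
            if k is not None:
                out[i] = self._lo[:, k]
        return out

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[k] for k in self.match_emit.argmax(axis=1))

    def check_normalized(self, tol: float = 1e-9) -> bool:
        ok = np.allclose(self.match_emit.sum(axis=1), 1.0, atol=tol)
        ok &= math.isclose(self.insert_emit.sum(), 1.0, abs_tol=tol)
        ok &= np.allclose(self.t_mm + self.t_mi + self.t_md, 1.0, atol=tol)
        ok &= np.allclose(self.t_im + self.t_ii, 1.0, atol=tol)
        ok &= np.allclose(self.t_dm + self.t_dd, 1.0, atol=tol)
        ok &= math.isclose(self.t_bm + self.t_bd, 1.0, abs_tol=tol)
        return bool(ok)


@dataclass
class HmmHit:
    """A Viterbi alignment of one sequence to the profile."""

    seq_id: str
    bit_score: float
    path: List[Tuple[str, int, int]]  # (state, node j, seq index i or -1)
    aligned_row: str  # one column per match state, residue or '-'


def build_profile(
    msa: Msa, gap_threshold: float = 0.5, pseudocount_weight: float = 1.0
) -> ProfileHmm:
    """Estimate a profile HMM from an alignment.

    Match columns are those with gap fraction <= ``gap_threshold``.
    Match emissions are residue counts (uniform sequence weights) mixed
    with ``pseudocount_weight`` x background and normalised; transitions
    are counted from each row's match/insert/delete path through the
    columns with Laplace (+1) smoothing.  Deterministic for fixed input.
    """
    if msa.n_rows < 2:
        raise ModelBuildError("profile estimation needs at least 2 aligned rows")
    mask = msa.compute_match_mask(gap_threshold)
    L = int(mask.sum())
    if L < 1:
        raise ModelBuildError(
            "no column has enough residues to be a match state "
            f"(gap threshold {gap_threshold})"
        )
    match_cols = np.flatnonzero(mask)
    col_of_node = {int(c): j for j, c in enumerate(match_cols)}

    # emissions
    counts = np.zeros((L, 20))
    for row in msa.rows:
        for j, c in enumerate(match_cols):
            k = _AA_INDEX.get(row[c])
            if k is not None:
                counts[j, k] += 1.0
    match_emit = counts + pseudocount_weight * _BACKGROUND[None, :]
    match_emit /= match_emit.sum(axis=1, keepdims=True)

    # transition counts; node index j = 1..L, arrays indexed j-1
    c_mm = np.zeros(max(L - 1, 1))
    c_mi = np.zeros(max(L - 1, 1))
    c_md = np.zeros(max(L - 1, 1))
    c_im = np.zeros(max(L - 1, 1))
    c_ii = np.zeros(max(L - 1, 1))
    c_dm = np.zeros(max(L - 1, 1))
    c_dd = np.zeros(max(L - 1, 1))
    c_bm = 0.0
    c_bd = 0.0
    for row in msa.rows:
        # state sequence across match nodes, with insert counts in between
        states = []  # 'M' or 'D' per node
        ins_after = np.zeros(L + 1)  # inserts between node j and j+1 (0 = before node 1)
        j = 0
        for col, ch in enumerate(row):
            if col in col_of_node:
                j += 1
                states.append("M" if ch != "-" else "D")
            elif ch != "-":
                ins_after[j] += 1.0
        # flanking inserts (before node 1 / after node L) are unpenalised flank
        if states[0] == "M":
            c_bm += 1.0
        else:
            c_bd += 1.0
        for node in range(1, L):  # transition out of node `node` into node+1
            a, b = states[node - 1], states[node]
            nins = ins_after[node]
            if nins > 0 and a == "M":
                c_mi[node - 1] += 1.0
                c_ii[node - 1] += nins - 1
                c_im[node - 1] += 1.0  # I -> next node (counted as I->M; see note)
            elif a == "M":
                (c_mm if b == "M" else c_md)[node - 1] += 1.0
            else:  # a == 'D'; inserts after a delete are rare - fold into D path
                (c_dm if b == "M" else c_dd)[node - 1] += 1.0

    def norm2(a, b):
        return (a + 1.0) / (a + b + 2.0)

    t_mm = np.empty(max(L - 1, 1))
    t_mi = np.empty_like(t_mm)
    t_md = np.empty_like(t_mm)
    tot_m = c_mm + c_mi + c_md + 3.0
    t_mm = (c_mm + 1.0) / tot_m
    t_mi = (c_mi + 1.0) / tot_m
    t_md = (c_md + 1.0) / tot_m
    t_im = norm2(c_im, c_ii)
    t_ii = 1.0 - t_im
    t_dm = norm2(c_dm, c_dd)
    t_dd = 1.0 - t_dm
    t_bm = norm2(c_bm, c_bd)
    if L == 1:
        # no internal transitions; keep well-formed unit-length arrays
        t_mm = np.array([1.0 / 3]); t_mi = np.array([1.0 / 3]); t_md = np.array([1.0 / 3])
        t_im = np.array([0.5]); t_ii = np.array([0.5])
        t_dm = np.array([0.5]); t_dd = np.array([0.5])

    return ProfileHmm(
        L=L,
        match_emit=match_emit,
        insert_emit=_BACKGROUND.copy(),
        background=_BACKGROUND.copy(),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        t_bm=float(t_bm), t_bd=float(1.0 - t_bm),
        pseudocount_weight=pseudocount_weight,
        match_mask=mask,
    )


def _log2(x) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


def score_forward(hmm: ProfileHmm, protein: str) -> float:
    """Forward bit score: log2 sum over all glocal alignments vs background.

    The alignment may start and end anywhere in the sequence (flanking
    residues are free); the model is traversed in full, deletes allowed.
    """
    if not protein:
        raise ValueError("cannot score an empty protein")
    L, n = hmm.L, len(protein)
    lo = hmm.emission_log_odds(protein)  # (n, L)
    l_mm, l_mi, l_md = _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md)
    l_im, l_ii = _log2(hmm.t_im), _log2(hmm.t_ii)
    l_dm, l_dd = _log2(hmm.t_dm), _log2(hmm.t_dd)
    l_bm, l_bd = math.log2(hmm.t_bm), math.log2(hmm.t_bd)

    # delete-chain prefix sums: dchain[j] = sum of l_dd[0..j-1]
    dchain = np.concatenate([[0.0], np.cumsum(l_dd)]) if L > 1 else np.array([0.0])

    def d_column(m_col: np.ndarray, boundary_entry: float) -> np.ndarray:
        """D[j] for one boundary given M[j] at the same boundary."""
        d = np.full(L, _NEG_INF)
        # sources: entry B->D1, and M_k -> D_{k+1} followed by D..D
        # D[j] = logsum( entry + dchain[j-1],  max over k<j of M[k]+l_md[k]+dchain[j-1]-dchain[k] )
        src = np.full(L, _NEG_INF)  # src[k] = mass entering D_{k+1} directly
        if L > 1:
            src[1:] = m_col[:-1] + l_md
        src[0] = np.logaddexp2(src[0], boundary_entry)
        adj = src - dchain  # normalise by chain prefix
        run = np.logaddexp2.accumulate(adj)
        d = run + dchain
        return d

    prev_m = np.full(L, _NEG_INF)
    prev_i = np.full(max(L - 1, 1), _NEG_INF)
    prev_d = d_column(prev_m, l_bd)  # boundary 0
    ends = [prev_d[L - 1]]  # all-delete path
    for i in range(n):
        m = np.full(L, _NEG_INF)
        m[0] = l_bm  # fresh entry at this position
        if L > 1:
            from_m = prev_m[:-1] + l_mm
            from_i = prev_i + l_im
            from_d = prev_d[:-1] + l_dm
            m[1:] = np.logaddexp2(np.logaddexp2(from_m, from_i), from_d)
        m += lo[i]
        if L > 1:
            i_new = np.logaddexp2(prev_m[:-1] + l_mi, prev_i + l_ii)
        else:
            i_new = prev_i
        d = d_column(m, l_bd)
        ends.append(np.logaddexp2(m[L - 1], d[L - 1]))
        prev_m, prev_i, prev_d = m, i_new, d
    return float(np.logaddexp2.reduce(np.array(ends)))


def _viterbi_dp(hmm: ProfileHmm, protein: str):
    """Max-scoring glocal path; returns (bits, backpointer structures)."""
    L, n = hmm.L, len(protein)
    lo = hmm.emission_log_odds(protein)
    l_mm, l_mi, l_md = _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md)
    l_im, l_ii = _log2(hmm.t_im), _log2(hmm.t_ii)
    l_dm, l_dd = _log2(hmm.t_dm), _log2(hmm.t_dd)
    l_bm, l_bd = math.log2(hmm.t_bm), math.log2(hmm.t_bd)

    NEG = _NEG_INF
    M = np.full((n + 1, L), NEG)
    I = np.full((n + 1, max(L - 1, 1)), NEG)
    D = np.full((n + 1, L), NEG)
    ptr_m = np.zeros((n + 1, L), dtype=np.int8)  # 0=B,1=M,2=I,3=D
    ptr_i = np.zeros((n + 1, max(L - 1, 1)), dtype=np.int8)  # 1=M,2=I
    ptr_d = np.zeros((n + 1, L), dtype=np.int8)  # 0=B,1=M,3=D

    def fill_d(b):
        D[b, 0] = l_bd
        ptr_d[b, 0] = 0
        for j in range(1, L):
            via_m = M[b, j - 1] + l_md[j - 1]
            via_d = D[b, j - 1] + l_dd[j - 1]
            if via_m >= via_d:
                D[b, j], ptr_d[b, j] = via_m, 1
            else:
                D[b, j], ptr_d[b, j] = via_d, 3

    fill_d(0)
    for b in range(1, n + 1):
        i = b - 1  # residue index
        M[b, 0] = l_bm + lo[i, 0]
        ptr_m[b, 0] = 0
        for j in range(1, L):
            cands = (
                (M[b - 1, j - 1] + l_mm[j - 1], 1),
                (I[b - 1, j - 1] + l_im[j - 1], 2),
                (D[b - 1, j - 1] + l_dm[j - 1], 3),
            )
            best, tag = max(cands, key=lambda t: t[0])
            M[b, j] = best + lo[i, j]
            ptr_m[b, j] = tag
        for j in range(max(L - 1, 0)):
            via_m = M[b - 1, j] + l_mi[j]
            via_i = I[b - 1, j] + l_ii[j]
            if via_m >= via_i:
                I[b, j], ptr_i[b, j] = via_m, 1
            else:
                I[b, j], ptr_i[b, j] = via_i, 2
        fill_d(b)
    return M, I, D, ptr_m, ptr_i, ptr_d


def score_viterbi(hmm: ProfileHmm, protein: str) -> float:
    M, I, D, *_ = _viterbi_dp(hmm, protein)
    L = hmm.L
    return float(max(M[:, L - 1].max(), D[:, L - 1].max()))


def align_viterbi(hmm: ProfileHmm, protein: str, seq_id: str = "seq") -> HmmHit:
    """Best glocal alignment; ties broken Match > Insert > Delete.

    The returned ``aligned_row`` has exactly one column per match state
    (the aligned residue, or '-' where the path deletes the state);
    insertions and flanking residues are dropped.
    """
    M, I, D, ptr_m, ptr_i, ptr_d = _viterbi_dp(hmm, protein)
    L = hmm.L
    # choose end (prefer M over D on ties, later boundary on further ties)
    b_m = int(M[:, L - 1].argmax())
    b_d = int(D[:, L - 1].argmax())
    if M[b_m, L - 1] >= D[b_d, L - 1]:
        state, b, score = "M", b_m, float(M[b_m, L - 1])
    else:
        state, b, score = "D", b_d, float(D[b_d, L - 1])
    path: List[Tuple[str, int, int]] = []
    j = L - 1
    while True:
        if state == "M":
            path.append(("M", j + 1, b - 1))
            tag = ptr_m[b, j]
            b -= 1
            if tag == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(tag)]
            j -= 1
        elif state == "I":
            path.append(("I", j + 1, b - 1))
            tag = ptr_i[b, j]
            b -= 1
            state = "M" if tag == 1 else "I"
        else:  # D consumes nothing
            path.append(("D", j + 1, -1))
            tag = ptr_d[b, j]
            if tag == 0:
                break
            state = "M" if tag == 1 else "D"
            j -= 1
    path.reverse()
    row = ["-"] * L
    for st, node, i in path:
        if st == "M":
            row[node - 1] = protein[i]
    return HmmHit(seq_id=seq_id, bit_score=score, path=path, aligned_row="".join(row))


def sample_background_sequence(rng: np.random.Generator, length: int, background=None) -> str:
    bg = _BACKGROUND if background is None else np.asarray(background)
    idx = rng.choice(20, size=length, p=bg / bg.sum())
    return "".join(AMINO_ACIDS[k] for k in idx)


def calibrate_threshold(
    hmm: ProfileHmm,
    n_random: int = 200,
    length_dist: Sequence[int] = (),
    seed: int = 0,
    alpha: float = 1e-3,
) -> float:
    """Bit threshold: the (1 - alpha) quantile of forward scores of
    random background sequences.  ``length_dist`` is a pool of lengths
    sampled uniformly (default: the model length).  ``alpha = 1``
    returns the minimum sampled score.  Reproducible given ``seed``.
    """
    if n_random < 100:
        raise ValueError("need n_random >= 100 for a stable quantile")
    rng = np.random.default_rng(seed)
    lengths = list(length_dist) or [hmm.L]
    scores = np.empty(n_random)
    for i in range(n_random):
        ln = int(lengths[rng.integers(0, len(lengths))])
        scores[i] = score_forward(hmm, sample_background_sequence(rng, max(ln, 1)))
    return float(np.quantile(scores, 1.0 - alpha))


# ---------------------------------------------------------------------------
# HMMER3 ASCII export (interoperability)

def write_hmmer3(hmm: ProfileHmm, path, name: str = "cdzminer_profile") -> None:
    """Write the model as a HMMER3/f ASCII profile.

    Probabilities are stored as negative natural logs; '*' marks
    impossible transitions.  Flanking/looping special states are left to
    the reading implementation's defaults.
    """

    def nl(p: float) -> str:
        return "*" if p <= 0.0 else f"{-math.log(p):.5f}"

    L = hmm.L
    lines = [
        "HMMER3/f [3.4 | cdzminer export]",
        f"NAME  {name}",
        f"LENG  {L}",
        "ALPH  amino",
        "RF    no",
        "MM    no",
        "CONS  yes",
        "CS    no",
        "MAP   no",
        "HMM          " + "        ".join(AMINO_ACIDS),
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
    ]
    compo = -np.log(hmm.match_emit.mean(axis=0))
    lines.append("  COMPO   " + "  ".join(f"{v:.5f}" for v in compo))
    ins = "  ".join(nl(p) for p in hmm.insert_emit)
    lines.append("          " + ins)
    # node 0: B transitions (no I0 in this model)
    lines.append(
        "          "
        + "  ".join([nl(hmm.t_bm), "*", nl(hmm.t_bd), nl(1.0), "*", nl(1.0), "*"])
    )
    cons = hmm.consensus()
    for j in range(L):
        em = "  ".join(nl(p) for p in hmm.match_emit[j])
        lines.append(f"{j + 1:7d}   {em}      {j + 1} {cons[j].lower()} - - -")
        lines.append("          " + ins)
        if j < L - 1:
            tr = [
                nl(hmm.t_mm[j]), nl(hmm.t_mi[j]), nl(hmm.t_md[j]),
                nl(hmm.t_im[j]), nl(hmm.t_ii[j]),
                nl(hmm.t_dm[j]), nl(hmm.t_dd[j]),
            ]
        else:
            tr = [nl(1.0), "*", "*", nl(1.0), "*", nl(1.0), "*"]
        lines.append("          " + "  ".join(tr))
    lines.append("//")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Search-engine contract: the pipeline only needs build/score/align/calibrate,
# so an external profile-search implementation can stand in for the built-in
# one, provided it returns bit scores and match-column alignment rows.

class BuiltinEngine:
    """The package's own profile HMM as a search engine."""

    def __init__(self, gap_threshold: float = 0.5, pseudocount_weight: float = 1.0):
        self.gap_threshold = gap_threshold
        self.pseudocount_weight = pseudocount_weight

    def build(self, msa: Msa) -> ProfileHmm:
        return build_profile(msa, self.gap_threshold, self.pseudocount_weight)

    def score(self, model: ProfileHmm, proteins: Sequence[str]) -> np.ndarray:
        return np.array([score_forward(model, p) for p in proteins])

    def align(self, model: ProfileHmm, protein: str) -> str:
        return align_viterbi(model, protein).aligned_row

    def model_length(self, model: ProfileHmm) -> int:
        return model.L

    def calibrate(self, model: ProfileHmm, n_random: int, length_dist, seed: int, alpha: float) -> float:
        return calibrate_threshold(model, n_random, length_dist, seed, alpha)


class PyhmmerEngine:
    """HMMER (via pyhmmer) behind the same engine contract.

    Used as an independent cross-check that pipeline results are
    engine-agnostic on planted data; heuristic prefilters and the bias
    composition filter are disabled.
    """

    def __init__(self):
        import pyhmmer

        self._pyhmmer = pyhmmer
        self.alphabet = pyhmmer.easel.Alphabet.amino()
        self.bg = pyhmmer.plan7.Background(self.alphabet)

    def build(self, msa: Msa):
        easel = self._pyhmmer.easel
        tmsa = easel.TextMSA(name=b"seed", sequences=[
            easel.TextSequence(name=f"r{i}".encode(), sequence=row)
            for i, row in enumerate(msa.rows)
        ])
        dmsa = tmsa.digitize(self.alphabet)
        builder = self._pyhmmer.plan7.Builder(self.alphabet)
        hmm, _, _ = builder.build_msa(dmsa, self.bg)
        return hmm

    def model_length(self, model) -> int:
        return model.M

    def _block(self, proteins: Sequence[str]):
        easel = self._pyhmmer.easel
        seqs = [
            easel.TextSequence(name=str(i).encode(), sequence=p).digitize(self.alphabet)
            for i, p in enumerate(proteins)
        ]
        return easel.DigitalSequenceBlock(self.alphabet, seqs)

    def score(self, model, proteins: Sequence[str]) -> np.ndarray:
        pipeline = self._pyhmmer.plan7.Pipeline(
            self.alphabet, background=self.bg,
            bias_filter=False, F1=1.0, F2=1.0, F3=1.0, E=1e9,
        )
        hits = pipeline.search_hmm(model, self._block(proteins))
        out = np.full(len(proteins), -np.inf)
        for h in hits:
            name = h.name.decode() if isinstance(h.name, bytes) else h.name
            out[int(name)] = h.score
        return out

    def align(self, model, protein: str) -> str:
        msa = self._pyhmmer.hmmer.hmmalign(model, self._block([protein]), trim=True)
        row = msa.alignment[0]
        # uppercase/'-' columns are match states; lowercase/'.' are inserts
        return "".join(c if c != "." else "-" for c in row if not c.islower())

    def calibrate(self, model, n_random: int, length_dist, seed: int, alpha: float) -> float:
        rng = np.random.default_rng(seed)
        lengths = list(length_dist) or [model.M]
        seqs = [
            sample_background_sequence(rng, max(int(lengths[rng.integers(0, len(lengths))]), 1))
            for _ in range(n_random)
        ]
        scores = self.score(model, seqs)
        finite = np.where(np.isfinite(scores), scores, np.nanmin(scores[np.isfinite(scores)]) if np.isfinite(scores).any() else 0.0)
        return float(np.quantile(finite, 1.0 - alpha))
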