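import math

import numpy as np
import pytest

from cdzminer.config import AMINO_ACIDS
from cdzminer.profilehmm import (
    BuiltinEngine,
    ModelBuildError,
    Msa,
    align_viterbi,
    build_profile,
    calibrate_threshold,
    read_msa,
    sample_background_sequence,
    score_forward,
    score_viterbi,
    write_hmmer3,
)

from _oracles import enumerate_paths_score


def random_msa(rng, n_rows, n_cols, gap_frac=0.15):
    rows = []
    for _ in range(n_rows):
        row = "".join(
            "-" if rng.random() < gap_frac else AMINO_ACIDS[int(rng.integers(0, 20))]
            for _ in range(n_cols)
        )
        rows.append(row)
    return Msa(names=[f"s{i}" for i in range(n_rows)], rows=rows)


class TestBuild:
    def test_gapless_identical_rows(self):
        msa = Msa(names=list("abc"), rows=["ACDE"] * 3)
        hmm = build_profile(msa)
        assert hmm.L == 4
        for j, aa in enumerate("ACDE"):
            assert AMINO_ACIDS[hmm.match_emit[j].argmax()] == aa
        assert hmm.check_normalized()

    def test_gap_heavy_column_is_not_match_state(self):
        msa = Msa(names=list("abc"), rows=["A-CD", "A-CD", "AGCD"])
        hmm = build_profile(msa, gap_threshold=0.5)
        assert hmm.L == 3
        assert list(hmm.match_mask) == [True, False, True, True]

    def test_emissions_equal_pseudocount_formula(self, rng):
        """Emission vectors match the (counts + w*bg)/norm recomputation."""
        from cdzminer.profilehmm import _BACKGROUND

        msa = random_msa(rng, 6, 12, gap_frac=0.1)
        w = 1.7
        hmm = build_profile(msa, pseudocount_weight=w)
        mask = msa.compute_match_mask(0.5)
        cols = np.flatnonzero(mask)
        for j, c in enumerate(cols):
            counts = np.zeros(20)
            for row in msa.rows:
                if row[c] in AMINO_ACIDS:
                    counts[AMINO_ACIDS.index(row[c])] += 1
            expect = counts + w * _BACKGROUND
            expect /= expect.sum()
            assert np.allclose(hmm.match_emit[j], expect)

    def test_all_gap_columns_error(self):
        msa = Msa(names=["a", "b"], rows=["--", "--"])
        with pytest.raises(ModelBuildError):
            build_profile(msa)

    def test_single_row_rejected(self):
        with pytest.raises(ModelBuildError):
            build_profile(Msa(names=["a"], rows=["ACD"]))


class TestScoring:
    def test_trained_residue_scores_above_other(self):
        msa = Msa(names=["a", "b"], rows=["G", "G"])
        hmm = build_profile(msa)
        assert score_forward(hmm, "G") > score_forward(hmm, "W")

    def test_forward_and_viterbi_equal_path_enumeration(self, rng):
        """Exact agreement with exhaustive enumeration for tiny models."""
        for L in (1, 2, 3):
            for trial in range(6):
                msa = random_msa(rng, 3, L, gap_frac=0.2 if L > 1 else 0.0)
                try:
                    hmm = build_profile(msa)
                except ModelBuildError:
                    continue
                for n in (1, 2, 3, 4):
                    seq = sample_background_sequence(rng, n)
                    f = score_forward(hmm, seq)
                    v = score_viterbi(hmm, seq)
                    assert f == pytest.approx(enumerate_paths_score(hmm, seq, "sum"), abs=1e-9)
                    assert v == pytest.approx(enumerate_paths_score(hmm, seq, "max"), abs=1e-9)

    def test_forward_at_least_viterbi_on_random_pairs(self, rng):
        for _ in range(200):
            msa = random_msa(rng, 3, int(rng.integers(2, 15)))
            try:
                hmm = build_profile(msa)
            except ModelBuildError:
                continue
            seq = sample_background_sequence(rng, int(rng.integers(1, 40)))
            assert score_forward(hmm, seq) >= score_viterbi(hmm, seq) - 1e-9

    def test_consensus_scores_above_shuffles(self, toy_hmm, rng):
        cons = toy_hmm.consensus()
        ref = score_forward(toy_hmm, cons)
        shuffled = []
        for _ in range(100):
            perm = rng.permutation(len(cons))
            shuffled.append(score_forward(toy_hmm, "".join(cons[i] for i in perm)))
        assert ref > np.mean(shuffled)

    def test_unknown_residues_score_as_background(self, toy_hmm):
        assert score_forward(toy_hmm, "XXXX") == pytest.approx(
            score_forward(toy_hmm, "XXXX")
        )
        # an X in place of a consensus residue can only lower the score
        cons = toy_hmm.consensus()
        assert score_forward(toy_hmm, cons) > score_forward(toy_hmm, "X" + cons[1:])


class TestViterbiAlignment:
    def test_consensus_aligns_all_match(self, toy_hmm):
        cons = toy_hmm.consensus()
        hit = align_viterbi(toy_hmm, cons)
        assert hit.aligned_row == cons
        assert all(st == "M" for st, _, _ in hit.path)

    def test_alignment_row_width_is_model_length(self, toy_hmm, rng):
        for _ in range(20):
            seq = sample_background_sequence(rng, int(rng.integers(5, 30)))
            hit = align_viterbi(toy_hmm, seq)
            assert len(hit.aligned_row) == toy_hmm.L
            assert hit.bit_score <= score_forward(toy_hmm, seq) + 1e-9


class TestCalibration:
    def test_alpha_one_gives_minimum(self, toy_hmm):
        scores_min = calibrate_threshold(toy_hmm, n_random=100, seed=5, alpha=1.0)
        scores_q = calibrate_threshold(toy_hmm, n_random=100, seed=5, alpha=1e-3)
        assert scores_min <= scores_q

    def test_reproducible_and_stable(self, toy_hmm):
        a = calibrate_threshold(toy_hmm, n_random=200, seed=9)
        b = calibrate_threshold(toy_hmm, n_random=200, seed=9)
        assert a == b

    def test_separates_planted_toxins_from_shuffles(self, small_synth, rng):
        """Planted family members score above threshold; shuffles below."""
        hmm = build_profile(small_synth.seed_msa)
        thr = calibrate_threshold(
            hmm, n_random=150, length_dist=[70, 90, 110], seed=3
        )
        toxins = [t.protein for t in small_synth.truth if t.kind == "true_toxin"]
        tox_scores = [score_forward(hmm, p) for p in toxins]
        assert all(s >= thr for s in tox_scores)
        # background-composition sequences stay below the threshold
        bg = [
            sample_background_sequence(rng, int(rng.integers(70, 120)))
            for _ in range(40)
        ]
        bg_scores = [score_forward(hmm, s) for s in bg]
        assert np.mean([s < thr for s in bg_scores]) >= 0.95
        # residue order carries most of the signal: every true toxin beats
        # every composition-preserving shuffle of the family
        shuffles = []
        for p in toxins * 10:
            perm = rng.permutation(len(p))
            shuffles.append("".join(p[i] for i in perm))
        sh_scores = [score_forward(hmm, s) for s in shuffles]
        assert min(tox_scores) > max(sh_scores)


class TestInterop:
    def test_msa_reader_fasta_and_stockholm(self, tmp_path):
        (tmp_path / "a.afa").write_text(">x\nAC-E\n>y\nACDE\n")
        m = read_msa(tmp_path / "a.afa")
        assert m.rows == ["AC-E", "ACDE"]
        sto = "# STOCKHOLM 1.0\nx AC.E\ny ACDE\n//\n"
        (tmp_path / "a.sto").write_text(sto)
        m2 = read_msa(tmp_path / "a.sto")
        assert m2.rows == ["AC-E", "ACDE"]

    def test_hmmer3_export_readable_by_pyhmmer(self, toy_hmm, tmp_path):
        pyhmmer = pytest.importorskip("pyhmmer")
        path = tmp_path / "model.hmm"
        write_hmmer3(toy_hmm, path, name="toy")
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmm = fh.read()
        assert hmm.M == toy_hmm.L
        # match emissions survive the round trip
        alpha = "ACDEFGHIKLMNPQRSTVWY"
        file_order = hmm.alphabet.symbols[:20]
        probs = np.asarray(hmm.match_emissions)[1:, :]
        for j in range(toy_hmm.L):
            for k, aa in enumerate(file_order):
                assert probs[j, k] == pytest.approx(
                    toy_hmm.match_emit[j, alpha.index(aa)], abs=1e-4
                )
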