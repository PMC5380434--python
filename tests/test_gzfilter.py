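import numpy as np
import pytest

from cdzminer.config import AMINO_ACIDS, ClassifierParams
from cdzminer.gzfilter import (
    check_cterm,
    check_flanks,
    check_polar_spans,
    classify_toxin,
    composition_stats,
    detect_leader,
    find_interrupted_runs,
    find_zippers,
)

from _oracles import brute_leader, brute_polar_spans_ok, brute_tail_ok, brute_zippers


def random_protein(rng, n):
    return "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=n))


def zipperish_protein(rng, n):
    """Random sequence enriched for G and small hydrophobics so motifs occur."""
    alpha = "GGGAVILFSTDEKP"
    return "".join(alpha[int(i)] for i in rng.integers(0, len(alpha), size=n))


class TestLeader:
    def test_forced_call(self):
        p = "MKAILLAVSLGG" + "AVIGAVIG" * 6
        call = detect_leader(p)
        assert call.cleavage_index == 12 and call.dipeptide == "GG"

    def test_absent_when_no_motif_in_window(self):
        assert detect_leader("MK" + "K" * 60) is None

    def test_matches_window_scan_oracle(self, rng):
        for _ in range(3000):
            p = random_protein(rng, int(rng.integers(36, 90)))
            call = detect_leader(p)
            want = brute_leader(p)
            assert (call.cleavage_index if call else None) == want


class TestZippers:
    def test_canonical_motif(self):
        (m,) = find_zippers("GAVIGAVIG")
        assert m.anchors == (0, 4, 8)

    def test_proline_interrupts(self):
        assert find_zippers("GAVIGAPIG") == []
        assert find_interrupted_runs("GAVIGAPIG") != []

    def test_matches_pattern_oracle(self, rng):
        for _ in range(3000):
            m = zipperish_protein(rng, 60)
            got = {z.anchors for z in find_zippers(m)}
            assert got == brute_zippers(m)

    def test_maximality(self):
        # one long run, not two overlapping sub-runs
        ms = find_zippers("GAVIGAVIGAVIGAVIG")
        assert len(ms) == 1 and ms[0].n_anchors == 5


class TestFlanksAndTail:
    def test_flank_near_charged(self):
        m = find_zippers("AAAGAVIGAVIGAAKAA")[0]
        assert check_flanks("AAAGAVIGAVIGAAKAA", m) is True

    def test_flank_absent_in_hydrophobic_context(self):
        seq = "AAAAAGAVIGAVIGAAAAA"
        m = find_zippers(seq)[0]
        assert check_flanks(seq, m) is False

    def test_terminus_counts_as_flank(self):
        seq = "GAVIGAVIGAAAAAAAA"
        m = find_zippers(seq)[0]
        assert check_flanks(seq, m) is True

    @pytest.mark.parametrize(
        "tail,expect",
        [("DKRES", True), ("A" * 25, False), ("", True), ("DDAA", True), ("AAAD", False)],
    )
    def test_cterm_rule(self, tail, expect):
        seq = "GAVIGAVIG" + tail
        ms = find_zippers(seq)
        assert check_cterm(seq, ms) is expect

    def test_cterm_matches_counting_oracle(self, rng):
        # G-free random tails so the zipper cannot extend into the tail
        alpha = "ACDEFHIKLMNPQRSTVWY"
        for _ in range(3000):
            tail = "".join(alpha[int(i)] for i in rng.integers(0, 19, size=int(rng.integers(0, 30))))
            seq = "GAVIGAVIG" + tail
            ms = find_zippers(seq)
            got = check_cterm(seq, ms)
            assert got == brute_tail_ok(seq[9:])


class TestPolarSpans:
    def test_clean_zipper_passes(self):
        assert check_polar_spans("GAVIGAVIGAVIG") is True

    def test_dense_polar_block_fails(self):
        assert check_polar_spans("GAVIGADEKRSNVIG") is False

    def test_matches_window_oracle(self, rng):
        for _ in range(3000):
            m = random_protein(rng, int(rng.integers(6, 80)))
            assert check_polar_spans(m) == brute_polar_spans_ok(m)


class TestClassifier:
    def test_generated_toxin_passes(self, rng):
        from cdzminer.synthgen import make_toxin_protein

        for _ in range(50):
            p, _ = make_toxin_protein(rng)
            assert classify_toxin(p).overall

    def test_padding_past_151_fails_length_only(self, rng):
        from cdzminer.synthgen import make_toxin_protein

        p, ann = make_toxin_protein(rng)
        v = classify_toxin(p)
        assert v.overall
        # lengthen via an inserted hydrophobic stretch before the zipper
        cut = ann["cleavage_index"]
        padded = p[:cut] + "A" * (160 - len(p)) + p[cut:]
        v2 = classify_toxin(padded)
        assert not v2.length_ok and not v2.overall

    def test_zipper_g_to_p_fails(self, rng):
        from cdzminer.synthgen import make_toxin_protein

        p, ann = make_toxin_protein(rng)
        anchors = ann["zipper_anchors"]
        mid = anchors[len(anchors) // 2]
        broken = p[:mid] + "P" + p[mid + 1 :]
        v = classify_toxin(broken)
        assert not v.overall

    def test_cascade_monotonicity(self, rng):
        """Tightening thresholds never admits new sequences."""
        from cdzminer.synthgen import make_toxin_protein, make_decoy, DECOY_CLASSES

        pool = []
        for _ in range(30):
            pool.append(make_toxin_protein(rng)[0])
        for cls in DECOY_CLASSES:
            pool.append(make_decoy(rng, cls)[0])
        for _ in range(60):
            pool.append(random_protein(rng, int(rng.integers(50, 170))))
        loose = ClassifierParams()
        tighter = [
            ClassifierParams(min_len=70, max_len=140),
            ClassifierParams(min_anchors=4),
            ClassifierParams(max_tail=10),
            ClassifierParams(max_motifs=1),
        ]
        passing_loose = {p for p in pool if classify_toxin(p, loose).overall}
        for tp in tighter:
            passing_tight = {p for p in pool if classify_toxin(p, tp).overall}
            assert passing_tight <= passing_loose

    def test_verdict_is_pure_conjunction(self, rng):
        from cdzminer.synthgen import make_decoy, DECOY_CLASSES

        for cls in DECOY_CLASSES:
            p, _ = make_decoy(rng, cls)
            v = classify_toxin(p)
            d = v.as_dict()
            expect = all(val for key, val in d.items() if key != "overall")
            assert d["overall"] == expect


class TestComposition:
    def test_pure_classes(self):
        assert composition_stats("GAVI")["small_hydrophobic"] == 1.0
        assert composition_stats("DDDD")["charged"] == 1.0

    def test_mature_only_requires_leader(self):
        with pytest.raises(ValueError, match="leader"):
            composition_stats("K" * 60, mature_only=True)

    def test_mature_only_removes_leader(self, rng):
        from cdzminer.synthgen import make_toxin_protein

        p, ann = make_toxin_protein(rng)
        stats = composition_stats(p, mature_only=True)
        assert stats["length"] == len(p) - ann["cleavage_index"]
        assert stats["small_hydrophobic"] >= 0.6
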