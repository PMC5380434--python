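import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cdzminer.gzfilter import classify_toxin, composition_stats, detect_leader
from cdzminer.synthgen import (
    DECOY_CLASSES,
    SynthParams,
    generate,
    make_decoy,
    make_toxin_protein,
)


class TestToxinDraws:
    def test_every_draw_passes_classifier(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p, ann = make_toxin_protein(rng)
            v = classify_toxin(p)
            assert v.overall
            assert 60 <= len(p) <= 151

    def test_mature_small_hydrophobic_fraction(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            p, ann = make_toxin_protein(rng)
            mature = p[ann["cleavage_index"] :]
            assert composition_stats(mature)["small_hydrophobic"] >= 0.6

    def test_fixed_seed_determinism(self):
        a = make_toxin_protein(np.random.default_rng(5))[0]
        b = make_toxin_protein(np.random.default_rng(5))[0]
        assert a == b

    def test_annotations_are_consistent(self):
        rng = np.random.default_rng(13)
        p, ann = make_toxin_protein(rng)
        call = detect_leader(p)
        assert call.cleavage_index == ann["cleavage_index"]
        assert all(p[i] == "G" for i in ann["zipper_anchors"])


class TestDecoys:
    @pytest.mark.parametrize("cls", [c for c in DECOY_CLASSES if c != "decoy_no_anchor"])
    def test_each_class_fails_its_criterion(self, cls):
        rng = np.random.default_rng(21)
        expected_fail = {
            "decoy_interrupted": "zipper_uninterrupted",
            "decoy_bad_length": "length_ok",
            "decoy_no_leader": "leader_ok",
            "decoy_no_tail": "cterm_ok",
        }[cls]
        for _ in range(100):
            p, _ = make_decoy(rng, cls)
            d = classify_toxin(p).as_dict()
            assert not d["overall"]
            assert not d[expected_fail]

    def test_bad_length_fails_only_length(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            p, _ = make_decoy(rng, "decoy_bad_length")
            d = classify_toxin(p).as_dict()
            assert not d["length_ok"]
            others = {k: v for k, v in d.items() if k not in ("length_ok", "overall")}
            assert all(others.values())

    def test_no_anchor_decoy_passes_classifier(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            p, _ = make_decoy(rng, "decoy_no_anchor")
            assert classify_toxin(p).overall

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            make_decoy(np.random.default_rng(0), "decoy_of_doom")

    def test_fixed_seed_determinism(self):
        for cls in DECOY_CLASSES:
            a = make_decoy(np.random.default_rng(9), cls)[0]
            b = make_decoy(np.random.default_rng(9), cls)[0]
            assert a == b


class TestGenerate:
    def test_truth_counts(self):
        res = generate(SynthParams(seed=3, n_genomes=2, n_true_clusters=1))
        tt = res.truth_table()
        assert (tt.kind == "anchor_gene").sum() == 4  # 2 genomes x 2 genes
        per_kind = tt.groupby("kind").size()
        for cls in DECOY_CLASSES:
            assert per_kind[cls] == 2
        assert per_kind["true_toxin"] >= 2

    def test_toxins_near_anchor_and_far_decoys_beyond(self, small_synth):
        tt = small_synth.truth_table()
        for gid, sub in tt.groupby("genome_id"):
            anchors = sub[sub.kind == "anchor_gene"]
            span = (anchors.start.min(), anchors.end.max())

            def gap(row):
                if row.end <= span[0]:
                    return span[0] - row.end
                if row.start >= span[1]:
                    return row.start - span[1]
                return 0

            for row in sub[sub.kind == "true_toxin"].itertuples():
                assert gap(row) <= 10_000
            for row in sub[sub.kind == "decoy_no_anchor"].itertuples():
                assert gap(row) > 10_000

    def test_planted_intervals_do_not_overlap(self, small_synth):
        tt = small_synth.truth_table().sort_values(["genome_id", "start"])
        for _, sub in tt.groupby("genome_id"):
            ends = sub.end.values
            starts = sub.start.values
            assert all(starts[1:] >= ends[:-1])

    def test_genome_sequence_encodes_planted_proteins(self, small_synth):
        from cdzminer.orfscan import enumerate_orfs
        from cdzminer.config import OrfParams

        g = small_synth.genomes[0]
        truth = [t for t in small_synth.truth if t.genome_id == g.id and t.kind == "true_toxin"]
        params = OrfParams()
        orfs = {
            (c.start, c.end, c.strand): c.protein
            for c in enumerate_orfs(g.sequence, params, contig_id=g.id)
        }
        for t in truth:
            assert orfs.get((t.start, t.end, t.strand)) == t.protein

    def test_seed_msa_is_alignable_toxin_family(self, small_synth):
        msa = small_synth.seed_msa
        assert msa.n_rows == 4
        assert len({len(r) for r in msa.rows}) == 1
        for row in msa.rows:
            assert classify_toxin(row.replace("-", "")).overall

    def test_files_byte_identical_across_runs(self, tmp_path):
        p = SynthParams(seed=5, n_genomes=1)
        generate(p, out_dir=tmp_path / "a")
        generate(p, out_dir=tmp_path / "b")
        files_a = sorted((tmp_path / "a").rglob("*"))
        for fa in files_a:
            if fa.is_file():
                fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_contig_too_short_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate(SynthParams(seed=1, n_genomes=1, contig_len_nt=30_000))
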