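import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdzminer.seqio import (
    EmptyInputError,
    FastaParseError,
    Feature,
    GenomeRecord,
    extract_window,
    read_bed,
    read_fasta,
    read_genbank,
    read_gff3,
    revcomp,
    write_fasta,
    write_gff3,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=1000)


def test_read_fasta_parses_multi_record(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">a desc\nac\ngt\n>b\nTT\n")
    recs = read_fasta(p)
    assert [(r.id, r.sequence) for r in recs] == [("a", "ACGT"), ("b", "TT")]


def test_read_fasta_errors(tmp_path):
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(EmptyInputError):
        read_fasta(empty)
    bad = tmp_path / "bad.fa"
    bad.write_text(">a\nACGT\nAC!T\n")
    with pytest.raises(FastaParseError, match="line 3"):
        read_fasta(bad)


def test_fasta_round_trip(tmp_path, rng):
    recs = [
        ("r%d" % i, "".join(rng.choice(list("ACGT"), size=rng.integers(10, 200))))
        for i in range(20)
    ]
    path = tmp_path / "rt.fa"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert [(r.id, r.sequence) for r in back] == recs


def test_genbank_coordinates_are_half_open(tmp_path, small_synth):
    """CDS 11..40 means internal [10, 40); complement flips the strand."""
    gb = tmp_path / "t.gbk"
    gb.write_text(
        "LOCUS       test                 60 bp    DNA     linear   UNA 01-JAN-2000\n"
        "FEATURES             Location/Qualifiers\n"
        "     CDS             11..40\n"
        '                     /locus_tag="g1"\n'
        "     CDS             complement(11..40)\n"
        '                     /locus_tag="g2"\n'
        "ORIGIN\n"
        "        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt\n"
        "//\n"
    )
    rec = read_genbank(gb)[0]
    f1, f2 = rec.features
    assert (f1.start, f1.end, f1.strand) == (10, 40, "+")
    assert (f2.start, f2.end, f2.strand) == (10, 40, "-")


def test_genbank_round_trip_matches_truth(tmp_path, small_synth):
    """Features read back from generated GenBank equal the truth table."""
    from cdzminer.synthgen import _write_outputs
    from pathlib import Path

    _write_outputs(small_synth, Path(tmp_path))
    g = small_synth.genomes[0]
    rec = read_genbank(tmp_path / "genomes" / f"{g.id}.gbk")[0]
    assert rec.sequence == g.sequence
    truth = {
        (t.element_id, t.start, t.end, t.strand)
        for t in small_synth.truth
        if t.genome_id == g.id
    }
    parsed = {(f.id, f.start, f.end, f.strand) for f in rec.features}
    assert parsed == truth


@pytest.mark.parametrize(
    "anchor,flank,expect",
    [((20000, 21000), 10000, (10000, 31000)), ((500, 1500), 10000, (0, 11500))],
)
def test_extract_window_clips_to_contig(anchor, flank, expect, rng):
    seq = "".join(rng.choice(list("ACGT"), size=100_000))
    g = GenomeRecord(id="c", description="", sequence=seq)
    f = Feature(id="a", kind="anchor", contig_id="c", start=anchor[0], end=anchor[1], strand="+")
    win, sub = extract_window(g, f, flank)
    assert win.interval == expect
    assert sub == seq[expect[0] : expect[1]]
    assert 0 <= win.start < win.end <= len(g)


def test_extract_window_wrong_contig_raises():
    g = GenomeRecord(id="c", description="", sequence="ACGT" * 100)
    f = Feature(id="a", kind="anchor", contig_id="other", start=0, end=10, strand="+")
    with pytest.raises(KeyError):
        extract_window(g, f, 100)


@settings(max_examples=200, derandomize=True)
@given(dna)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AAAC") == "GTTT"


def test_gff3_round_trip(tmp_path, small_synth):
    """Written GFF3 uses 1-based inclusive coords and reads back exactly."""
    from cdzminer.config import MinerConfig
    from cdzminer.pipeline import scan

    res = scan(
        small_synth.genomes, small_synth.seed_msa, small_synth.t1ss_refs,
        config=MinerConfig(),
    )
    out = tmp_path / "c.gff3"
    write_gff3(res.clusters, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    feats = read_gff3(out)
    originals = {
        (g.id, g.start, g.end)
        for cl in res.clusters
        for g in cl.anchor.genes
    } | {(t.orf.id, t.orf.start, t.orf.end) for cl in res.clusters for t in cl.toxins}
    assert {(f.id, f.start, f.end) for f in feats} == originals
    # spot-check the +1 convention on the first data line
    first = lines[1].split("\t")
    f0 = feats[0]
    assert int(first[3]) == f0.start + 1 and int(first[4]) == f0.end


def test_gff3_empty_cluster_list(tmp_path):
    out = tmp_path / "empty.gff3"
    write_gff3([], out)
    assert out.read_text() == "##gff-version 3\n"
    assert read_gff3(out) == []


def test_read_bed(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("ctg1\t100\t200\tanchorX\t0\t-\n# comment\nctg2\t5\t50\n")
    feats = read_bed(p)
    assert (feats[0].contig_id, feats[0].start, feats[0].end, feats[0].strand) == (
        "ctg1", 100, 200, "-",
    )
    assert feats[1].id == "anchor3"
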