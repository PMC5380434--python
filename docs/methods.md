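# Methods

This note documents the models and procedures implemented in `cdzminer`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmark does and does not establish.

## Discovery procedure

The scan reproduces the logic of a genomic-context + iterative homology
search for contact-dependent glycine-zipper bacteriocin (Cdz-like) systems,
with user-supplied genomes standing in for public sequence databases — the
procedure is the same, the data source is a parameter.

1. **Anchors.**  Annotated CDS are translated and scored against profile
   HMMs built from reference alignments of the two T1SS protein families
   (ABC transporter, membrane-fusion adaptor).  Genes scoring above a
   calibrated bit threshold are grouped into loci when within 5 kb of each
   other on one contig.  A user-supplied BED of anchor coordinates bypasses
   scoring.  Unannotated genomes may be scanned in a slower six-frame mode
   that treats 200–900-residue ORFs as anchor candidates.
2. **Windows and ORFs.**  10 kb of flank is cut on each side of every anchor
   locus (clipped at contig edges; contigs are treated as linear) and *all
   possible* ORFs of 60–200 residues are enumerated in six frames: every
   start codon (ATG/GTG/TTG, translation table 11) paired with its first
   in-frame stop inside the window, nested starts reported individually.
   The initiator codon translates as M; codons containing N translate to X
   and never terminate an ORF.
3. **Iterative search.**  Round 0 scores every candidate with the profile
   built from the seed toxin alignment.  Hits with a bit score at or above
   the calibrated threshold *and* a passing classifier verdict (below) are
   aligned back into the alignment (Viterbi, match columns only), the model
   is rebuilt, and scoring repeats.  Two rebuild rounds are the default —
   deeper iteration is known to drift into generic class-IIb bacteriocins,
   so the search stops where the signal is still specific.  The accepted
   set grows monotonically; a round that adds nothing ends the search early.
4. **Cluster assembly.**  Accepted ORFs are first deduplicated by (contig,
   strand, stop codon) — nested start choices of one gene count once, the
   highest-scoring longest call wins.  Each toxin is assigned to the nearest
   anchor within 10 kb (ties broken toward the leftmost locus); toxins with
   no anchor in range are dropped and reported separately.  Clusters carry
   anchor–toxin distances, adjacency flags (gap < 500 nt) and a 1 / 2 / 3+
   toxin-count class.

## Toxin classifier

A candidate passes only if all of the following hold:

| rule | default | notes |
| --- | --- | --- |
| full length | 60–151 aa | applies to the whole ORF, leader included |
| leader | G[G/A/S] ending at position 10–35 | first qualifying position; mature = remainder |
| zipper motifs | 1 or 2 | maximal period-4 glycine chains, ≥3 anchors, no P/C/charged at intervening positions |
| uninterrupted | required | a period-4 G chain of zipper size carrying P/C/charged between anchors disqualifies, even where the clean fragments would individually qualify |
| flanks | ≥1 side | P or charged residue within 3 residues of a motif end; a sequence terminus counts |
| C-tail | ≤20 aa, ≥40% charged+polar | residues after the last zipper anchor |
| polar spans | ≤4 charged+polar per 6-residue window | pre-tail mature region |

Residue classes: charged {D,E,K,R} (H is treated as polar), polar
{S,T,N,Q,H,Y}, small hydrophobic {G,A,V,I}, zipper anchors strictly {G}
(an option admits A/S anchors, off by default).  All windows and thresholds
are package choices parameterising prose criteria and are exposed in the
config; every criterion is computed independently and the overall verdict
is a pure conjunction, so tightening any threshold can only shrink the
passing set (tested as a property).

The uninterrupted rule deserves a note: counting motifs alone would pass a
zipper whose middle x-position carries a proline, because the two clean
halves each qualify.  The interruption filter therefore checks period-4
glycine chains *ignoring* intervening content and fails the candidate when
such a chain carries a forbidden residue between anchors.

## Profile HMM

Match/insert/delete profile with one match state per alignment column whose
gap fraction is ≤ 0.5.  Match emissions are residue counts mixed with a
single background pseudocount (weight 1.0, Swiss-Prot-like background
frequencies) — adequate for the 4–240-row alignments this search builds,
and much easier to verify than Dirichlet mixtures.  Transitions are counted
from each row's match/delete path with Laplace smoothing; inserts after a
delete (rare) are folded into the delete path, and an insert running into a
delete is counted as insert→match, the nearest representable transition.

Scoring is **glocal** — global in the model, local in the sequence — so a
hit's leader and tail outside the modelled core carry no penalty: the
alignment may start and end at any residue for free, which makes the score
a sum (forward) or maximum (Viterbi) over entry/exit points of the core
log-odds.  Scores are bits (log2 odds against the background); residues
outside the 20-letter alphabet score 0 bits everywhere.  Forward ≥ Viterbi
by construction; both are verified against exhaustive path enumeration for
small models in the tests.  There is deliberately **no composition bias
correction**: the original search disabled it, and the downstream
classifier — not the score — is what rejects composition-only lookalikes.
Consequently a composition-preserving shuffle of a true toxin still scores
tens of bits (order contributes the remaining ~200), and the calibrated
threshold should be read as "above background", not "toxin-specific".

Significance uses a calibrated bit threshold rather than E-values: the
(1−α) quantile (α = 10⁻³) of forward scores of ≥100 random background
sequences with lengths drawn from the candidate pool, reproducible from a
seed.  Viterbi ties break Match > Insert > Delete.  Models export to
HMMER3 ASCII for interoperability, and the pipeline accepts any engine
implementing build/score/align/calibrate — a pyhmmer-backed adapter is
included and must reproduce the built-in engine's hit set on planted data
(tested).

## Aggregation consensus and competition statistics

External per-residue aggregation predictors are consumed as boolean TSV
tracks; a residue is aggregation-prone when ≥3 of ≥4 predictors agree
(per-residue, the stricter reading of "in accordance"), merged into maximal
intervals.  A Kyte–Doolittle window predictor (window 7) is built in purely
so the combiner can be exercised offline; it does not emulate any specific
external tool.

CFU density is colonies/(dilution × plated volume), with 3–100 colonies per
10 µL spot treated as reliably countable (a QC convention).  The
competitive index is the indicator/producer ratio at the final time point
over the same ratio at t₀; zero indicator counts are reported as an upper
bound at a caller-supplied detection limit rather than 0, zero producer
counts are an error.  Fold induction is fluorescence density relative to
the culture-density baseline (OD₆₀₀ = 0.025).  PI-positive fractions are
averaged over ≥3 microscopy fields of ≥250 cells, smaller fields flagged.

## Synthetic benchmark

The generator plants, per genome (default 20 genomes of 120 kb, one cluster
each): a two-gene T1SS operon (noisy copies of two reference proteins,
~10% substitutions), 1–3 toxin genes within 10 kb of the operon (drawn
0.81/0.14/0.05 — most clusters single-toxin, a minority with two or three,
matching the reported field distribution), and five decoy classes that each
violate exactly one rule: interrupted zipper, length > 151, destroyed
leader, hydrophobic over-long tail, and a fully valid toxin placed > 15 kb
from every anchor.  Toxins are drawn from one family blueprint per run
(positions resampled within their residue class at rate 0.12; the 4-row
seed alignment uses rate 0.08), so planted toxins are genuine homologs of
the seed.

Constructions that keep truth labels deterministic: reverse translation
avoids GTG/TTG codons and planted proteins contain no internal M, so no
nested in-frame start exists inside a planted gene; an in-frame stop codon
is placed flush against each gene end so chance upstream starts cannot
extend a planted ORF past its truth interval; the residue after each
zipper anchor excludes A/G/S so no accidental G[G/A/S] arises inside a
zipper; intergenic spacers carry a stop cassette covering all six frames
at least every 150 nt to suppress long spurious ORFs.  A hydrophobic
"shoulder" segment between leader and zipper brings totals into 60–151
(leader + zipper + tail ranges alone cannot reach 60) and mirrors the
hydrophobic mature regions of real family members; mature {G,A,V,I}
content is guaranteed ≥ 0.6 by rejection.  Codons are chosen uniformly
weighted toward the target GC (0.55); no codon-usage tables, which the
search never sees.

**What passing means.**  On this benchmark the pipeline attains full
sensitivity with zero accepted decoys, deterministically, because each
decoy violates a hard criterion and planted toxins are bona fide family
members.  Real data differ in ways the generator does not emulate: indel
variation within the toxin family, leaders/tails that straddle the rule
boundaries, fragmented assemblies, annotation errors, and homologs of the
anchor proteins that are not secretion systems.  The benchmark validates
the machinery (coordinates, scoring, filtering, assembly), not the field
performance of the rule set.

## Numerical and design choices

- One coordinate convention internally (0-based half-open); GenBank/GFF3
  converted at the I/O boundary only.  Circular contigs are not modelled.
- ORFs must lie fully inside their window; partial genes at window edges
  are not called.  Windows clipped at contig edges are kept.
- The longest-only ORF mode keeps, per (strand, stop), the longest ORF that
  satisfies the length band, making it a subset of the all-starts output.
- Anchor thresholds are calibrated per reference profile on the length
  distribution of the scanned proteins (seeded); pipeline thresholds are
  recalibrated per rebuilt model with a per-iteration seed offset.
- Degenerate inputs: empty FASTA → explicit empty-input error; all-gap
  alignment columns → model-build error; a mid-iteration rebuild failure
  aborts with the state of the last completed round; an empty cluster list
  writes valid header-only outputs.
- Problem sizes in the shipped benchmark and tests (20 genomes × 120 kb,
  10⁴-instance oracle sweeps, enumeration oracles at L ≤ 3) were chosen to
  make every check exact or exhaustively verifiable at desk scale.

## Known limitations

- No Dirichlet-mixture priors or sequence weighting in profile estimation
  (uniform weights; flagged as a config hook).
- No domain-envelope decomposition: a sequence with two toxin cassettes
  scores as one glocal alignment.
- The anchor step requires CDS annotation or the slower six-frame mode;
  no gene prediction is performed.
- External aggregation predictors are not reimplemented; their published
  per-protein spans are illustrations, not targets, and only pre-exported
  tracks are consumed.
- Remote databases are never queried by the library; the only network
  touchpoint is the optional reference-protein fetch script.
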