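# cdzminer

Discovery of **Cdz-like contact-dependent bacteriocin systems** in bacterial
genomes, plus the companion statistics used to characterise them in co-culture
killing assays.

Cdz systems are an atypical class of two-peptide bacteriocins: small
(~5–10 kDa) toxins that remain associated with the producing cell surface and
kill neighbouring cells on contact.  Their genomic signature is distinctive —
a type I secretion system (T1SS: an ABC transporter plus a membrane-fusion
adaptor) with one to three small toxin genes within ~10 kb, each toxin
carrying:

1. a full length of **60–151 residues**,
2. an N-terminal secretion **leader ending in G[G/A/S]** (cleaved; 10–35
   residues),
3. one or two **glycine zippers** — `GxxxGxxxG` motifs with glycine anchors at
   exact period 4 and small hydrophobic residues between them, *flanked but
   never interrupted* by a proline or charged residue,
4. a short, charged/polar **C-terminal tail**.

`cdzminer` mines user-supplied genomes for this signature with a
T1SS-anchored genomic-context search and an iterative profile-HMM homology
search, and classifies candidates with the four-part rule set above.

## What the package does

- **`seqio`** – FASTA / GenBank / BED / GFF3 I/O; one internal coordinate
  convention (0-based half-open), converted at the boundary.
- **`orfscan`** – all-possible-ORF enumeration (60–200 aa, six frames,
  bacterial genetic code).
- **`profilehmm`** – a profile HMM built from a seed toxin alignment; glocal
  forward/Viterbi scoring in bits against a background residue model, score
  calibration on random sequences, HMMER3 ASCII export, and a pluggable
  engine contract (a `pyhmmer`-backed adapter ships for cross-checking).
- **`gzfilter`** – the rule-based toxin classifier (leader / zipper / flanks
  / tail / polar-span filters) with a per-criterion verdict.
- **`pipeline`** – anchors → 10 kb windows → ORFs → iterative search (2
  rebuild rounds, as in jackhmmer-style searches) → cluster assembly
  (orphans without a T1SS within 10 kb are dropped) → report tables.
- **`aggcons`** – ≥3-of-4 per-residue consensus over pluggable
  aggregation-propensity predictor tracks.
- **`competestats`** – CFU arithmetic from serial-dilution spots, the
  competitive index CI = (ind_tf/prod_tf)/(ind_t0/prod_t0), reporter
  fold-induction, and propidium-iodide–positive fractions.
- **`synthgen`** – a seeded generator of synthetic genomes with planted
  clusters, single-violation decoys and truth tables, so the whole pipeline
  is testable offline.

## Worked example

```bash
# generate 5 synthetic genomes with planted Cdz-like clusters
cdz-miner simulate --seed 7 --n-genomes 5 --out demo

# mine them with the emitted seed alignment and T1SS references
cdz-miner scan --genomes demo/genomes --seed-msa demo/seed_msa.afa \
    --t1ss-refs demo --out demo/scan
```

which prints

```
5 genomes, 40 planted elements -> demo
5 anchor loci; 5 accepted toxins; 5 clusters -> demo/scan
```

Each genome carries one planted T1SS operon (the 5 anchor loci found), and
the 5 accepted toxins are the planted family members — one single-toxin
cluster per genome in this draw.  `demo/scan/`
contains `clusters.gff3` (anchor + toxin coordinates), `toxins.faa`
(full-length and mature candidate proteins), `report.tsv` (one row per
candidate with its per-criterion classifier verdict and bit score),
`summary.tsv` (toxin-count-class distribution) and `run.log` (config echo).

The same library calls are available in Python:

```python
from cdzminer import SynthParams, generate, scan, MinerConfig

data = generate(SynthParams(seed=7, n_genomes=5))
result = scan(data.genomes, data.seed_msa, data.t1ss_refs, config=MinerConfig(seed=7))
len(result.clusters)   # 5
```

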