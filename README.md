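# srnavirome

Small RNA-based virome characterization for arthropod samples.

Metagenomic virus discovery from RNA sequencing struggles with three
problems: endogenous viral elements (EVEs) masquerading as viruses,
genome segments of one virus that cannot be linked by sequence
similarity, and "dark matter" contigs with no database hit at all.
Small-RNA sequencing solves all three, because the host's own antiviral
pathways label replicating viruses: Dicer-2 cleaves viral dsRNA
replication intermediates into 21-nt siRNAs drawn symmetrically from
both strands, the piRNA ping-pong cycle produces 24–29-nt read pairs
with a 10-nt 5′–5′ overlap (U1 on antisense, A10 on sense reads), and
segments of one virus co-occur across independent libraries.

`srnavirome` turns that logic into a tested pipeline, for virologists
and vector-biology groups analysing small-RNA libraries:

* **QC and mapping** — adapter trimming, Phred/length/ambiguity filters,
  and a Bowtie-v1-style ≤ 1-mismatch both-strand mapper with a
  brute-force oracle it is tested against;
* **profiles** — strand-resolved size distributions (15–35 nt), 5′-base
  bias, joint size × strand Z-scores, per-size-class coverage, and RPKM
  of 20–22-nt reads;
* **curation** — exogenous-virus vs putative-EVE calls (truncated ORF
  *and* no symmetric 21-nt peak ⇒ EVE), plus CD-HIT-style redundancy
  clustering (identity ≥ 0.90, coverage of the shorter ≥ 0.90);
* **association** — hierarchical co-occurrence clustering of the
  contig × library RPKM matrix (Euclidean, average linkage) merged with
  shared-closest-reference links, with Z-profile and (GC, CpG O/E)
  concordance as supporting evidence;
* **piRNA** — ping-pong 5′–5′ overlap spectra with Z-scores and U1/A10
  positional bias;
* **composition** — GC content and dinucleotide observed/expected
  ratios (CpG O/E ≈ 1 under independence, < 0.4 typical of
  bunyaviruses);
* **features** — ambigrammatic ORF layout, terminal G/C runs, −1
  frameshift slippery-heptamer scan (GGAAAAC and the XXXYYYZ consensus),
  capsid/polymerase frame layout, and in-silico PCR;
* **synthetic_data** — a ground-truthed virome generator (multi-segment
  viruses with shared abundance fingerprints, ping-pong piRNA models,
  EVE decoys, host background) that every stage is tested against.

Statistics in brief: for a contig, reads are tallied per size
s ∈ [15, 35] and strand; the Z-profile standardizes the 42 frequency
cells jointly. RPKM = n₍₂₀₋₂₂₎ / (L/10³ · N/10⁶) with L the contig
length and N the library's QC-passing reads. The ping-pong statistic is
the Z-score of the count of opposite-strand 24–29-nt pairs at 5′–5′
distance d over d = 1..30; a signature is a peak at d = 10 with
z₁₀ ≥ 1.96. CpG O/E = f(CG)/(f(C)·f(G)) over overlapping dinucleotides.

See `docs/methods.md` for the full model, parameter table, and
limitations.

## Worked example

Generate a synthetic virome (three bisegmented viruses across four
libraries plus one EVE decoy) and run every stage:

```bash
srnavirome simulate --seed 7 --outdir demo/data --depth 3000 --eve-decoys 1
srnavirome run-all demo/config.yaml   # paths to the files written above
```

`demo/out/verdicts.tsv` — the EVE rule separates replicating viruses
(symmetric 21-nt peak, intact ORF) from the decoy:

```
contig_id   verdict       sirna_peak  symmetry  orf_truncated
NarnaV_S1   exogenous     True        0.9787    False
NarnaV_S2   exogenous     True        0.9952    False
BunyaV_S1   exogenous     True        0.9214    False
...
EVE_1       putative_EVE  False       0.0000    False
```

`symmetry` is min/max of the two 21-nt strand counts — near 1 means the
peak is drawn evenly from both strands, the hallmark of Dicer-2 activity
on a replication intermediate.

`demo/out/segment_groups.tsv` — co-occurrence reunites the segments of
each virus, including `NarnaV_S2`, which carries no annotation (dark
matter) and is grouped purely by abundance, profile and composition
concordance:

```
group_id  contig_id  basis
group_1   BunyaV_S1  co-occurrence,composition-concordance,profile-concordance,shared-reference
group_1   BunyaV_S2  co-occurrence,composition-concordance,profile-concordance,shared-reference
group_2   NarnaV_S1  co-occurrence,composition-concordance,profile-concordance
group_2   NarnaV_S2  co-occurrence,composition-concordance,profile-concordance
...
```

`demo/out/pirna_summary.tsv` — every replicating contig shows the
ping-pong signature (spectrum peak at distance 10, z₁₀ ≈ 5) and the
U1 bias of antisense piRNAs:

```
contig_id   z10     peak_distance  signature  U1_antisense  A10_sense
NarnaV_S1   5.1428  10             True       0.7363        0.5387
BunyaV_S1   5.1910  10             True       0.7576        0.6745
...
EVE_1       0.0000  None           False      nan           nan
```

(A10 is diluted below U1 here because degradation reads of piRNA size
on the sense strand carry no bias — see `docs/methods.md`.)

Individual stages are also available as subcommands (`qc`, `map`,
`profile`, `curate`, `associate`, `pirna`, `composition`, `features`,
`pcr`, `simulate`), e.g.:

```bash
srnavirome pcr contigs.fasta --name S2 \
  --forward CCTTCCGTGGAGAATACTGG --reverse TTTGGACGGTGATACCACGG
```

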