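# Methods

`srnavirome` implements a small RNA-based virome characterization
procedure for mosquito (and other arthropod) samples: starting from QC'd
small-RNA reads and assembled contigs, it discriminates replicating
exogenous viruses from endogenous viral elements (EVEs), associates
contigs — including "dark matter" with no database similarity — into
multi-segment viruses, profiles siRNA/piRNA signatures, and verifies
genome-organization features at the sequence level.

## Biological model and assumptions

Replicating RNA viruses in mosquitoes expose double-stranded replication
intermediates that Dicer-2 cleaves into 21-nt siRNAs drawn symmetrically
from both strands. EVEs — virus-derived insertions in the host genome —
are transcribed from one strand only, lack the symmetric 21-nt peak, and
typically carry interrupted ORFs. Some viruses additionally feed the
piRNA pathway: ping-pong amplification produces 24–29-nt sense/antisense
read pairs whose 5′ ends overlap by exactly 10 nt, with U enriched at
position 1 of antisense (responder) reads and A at position 10 of sense
reads. Non-specific degradation contributes 18–35-nt reads biased toward
the more abundant viral strand, which is what the polarity-orientation
rule exploits. Finally, segments of one virus rise and fall together
across independent libraries, so co-occurrence of 20–22-nt read
abundance (RPKM) across libraries groups segments even when one of them
has no database hit.

The pipeline assumes reads are already depleted of host/bacterial
sequence (or that such reads simply fail to map to the supplied contigs)
and that contigs were assembled externally; assembly and similarity
search are out of scope, with similarity results imported as a TSV.

## Procedure and key parameters

| stage | rule | default | notes |
|---|---|---|---|
| QC | discard mean Phred < 20, length < 15 or > 35 nt, any ambiguous base | — | discards attributed to exactly one rule (length, then ambiguity, then quality) so tallies partition the input |
| adapter | 3′ adapter located by suffix-anchored match at ≥ 90% identity, ≥ 3 nt overlap | off | optional fixed 5′ clip for libraries with barcode-adjacent inserted nucleotides |
| contigs | admit length ≥ 200 nt | 200 | the boundary is inclusive |
| annotation | significant hit: e < 1e−5 (nt) or e < 1e−3 (aa) | — | viral + non-viral significant hits ⇒ viral with a conflict flag for curation |
| mapping | end-to-end, ≤ 1 mismatch, both strands, all best-stratum placements | 1 | pigeonhole half-seeds (k = 10) guarantee 1-mismatch sensitivity for reads ≥ 20 nt; shorter reads fall back to exhaustive scan; N never matches |
| Z profile | z over the 42 size × strand frequency cells jointly | joint | per-strand standardization available behind a flag; zero variance ⇒ all zeros |
| RPKM | 20–22-nt reads / (contig kb × library M reads) | — | denominator is total QC-passing reads of the library: computable before mapping, stable across contig sets |
| EVE rule | putative_EVE iff truncated longest ORF AND no symmetric 21-nt peak | symmetry ≥ 0.1, ORF span ≥ 50% | "truncated" operationalized as longest-ORF span < half the contig, or lacking both start and stop away from contig edges |
| clustering | greedy length-descending, identity ≥ 0.90 and coverage-of-shorter ≥ 0.90 vs representative | 0.90/0.90 | both orientations tested; assemblers emit arbitrary strands |
| co-occurrence | Euclidean distance on raw RPKM rows, average linkage, cut at median merge height | median | `--cut-height`/`--n-groups` override; log2 is a display transform only, never used for distances |
| orientation | strand with ≥ 60% of non-21-nt (18–35) reads wins; below that, longest-ORF strand | 0.60 | idempotent; reported with the rule that fired |
| ping-pong | all-vs-all 5′–5′ distances of opposite-strand 24–29-nt reads, distances 1–30, Z over the spectrum | z_crit 1.96 | signature requires the peak at distance 10 *and* z10 ≥ z_crit |
| composition | overlapping dinucleotides, one strand, N windows skipped | — | CpG O/E = f(CG)/(f(C)·f(G)); ≈ 1 under independence, < 0.4 typical of bunyaviruses |
| PCR | exact primer match (mismatches configurable), product spans both primer 5′ ends inclusive | 0 | verified against constructed amplicon arithmetic |

Global identity (used by clustering and for cross-virus comparisons) is
Needleman–Wunsch: nt match +1 / mismatch −1 / gap open −2 / extend −0.5;
aa BLOSUM62 with gap open −10 / extend −0.5. Identity is identical
columns over residue-to-residue columns, so an exact substring scores
identity 1.0 with full coverage of the shorter sequence — the semantics
the redundancy-clustering thresholds need.

## Synthetic viromes: what they emulate and what they do not

The generator (`synthetic_data`) is first-class, tested code. A
`VirusSpec` fixes segment lengths, a per-library abundance fingerprint
shared by all segments of the virus, and a read model
(siRNA / piRNA / degradation fractions, ping-pong fraction, U1/A10
biases, degradation strand bias). Realized counts per contig × library
are multinomial around fingerprint × segment length perturbed by
lognormal noise (σ = 0.3, the standard multiplicative model for
sequencing abundance). The positional biases are applied so the *final*
U1/A10 frequency equals the configured value over a uniform base
background (a base is forced with probability (f − 0.25)/0.75).
Ambigrammatic sequences are built from the 58 codons that are neither
stops nor reverse complements of stops, with a 5′ G-run and 3′ C-run as
first/last codons. EVE decoys get in-frame stops until the longest ORF
in any frame spans < 40% of the contig, and one-strand 24–29-nt reads
only. A configurable fraction of each library (default 10%) is drawn
from a random host sequence and must remain unassigned.

The default study condition is three bisegmented viruses across four
libraries with well-separated fingerprints. With six matrix rows the
median of the five merge heights is the largest within-virus merge, so
the default median-height cut separates exactly the between-virus
merges when fingerprints dominate the noise.

What the generator does **not** emulate: sequencing errors and quality
decay along reads, adapter read-through beyond a fixed suffix, uneven
positional coverage (hotspots), chimeric contigs or misassemblies, and
real phylogenetic structure in the sequences. Passing tests therefore
demonstrate that the statistics and decision rules recover the planted
structure under the stated noise model — not that they are robust to
assembly artifacts or base-calling error in field data.

## Numerical choices and degenerate inputs

* Zero-variance Z-profiles (all cells equal, including empty) are all
  zeros rather than NaN.
* Strand symmetry min/max is 0 when either strand is empty; a contig
  with no reads at all is a putative EVE "by absence of small-RNA
  support".
* Agglomeration ties break on the lowest-index pair (scipy's
  deterministic ordering); permuting matrix rows permutes group labels
  only.
* Sequences without C or G have undefined CpG O/E (NaN) and are treated
  as infinitely far in nearest-neighbour concordance.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; synthetic outputs are byte-identical per
  seed, and the pipeline is bit-reproducible given inputs and config.

## Problem sizes

Simulated viromes used by the test and acceptance suites run at 3,000 to
8,000 reads per library over 6–20 contigs of 0.9–3 kb, with 20
independent seeds for the recovery statistics; the mapper/oracle
comparison uses up to 10 kb of contig sequence. These sizes give stable
statistics (recovery rates and biases reproduce to within a few percent
across seeds) while the full suite completes in a few minutes.

## Known limitations

* The mapper is ungapped and desk-scale (pure Python); it reproduces the
  alignment contract, not the throughput, of a production short-read
  aligner.
* Greedy redundancy clustering compares members to the representative
  only (single-linkage-to-representative, as in CD-HIT); member-member
  identity is not enforced.
* "Truncated ORF" is a proxy; the original judgment compares ORF extent
  to database homologs, which requires similarity searches that are out
  of scope here.
* Dark-matter segments are associated by co-occurrence and concordance
  evidence; with fewer than three libraries the abundance fingerprint
  carries little signal and grouping degrades to shared-reference links.
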