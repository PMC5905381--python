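# Methods

This note documents the models, algorithms and numerical choices behind
`ampcon`, and what the simulation-based tests do and do not demonstrate.

## Problem setting

Input is a multiplexed long-read amplicon run: each sample's PCR product
(~500–900 bp mitochondrial barcode) carries a sample barcode and tailed
primers, and the reads show the error profile of nanopore basecalls —
roughly 10% per-base error dominated by indels, with systematic
under-calling of homopolymer run lengths. The task is to recover, per
sample, a consensus sequence accurate enough for species identification
(>99% identity to a Sanger-derived truth), and to quantify how accuracy
depends on read depth and multiplexing.

## Quality model and filtering

Per-read quality is averaged on the error-probability scale:
`Q_read = −10·log₁₀( mean_i 10^(−q_i/10) )`. This is the convention of
standard nanopore read filters and is dominated by the worst bases; a
read of Q10s with one Q30 base scores ≈10, not 20. The filter keeps
reads with `Q_read > 13` **and** length > 200 bp, both strict
inequalities. A read failing both is counted against the length
criterion (checked first); kept + dropped counts always total the input.

## Demultiplexing

Each barcode and its reverse complement is searched by semi-global
(infix) edit-distance alignment within the first and last 150 bases of
the read. The best hit wins if its edit distance is at most
`floor(0.25 × barcode length)`; ties break by fewer edits, then 5'-end
hit, then barcode id. Strand is reported from the orientation of the
matching barcode sequence; in double-ligated libraries both ends carry
the barcode, so strand is informative only for single-ended constructs.

Adapter-only junk — the signature of failed adapter ligation — is
flagged by iteratively locating near-exact (≤10% edits) copies of every
adapter-flank+barcode pattern in the read, masking each hit, and testing
whether the interval union covers more than 80% of the read. Flagged
reads are excluded from consensus building. Note that heavily mutated
junk copies can escape the 10% edit bound; such reads are instead
removed by the length filter (pure adapter concatenations are short).

Reads left unassigned can be rescued by mapping them back against the
run's finished consensi (≥75% identity over ≥50% of the read length),
which quantifies how much signal the barcode classifier left behind.

## De novo consensus

**Overlap detection.** The exact operation is an overlap (free-end-gap)
alignment with match +1, mismatch −1, affine gap 2 + 1·(k−1), accepting
spans ≥ `min_overlap` (50 bp) at identity ≥ `min_overlap_identity`
(0.70); both orientations are tried. Inside clustering, pairs are first
screened by a fast containment alignment (edlib): identities at or above
the threshold accept the edge directly, identities more than 0.03 below
it reject, and only the narrow gray zone falls through to the exact DP.
Simulated same-locus pairs at the default error model sit near 0.80,
unrelated pairs near 0.55, so the screen is decisive in practice.

**Clustering.** Single-linkage over the overlap graph, with two
standard scale concessions: pairs already in one component are skipped
(provably no effect on the result), and once components grow, cross-
component edges are probed only between each component's first five
reads. For homogeneous amplicon clusters this is exact up to that
representative count; pathological topologies in which only
non-representative members overlap would be merged late or not at all.

**Center-star draft.** All cluster reads are oriented to and aligned
against the longest read; the induced pileup is called by column
majority over {A, C, G, T, deletion} (ties break A<C<G<T with deletion
last, for determinism), and an insertion is emitted at a junction when
carried by more than half of the reads spanning it. Columns no read
covers fall back to the anchor base.

## Polishing

Polishing alternates two mechanisms until a joint fixed point (or a
round budget of 8):

1. **Majority + run-length voting.** Reads are realigned to the current
   consensus (semi-global, both orientations, ≥60% identity to
   participate) and the pileup is re-called as above. Every homopolymer
   run of ≥2 bases is then re-called from the per-read run-length mode:
   a read's observation is the number of bases it carries across the
   run's columns and interior junctions, plus run-base characters parked
   by equivalent-cost alignments as boundary insertions or as mismatches
   on the single flanking column. Ties vote for the longer length,
   because the deletion bias puts under-called lengths in excess when
   the consensus is at the true length. Runs whose column majority is
   not itself a pure run are left to the column calls, so substitution
   evidence inside a run is never overwritten.

2. **Median-string refinement.** At the majority fixed point, minority
   evidence (junction insertions or column runner-ups carried by >25% of
   covering reads) is turned into candidate single edits, and each is
   kept only if it strictly lowers `Σ_r d_edit(r, consensus)` — the
   median-string objective an amplicon consensus should locally
   minimize. Candidates that would change a voted run's length are
   excluded: the edit-distance objective is degenerate exactly at run
   boundaries (a carrier read's credit can be absorbed by equal-cost
   paths), so run lengths belong to the vote and isolated columns to the
   objective. Accepted refinements re-open the majority call on the
   next round.

The polish report carries two depth figures: `mean_depth`, the mean
per-column aligned depth, and `total_depth`, the sum of mapped read
lengths over the consensus length. Junk reads that map only partially
inflate the total but not the mean, so a large gap between the two is a
library-quality diagnostic.

**Trimming.** The forward primer is located near the 5' end and the
reverse-complemented reverse primer near the 3' end (≤20% edits, both
orientations of the consensus tried); everything outside the insert —
including residual barcode/adapter tails — is removed, and the output is
oriented so the forward primer reads 5'→3'. If neither primer is found
the consensus is returned unchanged with a warning flag.

## Reference-guided consensus

Reads are aligned semi-globally to the reference (edit-distance bound
starting at the 100-band and doubling on failure; <60% identity is
unmapped), the pileup is called as in the de novo path, and the draft is
handed to the same polisher. Columns below `min_depth` (default 1, i.e.
zero-coverage columns) emit the reference base. This reference fill is a
deliberate design choice: it makes reference bias explicit — a divergent
congener's content appears verbatim wherever reads are missing — rather
than hiding it behind Ns. With full-coverage read sets and this
pileup caller (which, unlike per-column base callers, votes on deletions
and emits insertions), the polished reference-guided consensus is in
practice as accurate as the de novo one; the historical accuracy gap
between the strategies stems from indel-blind callers and is not
reproduced here. De novo remains the default recommendation because it
needs no reference at all.

## Evaluation

Consensus vs truth uses optimal global alignment with match +1, mismatch
−1, gap open −2, gap extend −1 (a k-gap costs 2 + (k−1)). End-gaps on
the query side are free so untrimmed flanks are not penalized; the truth
must be spanned, so missing consensus ends count as deletions. Identity
is `matches / alignment columns` over the truth-spanning region — one
column per gap base, the only convention under which indels reduce the
percentage. Differences are merged into events; an indel is flagged as a
homopolymer indel when the deleted bases sit in a truth run of ≥3, or
the inserted bases match an adjacent truth run of ≥3. Reports round
half-even to one decimal; internal values stay full precision.

The subsampling experiment draws read subsets without replacement at
each (size, replicate) cell using `default_rng([seed, size, replicate])`
— a documented derivation, so any cell is reproducible in isolation —
and runs the configured pipeline on each subset.

## The simulator

`simulate_run` emits, per locus, reads of
`flank + barcode + primer_F + insert + rc(primer_R) + rc(barcode) + rc(flank)`
mutated base-by-base at the error model's rates, reverse-complemented
with probability 0.5, with per-base qualities drawn from
Normal(qual_mean, qual_sd) clipped to [2, 40]. Junk categories are
adapter-only concatenations (2–5 flank+barcode copies), contaminants
(uniform-random inserts or another locus' truth under this locus'
barcode — the cross-talk failure mode), and positive-control inserts.
Junk counts are fractions of the total run, rounded by largest
remainder, so configured locus read counts are exact. The whole run is a
pure function of the seed; FASTQ output is byte-identical across
repeats.

Default rates are 3% substitution, 3% insertion, 5% deletion with a 2×
deletion multiplier inside homopolymer runs ≥3 (~11% total), and
qualities Normal(14, 3) — approximating R9-era nanopore basecalls. With
these quality parameters the error-averaged read quality concentrates
just below Q13, so the Q>13 filter removes roughly half of the simulated
reads; that mirrors the heavy filter losses reported for degraded field
libraries and exercises the bookkeeping, but the retained/dropped split
is quality-driven only — the simulator does not couple a read's quality
string to its actual error count.

What the simulator does **not** model, and the tests therefore cannot
show: signal-level artifacts, chimeras, quality–error correlation,
length-dependent error profiles, read truncation, and real barcode/
adapter chemistry (synthetic stand-in sequences are generated from a
frozen seed; real kit sequences are user-supplied input).

## Problem sizes in the test and benchmark suites

The bundled benchmarks simulate a 4,000-read pool for the subsampling
experiment (scored at 30 and 100 reads, three replicates), a 1,000 + 96
read two-locus multiplex, and property fixtures of 30–300 reads; these
sizes reproduce the regimes of interest (low-coverage accuracy,
asymmetric multiplexing) at desk scale. Unit tests cross-check the
aligners, consensus caller and identity scorer against brute-force
dynamic-programming oracles on small instances, where exhaustive
computation is feasible.

## Known limitations

- Run-length voting is robust at depth ≥50 but inherits sampling noise
  at ~30 reads: the mode of ~30 binomial observations of a 5–6 base run
  is occasionally wrong, which bounds 30-read consensus accuracy near
  99.4–100% on 500 bp amplicons — matching field experience.
- Strand assignment from barcodes is uninformative for double-ligated
  constructs (both ends carry the barcode in both orientations).
- The clustering representative bound (5 reads/component) trades exact
  single-linkage for near-linear scaling on homogeneous clusters.
- `pairwise_overlap` is exact but quadratic per pair; callers at scale
  should go through `cluster_reads`.
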