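# Methods

`tryclip` implements the computational half of an iCLIP (individual-nucleotide
resolution UV crosslinking and immunoprecipitation) experiment on a small,
fully enumerable reference set: the trypanosome spliceosomal snRNAs (U1, U2,
U4, U5, U6), the 139-nt spliced-leader (SL) RNA, tRNA/rRNA decoys and a toy
genomic contig. This note records the model, the parameter choices, the
numerical conventions, and what the synthetic data do and do not establish.

## The cDNA-truncation model

iCLIP relies on reverse transcription stopping at the covalent protein–RNA
adduct. The 5′ end of a sequenced cDNA therefore starts one nucleotide
downstream of the crosslinked base. All of `tryclip` is built around this
single convention:

* a uniquely mapped plus-strand read starting at reference position `s`
  yields a crosslink site at `s − 1`;
* a minus-strand read (genomic contigs only) ending at `e` yields `e + 1`;
* a read starting at position 1 has no upstream nucleotide and is dropped
  (`DROPPED_EDGE`, counted).

The simulator encodes the *same* convention — the biological insert of a
read with truth site `p` is the reference substring starting at `p + 1` —
so pipeline and generator form a closed, exactly checkable pair. A
`--site-at-start` sensitivity variant was considered and rejected: with the
generator and pipeline sharing one convention, the flag would only test
its own inverse. Crosslink sites on the reference are 1-based inclusive
everywhere; BED (0-based half-open) appears only at the export boundary.

## Read structure and processing

A raw read is `lead random-mer (3 nt) + sample barcode (4 nt) + trailing
random-mer (2 nt) + insert + 3′ adapter + 'A' padding`, truncated to the
read length (default 105 nt, a typical single-end short-read length for
this assay). The two random parts concatenated in read order form the 5-nt
UMI. The layout is a parameter (`BarcodeLayout`) because published iCLIP
designs vary; 3+4+2 is the classic arrangement.

**Demultiplexing.** A read is assigned iff exactly one barcode lies within
`max_mm` mismatches of the observed barcode field; zero or several
candidates give `UNASSIGNED`. The default `max_mm = 0`; barcode sets are
validated up front for pairwise Hamming distance ≥ `2·max_mm + 1` (≥ 2 at
minimum), so assignment can never silently cross samples. The default
sample set (`u1c: ACGT`, `u70k: CATG`, `wt: GTCA`) has pairwise distance 4
and stays unambiguous at `max_mm = 1`, the setting used when substitution
errors are simulated.

**Adapter trimming** is a single pass: the leftmost full internal
occurrence of the adapter within a 10% mismatch budget wins; otherwise the
longest terminal suffix of the insert matching an adapter prefix with
overlap ≥ 3 is removed. The default adapter is the 20-nt iCLIP 3′ linker
`AGATCGGAAGAGCGGTTCAG`. This sequence was checked to have no approximate
self-overlap: no shift `k` exists at which the adapter matches itself
within the mismatch budget minus one, so the leftmost-occurrence rule cuts
exactly at the insert/adapter boundary on error-free reads rather than a
few bases early. Trimming is deliberately *not* iterated to a fixpoint:
when a genuine insert happens to end in an adapter-prefix-like suffix
(probability ≈ 4^−3 per read at overlap 3), a second pass would cut real
biology. The price is that idempotence holds only for inserts that do not
end in such a suffix — an intrinsic ambiguity of adapter trimming, made
explicit in the property tests.

**Length filter.** Trimmed inserts shorter than 15 nt are counted but not
written; 15 nt is the shortest insert that maps uniquely with useful
probability on references this small. The accounting identity
`n_input = n_unassigned + n_too_short + n_passed` is enforced on every run.
No quality-based filtering is performed (qualities are ignored throughout).

## Alignment

The mapper is an exhaustive ungapped Hamming scan (`max_mm` default 1): all
placements of the insert on every allowed reference and strand are scored
with vectorised byte comparisons, and the full best stratum (minimum
distance) is returned. Uniqueness is judged within the best stratum only,
so a perfect hit with a distance-1 shadow elsewhere is still unique. RNA
references are searched sense-strand only — iCLIP cDNAs are sense copies
of the bound RNA — while genomic contigs are searched on both strands. No
indels are modelled; on 60–1,100-nt references an exact scan is fast, and
it admits a position-by-position pure-Python oracle against which the
implementation is tested for strict equality. For real genome-scale data
the mapping step is the natural seam at which to substitute an external
short-read aligner; everything downstream consumes only `(ref, start, end,
strand)` tuples.

**Two-pass SL rescue.** The SL RNA is genomically encoded as a tandem
array of identical copies, so SL reads can never map uniquely in a genome
pass. Pass 1 aligns against every reference except the standalone SL
sequence; reads left multi-mapped or unmapped are then aligned to the
139-nt SL RNA alone, and a unique SL placement rescues them. A read unique
in pass 1 is never reassigned. Reads whose single best hit lies on a tRNA
or rRNA are excluded (`excluded_class`) before profiling.

## Profiles and UMI deduplication

Tag counts are "random-barcode filtered": at each `(sample, reference,
site)` the count is the number of distinct UMIs, with exact string
comparison (no 1-mismatch UMI clustering — exactness admits a set oracle,
and clustering would conflate distinct ligation events at saturated
sites). With a 5-nt UMI there are 4⁵ = 1024 codes per site; at heavily
occupied sites the deduplicated count saturates according to the classical
birthday/occupancy expectation `1024·(1 − (1 − 1/1024)^n)`, which is the
intended behaviour of UMI counting, not a loss — the simulator draws UMIs
uniformly, so truth table and pipeline saturate identically.

Replicate profiles are summed element-wise without normalisation, matching
how replicate iCLIP tag counts are conventionally pooled. Profiles display
positions `1..L−15` (the last 15 nt cannot carry a mappable tag), with a
per-reference override table defaulting to `{SL: 123}` to match the
conventional printed SL profile range. Class distributions report each
snRNA class as a fraction of the non-SL total; SL tags, produced by the
separate alignment pass, are a stand-alone line item and never enter the
snRNA denominator.

## Profile statistics

* **Region fractions** are computed over the displayed range
  `1..display_end`, since that is the mappable universe of the assay;
  fractions over a partition of the displayed range sum to 1.
* **Peak calling** is a descriptive local-maximum report (height ≥ 10% of
  the profile maximum, strict maxima over a ±2-nt window, plateaus
  reported at their 5′-most position with their extent). No significance
  model is attached: on references this small, peak lists are read by eye
  and a null model for RNase-resistant RNP fragments would be fiction.
* **Replicate agreement** is Pearson or Spearman (average ranks for ties)
  over the displayed range; zero-variance profiles raise rather than
  returning a silent NaN.

## Base-pairing registers

`duplex_register` scores the antiparallel register between an snRNA
segment (read 3′→5′) and a 5′-splice-site-spanning target (read 5′→3′) at
an explicit offset. Watson–Crick pairs and, by default, G·U wobble pairs
count as paired (RNA duplex; toggleable). The offset is an explicit input
rather than an inferred optimum because published register diagrams fix
the alignment by hand; an optimiser would silently disagree with them.
Target coordinates use the −1/+1 splice-site convention (the
`splice_index` marks the last exonic nucleotide). Crosslink overlays mark
snRNA positions whose deduplicated tag count reaches a threshold, and
separately report marked positions within 5 nt *outside* the paired range
— the characteristic situation in which strong crosslinks flank a
protected, base-paired element such as the U6 ACAGAG box.

## The synthetic generator: what it emulates, and what it does not

The toy reference set is deterministic in the seed: U1 (75 nt, with the
U1-70K site AUCACGAA at 20–27 and an Sm-like ACUUUG), U6 (97 nt, ACAGAG at
37–42), SL (139 nt, 39-nt mini-exon, GT at intron positions +1/+2), U2/U4/
U5, one tRNA and one rRNA decoy, and a genomic contig embedding `sl_copies`
(≥ 2, default 3) exact SL copies plus an exon–GT…AG-intron–exon gene.
Candidate sets are redrawn (deterministically) until no 15-mer outside the
SL array is shared between mapping loci, including the contig minus
strand, so unique mappability of signal reads is guaranteed by
construction rather than by luck.

Truth profiles place stated masses uniformly within their regions
(exactly), route background mass uniformly over decoy positions, and
spread any remainder uniformly over snRNA/SL positions outside the peak
regions. Allowed sites are `[2, L−15]`: position 1 would need a read
starting at position ≤ 1, and sites beyond `L−15` would yield inserts
shorter than the length filter — the same constraint that motivates the
display truncation.

Defaults chosen where the study conditions leave freedom: insert lengths
uniform on [15, 40] (RNase-fragmentation lengths are not reported for this
assay; the range brackets typical iCLIP cDNA inserts), substitution errors
only (no indels, no platform-specific error profiles), constant `I`
quality strings, deterministic `A` padding after the adapter.

Passing the end-to-end tests on these data shows that the pipeline's
bookkeeping is exact under its own model: barcode→sample, UMI, site
placement, SL rescue and deduplication commit no off-by-one or collision
errors, at any seed. It does *not* show robustness to features real lanes
have and the generator lacks: indels, 5′ adapter contamination, quality
decay, non-uniform PCR amplification, partial RNase resistance of intact
RNPs, or a 35-Mb genome's repeat structure. The control (`wt`) sample is
simulated like any other; no control subtraction is implemented.

## Problem sizes and numerical conventions

The standard verification lane is 50,000 reads (three multiplexed
samples) with the study mixture — 40% of crosslink mass on U1 nt 1–9, 20%
on SL nt 36–43, 10% on U6 nt 30–45, 5% tRNA/rRNA background, remainder
uniform — which exercises every pipeline branch while keeping the full
suite in tens of seconds; the robustness and replicate checks use 20,000
reads each. Ties in peak ordering break toward the 5′-most position;
truth-profile weights are validated to sum to 1 within 1e-9; region-
fraction partition identities hold to 1e-12. All randomness flows from a
single integer seed through one `numpy` generator per simulated lane, in
a fixed draw order (samples, sites, insert lengths, UMIs, errors), so
identical configurations are byte-identical.

## Known limitations

* Ungapped alignment only; a single indel in a read defeats mapping.
* The exhaustive mapper is for small reference sets; genome-scale inputs
  need an external aligner behind the mapping seam.
* UMI counts at saturated sites are occupancy-limited (5-nt UMI); the
  generator and pipeline agree, but absolute tag counts at such sites
  under-represent event counts, as in the real assay.
* No peak significance model, no control subtraction, no spliced reads.
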