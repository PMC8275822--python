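# Methods

This note documents the models and procedures implemented in `lncpep`, the
parameter choices where the design was genuinely open, what the synthetic
data generators do and do not emulate, and known limitations.

## ORF scanning and the microprotein database

A transcript is normalized to the DNA alphabet `{A, C, G, T, N}` (RNA `U`
mapped to `T`, uppercased); any other character is rejected with its
position. Two scans run over both strands, the reverse strand being
represented by the reverse complement with its own 0-based half-open
coordinate system (a minus-strand interval `[s, e)` maps to transcript
positions `[L − e, L − s)`):

* **AUG scan** — every ATG in every frame is extended codon by codon to the
  first in-frame stop. An optional Kozak filter applies the relaxed
  consensus of `gccRccATGG`: purine at −3 *or* G at +4. It is off by
  default because the stringency of the published "Kozak-containing" scans
  is not standardized.
* **Stop-to-stop scan** — each frame's maximal codon runs bounded by stop
  codons are emitted, capturing products whose initiator is non-AUG or
  unknown. By default both bounding stops are required; ORFs truncated by
  the transcript end can be admitted with a flag.

Codons containing `N` translate to `X` and terminate ORF extension without
providing a bounding stop — a conservative reading of ambiguous bases.
Closing stop codons are included in the nucleotide interval but never in
the amino-acid sequence, so `len(aa_seq)` is the interval's codon count
minus one when a stop is present.

**Start classification** uses the interval's first codon: `ATG` → AUG; one
of the nine single-mismatch variants of ATG (CTG, GTG, TTG, ATA, ATT, ATC,
ACG, AAG, AGG — the standard near-cognate set) → NEAR_COGNATE; anything
else → UNKNOWN. An ATG internal to a stop-to-stop interval does not
re-classify the interval; it spawns its own nested AUG-initiated record.
Consequently the product length is the predicted smORF length for known
starts and the stop-to-stop interval length for unknown starts, both equal
to the record's residue count.

`build_database` merges candidates identical by (transcript, strand, frame,
coordinates), then — with deduplication on, the default — collapses records
sharing an amino-acid sequence into one entry whose provenance lists every
source ORF and whose class is the most informative observed (AUG >
near-cognate > unknown). Record order is deterministic (accession, strand,
frame, start). The default minimum product length is 7 aa: comfortably
below the ~20 aa of the shortest credible MS-identified microproteins while
keeping the database bounded.

## Digestion and novelty

Trypsin cleaves C-terminal to K/R; cleavage before proline is suppressed by
default (the convention of mainstream search engines), configurable. All
peptides with at most `max_missed` (default 2) internal sites and length in
[6, 50] are generated with their missed-cleavage counts; concatenating the
zero-missed-cleavage peptides reconstructs the protein. N-terminal
Met-loss forms are not generated.

A peptide is *novel* when it occurs nowhere in the annotated proteome as an
exact substring. Isoleucine and leucine are collapsed before the comparison
by default because CID/HCD fragmentation cannot distinguish them; the
strict mode is available. Novelty is anti-monotone under proteome growth.
A peptide is *unique* when it occurs in exactly one deduplicated
microprotein sequence; only unique, novel peptides validate a specific
microprotein.

## Fragment ions and PSM acceptance criteria

Monoisotopic masses are used throughout: a fixed 20-residue table, proton
1.007276466 Da, water 18.010565 Da; carbamidomethyl-C (+57.02146) is fixed,
Met oxidation (+15.99491) variable with up to three sites enumerated
combinatorially. For a peptide of length L and fragment charge z:

    b_i = (Σ_{k≤i} m_k + z·m_p) / z        i = 1..L−1
    y_i = (Σ_{k>L−i} m_k + m_H2O + z·m_p) / z

which satisfies b_i + y_{L−i} − 2·m_p = M (neutral mass) for the singly
charged series — an identity the tests verify to 1e−6 Da. Charges 1–2 are
generated by default.

Peak matching is a greedy one-to-one assignment within ±0.02 Da, taken in
ascending |Δm/z| with ties broken toward the more intense peak. On
realistic (well-separated) peak lists this equals the exhaustive optimal
assignment, which the tests check on small instances; the greedy rule is
kept in production for transparency and speed.

A PSM passes when **all** of the following hold (each threshold is a
parameter of `QcParams`):

| criterion      | default rule                                       |
|----------------|----------------------------------------------------|
| LENGTH         | peptide ≥ 6 aa                                     |
| CONTINUITY     | longest run of consecutive ordinals within one series ≥ 5 ("more than four") |
| COVERAGE       | distinct matched (series, ordinal) pairs / 2(L−1) strictly > 0.40 |
| PURITY         | ≤ 50% of the 10 most intense peaks unmatched       |
| KNOWN_PEPTIDE  | peptide novel w.r.t. the annotated proteome        |

Runs never concatenate across the b and y series, and an ordinal matched at
several charges counts once in the coverage denominator — both deliberate
readings where conventions differ. Coverage exactly 0.40 fails the strict
inequality.

Spectral similarity for synthetic-standard comparison is the cosine of
square-root intensities accumulated on fixed 0.02 Da m/z bins; 0.7 is the
suggested "strong match" threshold. Target-decoy q-values rank PSMs by
engine score, estimate FDR as decoys/targets at or above each threshold
(ties pooled, estimates capped at 1), and take the running minimum from the
bottom; the retained set at q < 0.01 is always a prefix of the score-ranked
targets.

## Cohort statistics

Detection matrices hold raw area intensities with `NaN` as "not detected"
and a group label per sample. Group-level detection for presence/absence
comparison is the union over samples (≥ 1), so `missing`/`new` sets are
plain set differences and swapping groups swaps them. The stricter
"detected at least twice within each group" rule applies only to the
normalization/PCA filter — the two rules intentionally differ.

Total-area-sum normalization divides each retained intensity by its
sample's total over retained microproteins, so present values per sample
sum to 1. PCA runs on mean-centered, unscaled normalized intensities with
absent values imputed as zero (zero area is the natural reading of "not
detected" for area intensities); variance scaling is not applied because
the normalized fractions already share a scale. A matrix with zero total
variance yields all-zero scores and variance fractions rather than an
error, so degenerate inputs (e.g. identical samples) remain inspectable.

Sequence coverage is the fraction of residues covered by the union of all
occurrences of the assigned peptides; length histograms use 20-aa bins from
zero; start-class fractions sum to one.

## Synthetic data: what it emulates, and what it does not

* `make_transcripts` plants stop-bounded smORFs of each start class
  (default one per class per transcript, 12–30 aa bodies, 300–600 nt
  transcripts, both strands) into uniform random background; planted ORFs
  contain no internal stop or ATG, and generation retries if the background
  reproduces a planted product elsewhere. Recovery of every planted ORF
  with exact coordinates, strand, frame and class is therefore an exact,
  non-statistical check of the scanner.
* `make_spectrum` renders a chosen subset of the singly-charged b/y ladder
  with Gaussian m/z jitter (default 0.002 Da, an order of magnitude below
  the matching tolerance) and log-normal intensities; noise peaks are
  uniform in m/z but kept ≥ 0.05 Da from every theoretical ion so they can
  never be matched at ±0.02 Da. This makes filter behaviour deterministic:
  a complete ladder passes, a ladder truncated to runs of four fails
  continuity, and measured coverage equals the planted ordinal fraction.
* `make_cohort` draws per-microprotein base abundances log-normally
  (σ = 0.5 natural-log units around 10⁶ area units), adds log-normal
  replicate-level spread (σ = 0.25, ≈ 25% CV, typical of label-free
  replicates), detects each truly present value per sample with a
  Bernoulli probability (default 0.9), and plants 17 + 19 group-specific
  microproteins plus a 2³-fold abundance shift on half the 30-microprotein
  shared core — a deliberately strong disease signature with three samples
  per group, mirroring small plasma-EV cohorts.

These generators do **not** simulate chromatography, isotope envelopes,
co-isolation interference, charge-state mixtures, TMT channels or
search-engine score distributions. Passing tests therefore demonstrate the
correctness of the scanning, matching and counting logic under the stated
noise model — not the end-to-end sensitivity of the workflow on real raw
data, which depends on instrument performance and the upstream search
engine.

## Numerical choices and degenerate inputs

* Fragment tolerance 0.02 Da and all QC thresholds are parameters; strict
  vs non-strict inequalities follow the criteria wording ("more than").
* Peak-match ties (equal |Δm/z|) resolve toward higher intensity; remaining
  ties toward the lower peak index (stable sort).
* Empty FASTA files yield empty lists with a warning; malformed headers,
  unbalanced MGF blocks, duplicate matrix columns and schema violations
  raise typed errors rather than coercing.
* The packaged reference list re-validates its invariants (19 rows, unique
  ids, sequence length equal to the printed length) on every load; its
  genomic coordinates are spliced spans stored as printed and never used
  for arithmetic.
* FDR estimation with zero targets is an error; q-values are capped at 1.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
100-transcript oracle comparisons at ≤ 300 nt, 100-peptide spectrum
batches, 20-seed cohort replicates (50 for the null), completing in a few
seconds. Scaling to a full lncRNA catalogue (hundreds of thousands of
transcripts, millions of database entries) is a matter of runtime, not of
algorithm: every operation is linear or near-linear in its input except
substring novelty search, which uses Python's optimized substring scan over
a concatenated proteome and can be swapped for a suffix automaton if
needed.

## Known limitations

* Genome-to-transcript coordinate lifting (splicing) is out of scope; ORF
  coordinates are transcript-relative.
* The novelty check is exact-substring (with I/L collapsing); it does not
  consider SAAVs or semi-tryptic matches.
* Only b/y series are modelled (no a/c/x/z ions, neutral losses or
  immonium ions), matching the acceptance criteria but understating
  explainable intensity in rich HCD spectra — the purity criterion's 50%
  default absorbs this.
* The exact size of a published putative-microprotein database is not
  reproducible, since it depends on the lncRNA catalogue version used.
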