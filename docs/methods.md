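# Methods

`vagitax` implements a rapid taxonomic-profiling workflow for full-length
16S rRNA gene amplicons sequenced on a nanopore device, of the kind used for
same-day vaginal microbiota assessment in a clinical setting. This note
documents the models, parameters, and numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Pipeline model

A sample is a FASTQ file of single-molecule long reads from one of two
amplicon designs: **V1–9** (near full-length 16S, ~1.5–1.6 kb) or **V3–4**
(~0.4–0.5 kb). Processing stages run in a fixed order:

1. **Quality filter.** A read passes at mean quality ≥ `min_q` (default 7).
   Mean quality uses error-probability averaging,
   `Q = −10·log10( mean_i 10^(−q_i/10) )`, the basecaller's pass-read
   convention. By Jensen's inequality this is at most the arithmetic mean of
   the per-base scores, so it is the stricter of the two conventions.
2. **Length window.** Closed intervals per region: V1–9 keeps 1300–1950 bp,
   V3–4 keeps 350–600 bp. The windows are configuration fields; the V3–4
   default follows the stated extraction range of 350–600 bp, although a
   300–650 bp range also appears in the source workflow's prose — the
   discrepancy is surfaced here rather than resolved.
3. **Repeat masking.** Tandem repeats of period 1–10 spanning ≥ 15 bp are
   replaced by N (greedy run detection). This is a deliberate simplification
   of probabilistic repeat maskers: the pipeline needs repeat suppression
   ahead of alignment, not bit-compatibility with any particular tool.
   Reads ≥ 90% N after masking (`mask_discard_fraction = 0.9`) are dropped
   as carrying no taxonomic signal; whether the original workflow dropped or
   only soft-masked such reads is unknown, so the fraction is configurable.
   Rejection precedence is quality → length → mask, making category counts
   deterministic; the counts always partition the input count.
4. **Host screening.** Reads whose best local-alignment score against a host
   (human) panel reaches `min_host_score_frac × match × read_length`
   (default 0.5) are removed. The default passes a true host read at ~15%
   sequencing error while random 16S-vs-host local scores stay far below.
5. **Subsampling.** 3000 reads drawn uniformly without replacement (seeded,
   bit-reproducible) before alignment, so alignment work is not wasted on
   reads that would be discarded afterwards.
6. **Classification.** Per-read best-hit assignment (below).
7. **Reporting.** Composition tables at a chosen rank, an "Others" bin for
   taxa below 1% (strict inequality; the unclassified bin is not a bacterial
   assignment and is never merged), Shannon diversity
   `H = −Σ p_i ln p_i` (natural log, computed on the un-grouped profile by
   default since grouping distorts H), Krona-format text, and a run-statistics
   sidecar (pass/filtered counts, retention %, length summaries).

## Best-hit classification with even tie allocation

Each read is aligned to a reference panel (`ref_id → (sequence, taxon)`)
and assigned to the taxon with the highest alignment score. The rules that
matter:

- **Per-taxon score = max over that taxon's references**, computed *before*
  tie detection. A taxon with many redundant references can therefore never
  absorb tie mass, and strain-level duplicates collapse to their species
  before selection.
- **Ties split evenly.** If k taxa attain the top score exactly, each
  receives weight 1/k; weights per classified read always sum to 1. Integer
  scores tie iff equal; float scores from external mappers use a 1e−9
  tolerance. This is what produces the characteristic short-amplicon
  ambiguity: two species identical over the V3–4 window yield 0.5/0.5
  splits from V3–4 reads while V1–9 reads resolve them.
- **Threshold.** A read is unclassified when the top score falls below
  `min_score_frac × match × read_length` (default 0.4 of the perfect-match
  score) — permissive for ~10–15% nanopore error, strict enough to reject
  random sequence (validated against a random-sequence null in the tests).

Two scoring backends share these rules:

- **Built-in aligner.** Affine-gap Smith–Waterman (numba-compiled, score
  only, both strands; N matches nothing). Scheme defaults
  (match, mismatch, gap_open, gap_extend) = (2, −4, −4, −2); a gap of
  length L costs `gap_open + L·gap_extend`, the long-read-mapper convention.
  A minimizer prescreen (k = 15, window 10, hashes mixed through a 64-bit
  finalizer) ranks references by shared-minimizer count over both read
  strands, aligns up to 20 candidates, prunes candidates below 25% of the
  best candidate's count (chain-filtering in spirit; exact-tie candidates
  have identical sketches and always survive together), and resolves strand
  by the dominant sharing direction. Reads sharing no minimizer with any
  reference are unclassified.
- **External-mapper mode.** Precomputed PAF alignments are consumed
  directly; the score is the `AS:i` tag when present, else the
  residue-match count (PAF column 10). No built-in alignment runs.
  Assignments from the built-in aligner exported as PAF reproduce built-in
  results exactly (tested).

## Diversity and ordination

**Weighted UniFrac** between two fractional profiles over a shared rooted
tree: `raw = Σ_b ℓ_b · |P_A(b) − P_B(b)|` over branches, where `P_X(b)` is
the fraction of sample X descending from branch b. The normalized variant
divides by `Σ_j d_j (p_Aj + p_Bj)` (root-to-leaf depths), bounding the value
to [0, 1]; normalized is the default and the flag is recorded in output
metadata. Computation is delegated to scikit-bio with two adaptations:
fractions are scaled to large integer counts (the backend truncates to
integers; UniFrac is invariant to per-sample scaling, relative error
≤ 5e−10), and validation is done in-package because taxonomy-derived trees
legitimately multifurcate at the root. Profiles must map every taxon to a
tree leaf; reserved Others/unclassified bins are stripped and the remainder
renormalized before cohort analysis. No tree is ever invented silently: an
explicit Newick (fixture-generated or user-supplied) is required.

**PCoA** is classical metric scaling: `B = −½ J D² J`, eigendecomposed;
coordinates are eigenvectors scaled by √eigenvalue, axes ordered by
eigenvalue. Negative eigenvalues (non-Euclidean distortion) are reported in
the spectrum but treated as zero for coordinate scaling and the
explained-proportion denominator — simple, standard, and testable; no
Cailliez correction is applied.

## In-silico PCR

Degenerate primer cores are matched with IUPAC semantics (a degenerate
position never counts as a mismatch when the template base is in the code
set), up to `max_mismatch = 3` mismatches per primer — tolerant of reference
variation while keeping the random-match probability negligible (tested).
The built-in primer sets carry the anchored inner primers of the two-step
amplification design: V1–9 uses 27F/1492R-style cores, V3–4 uses 341F/805R
cores, both behind a shared 22-nt anchor tail; anchor + core reconstructs
the full published primer strings. For each forward site only the
minimal-length pairing with a downstream reverse site is emitted (PCR
favors the shortest product), products never overlap, and anchors are
attached only when requested (whether gel-estimated product sizes include
anchor tails is not stated in the source protocol, so the flag is explicit).

## Synthetic data: what it emulates, what it does not

The fixture generator stands in for a genome-scale reference database and
for deposited sequencing runs, at desk scale.

- **Reference panels.** A ~1550-bp 16S-like scaffold embeds realizations of
  both primer-core pairs at canonical positions (V3–4 spans positions
  340–805, giving a 465-bp amplicon; the V1–9 amplicon is the whole
  scaffold). Genus ancestors mutate the scaffold at disjoint random
  position sets sized `inter_genus_div/2` each, so realized pairwise
  inter-genus divergence equals the target by construction (defaults:
  inter 0.15, intra 0.02 — the scale of 16S divergence between genera and
  between congeneric species). Mutations avoid primer cores so every
  species stays amplifiable — a deliberate unrealism. The taxonomy is
  root → genus → species; tree branch lengths are half the generating
  divergences, so leaf-to-leaf distances equal them.
- **Confusable pair.** Two congeneric species identical over the V3–4
  amplicon span and ≥ 5% divergent (6% of scaffold positions) elsewhere in
  the V1–9 span — the constructed analogue of congeneric species pairs that
  short amplicons cannot separate.
- **Reads.** Per read: source taxon drawn from the abundance vector, the
  species' region amplicon as template, random strand, then per-base
  substitution/insertion/deletion errors (defaults 0.03/0.02/0.03, ~8%
  total — the error regime of recent nanopore chemistry after filtering).
  Emitted qualities are normal around Phred 14 at match positions and
  Phred 8 at error positions (sd 3, clipped to [2, 40]), so mean read
  quality lands near the observed ~12 and error positions are visibly
  lower-quality. Read-length jitter comes only from indels — filtered real
  reads sit close to amplicon length, so a fragmentation model is
  second-order for this purpose. Ground truth (source taxon, error counts)
  is recorded per read; everything is reproducible from one integer seed.

Not modelled: signal-level errors, homopolymer-specific error structure,
chimeras, barcode cross-talk, abundance-dependent extraction bias. Passing
the mock benchmarks therefore shows the *algorithmic* chain (filter → screen
→ align → tie-split → roll-up → report) recovers a known community under a
realistic error budget; it does not certify performance on real specimens
against a genome-scale database.

## Benchmarks the package reproduces at desk scale

- Retention percentages recompute exactly from the bundled published
  per-run pass/filtered read counts (e.g. 91,449/115,957 → 78.9%).
- The median of the 18 published V1–9 lavage filtered-read counts
  (35,462 reads per ~90-min session) predicts 3000 reads in ≈ 8 minutes;
  including the swab runs gives the same answer.
- 3000 simulated reads from a 10-genus mock community, run end-to-end,
  recover all 10 genera above the 1% Others threshold with per-genus error
  under 3 percentage points (typically < 1), in well under the workflow's
  4-hour envelope (~1 minute on one CPU).
- Paired multinomial resamples of the same composition at n = 3000 sit
  closer together in weighted-UniFrac space than samples from different
  compositions — the sampling-method-equivalence behaviour.

Problem sizes in the test suite (hundreds of reads for unit tests, 3000 for
the mock benchmark, 60-mers for alignment-oracle comparisons) were chosen so
the whole suite runs in a few minutes on one CPU while keeping every
statistical check well-powered.

## Known limitations

- The built-in aligner is score-only; per-base alignment paths (and hence
  exact PAF spans for its exported hits) are not tracked.
- The greedy repeat masker is not a probabilistic model and will mask
  borderline 15-bp tandem runs that a likelihood-based masker might keep.
- UniFrac results depend on the supplied tree; a taxonomy-derived cladogram
  with unit branch lengths and a sequence-based phylogeny give different
  distances, and neither choice is claimed to reproduce any particular
  published ordination.
- Nugent categorization operates on externally provided morphotype
  subscores; no microscopy image analysis is attempted.
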