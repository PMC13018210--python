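# Methods

This note records the models implemented in `tlpscan`, the parameter
choices that matter, what the synthetic benchmark does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and translation

All internal coordinates are 0-based half-open; user-facing outputs (GFF3,
motif and residue positions) are 1-based inclusive, matching how residue
numbers are cited in the structural literature (e.g. a superfold spanning
reference residues 673–2139).

Six-frame translation follows the EMBOSS `transeq` convention: frames
+1..+3 translate the forward strand at offsets 0..2; −1..−3 translate the
reverse complement at offsets 0..2; trailing partial codons are dropped.
The genetic code defaults to the Standard table, with the Bacterial table
(11) selectable — the two differ only in start-codon sets, which the screen
does not use. Codons containing `N` translate to `X`, which every model
scores as background (zero bits), so ambiguity can neither create nor
destroy a hit on its own.

Full-frame translations are split at stop codons into segments of at least
`min_segment_len` (default 30 aa, below the shortest domain worth scoring).
This is a deliberate strengthening of "same reading frame": two domains
separated by an in-frame stop cannot share a segment and therefore cannot
co-assemble, which is exactly the single-ORF requirement the architecture
filter encodes. In i.i.d. background at GC 0.5 the mean stop-free run is
~20 aa, so segment splitting also discards most background residues before
any scoring happens.

## Profile HMMs

Each domain model is estimated from its reference-split sub-alignment:

- **Match columns**: gap fraction < 0.5 (`match_gap_frac`).
- **Match emissions**: `(c + A·b) / (C + A)` with counts `c`, column total
  `C`, background `b`, pseudocount weight `A = 5`. Background defaults to
  uniform 1/20; insert emissions equal the background (no insert-specific
  estimation — at fixture scale there is too little signal to estimate
  them, and it makes insert residues score exactly zero bits).
- **Transitions**: counted from each row's implied match/insert/delete path
  and smoothed with the same weight `A` distributed over targets as
  (0.90, 0.05, 0.05) for M→(M,I,D) and (0.5, 0.5) for I and D. The
  informative M→M prior matters: an uninformative (uniform) prior imputes
  ~13% indel probability per state from small alignments, which both
  degrades alignment scores and — because the benchmark generator samples
  cassette domains from these same models — produces unrealistically
  indel-riddled planted domains. 0.90/0.05/0.05 keeps implied indel rates
  at the few-percent level typical of curated domain families.

Scoring is local: a path enters at any match state (uniform 1/M weight),
exits from any match state at no cost, and flanking/insert residues are
emitted by the background so their odds cancel. `score_viterbi` returns the
best path with its peptide envelope and model span (used for coverage and
adjacency); `score_forward` returns the log2 of the summed odds. Both are
verified against exhaustive path enumeration on all small instances
(M ≤ 3, peptide ≤ 4) to 1e-9 bits. The kernels are numba-compiled; the
scanning loop uses a score-only Viterbi pass and recomputes envelopes only
for segments that pass the E-value screen. There is no multi-hit J state
and no composition filter (Plan7 parity is a non-goal); tandem copies in
one segment are found by masking each accepted envelope and rescoring.

## E-values

HMMER calibrates its E-values internally; this package replaces that with
an explicit, reproducible procedure stored on the model: draw `n_cal = 200`
i.i.d. background peptides of length `len_cal = 400` from the model's
background distribution (fixed seed, recorded in the model file), score
them with Viterbi, and fit a Gumbel location/scale by maximum likelihood
(`scipy.stats.gumbel_r.fit`). Then

    E(S) = n_targets · (1 − exp(−exp(−λ(S − μ)))),

with `n_targets` the number of peptide segments scanned in the run — the
database-size correction appropriate to a per-segment search. A held-out
test (fresh background, 1% tail quantile, 99% binomial interval) guards the
fit. Calibration at a single length is a simplification: true background
segments are mostly shorter than 400 aa, so their null scores run lower and
the resulting E-values are conservative for them; segments much longer than
400 aa (vanishingly rare in stop-punctuated background) would be
anti-conservative. At the screen's operating point (E ≤ 1e-10, roughly
35–45 bits above μ) this slack is irrelevant to the planted-truth
benchmarks, where true-domain scores run hundreds of bits above background.

## Architecture filter

Hits are shortlisted at `E ≤ 1e-10` and model coverage ≥ 0.30 — coverage is
measured on the model side (fraction of match states spanned), the reading
of "domain overlap" closest to hmmscan's domain reports; a target-side
variant would only be weaker for partial decoys. Within one (genome, frame,
segment), candidate triples must follow FN-plug → NHL → YD-shell in N→C
order with inter-envelope gaps ≤ `max_gap = 300` aa and pairwise envelope
overlap ≤ 50% of the shorter envelope. The 300-aa default reflects that the
superfold is contiguous in the reference (673–2139), so genuine
inter-domain linkers are short; the bound is configurable and surfaced in
the CLI. Overlapping candidates are resolved greedily by summed bit score,
ties by leftmost genomic start; loci are numbered per genome by genomic
start. Each FASTA record is screened independently; loci never span
records.

Downstream neighbours (candidate immunity genes) are naive ORFs: ATG
through stop, same strand, 5′→3′ of the locus, start within 5000 nt,
length ≥ 150 nt, sorted by proximity. No ribosome-binding or operon model
is attempted.

## Synthetic benchmark

The generator emulates the statistical structure the screen assumes, not
real genomes: i.i.d. background DNA at configurable GC; cassettes built as
[FN-plug] + linker + [NHL] + linker + [YD-shell], with domain peptides
sampled from the scanning models themselves, linkers uniform 5–30 aa,
reverse-translated (uniform or GC-biased codons, never a stop), and
overwritten into the background on a random strand at non-overlapping
positions. Decoys cover exactly the three failure modes the architecture
rule must reject: shuffled domain order, domains split across strands, and
partial cassettes. Immunity-like ORFs (ATG + 60–150 random codons + stop)
are planted 50–400 nt downstream of cassettes on the same strand. Every
element is recorded in a truth table; a cassette counts as recovered when a
same-genome, same-strand locus overlaps it with Jaccard ≥ 0.8 (local
alignment trims a few residues at domain edges, so demanding exact spans
would measure envelope cosmetics, not detection).

The fixed benchmark is 20 genomes × 200 kb, 30 cassettes, 10 + 10 + 10
decoys, seed 1337, screened with the full-size three-model library built
from the 2139-residue synthetic superfold alignment (8 rows, 25%
substitution, 2% deletion — similar enough for sharp models, divergent
enough that emissions are not trivial one-hot columns). A rate-driven mode
(`positive_rates`) plants one cassette per genome with a per-taxon
probability instead, for prevalence-calibration experiments.

What passing these benchmarks does **not** show: performance on real
genomes with repeats, skewed composition, real codon usage, genuine
homologous families (rather than samples from the scanning model), or
distant homologs near the detection limit. The benchmark measures the
correctness of the machinery — coordinate maps, thresholds, the
architecture rule, determinism — under conditions where truth is knowable.

## RHS motif and CTD conventions

- Simple motif `P-x4-D-P-x-G`; bipartite `D-P-x-[GLR] - X18 - D-P-x-G`
  (first-tetrad glycine may be leucine or arginine; the observed residue is
  recorded). Overlapping matches are all reported. The spacer defaults to
  18 — the D-to-D distance is then 22, which is what the X18 grammar
  implies even though such motifs are sometimes loosely described as
  "twenty residues apart"; the spacer is configurable.
- Cleavage convention: `ctd_start = d2 + 5`, i.e. the bond after the second
  tetrad's glycine. This is the unique offset consistent with a second
  catalytic aspartate at residue 2140 and a CTD beginning at residue 2145,
  and it is the quantity `scripts/acceptance.py` recomputes.
- Hydropathy: Kyte–Doolittle, centered window 19, NaN where the window
  overhangs. TM segments: runs of window centres above 1.6, merged across
  gaps ≤ 3, reported at length ≥ 15. These are hydropathy predictions, not
  a trained TM topology model, and are labelled accordingly.
- Mass: Biopython average residue masses minus one water per peptide bond,
  in kDa. Catalytic/disulfide annotations (e.g. partner cysteines) are
  carried as metadata only; no structural computation is attempted.

## Membrane statistic

Patches are squares of side `patch_size` in x–y, anchored at the data
minimum (which makes D exactly translation-invariant). Each occupied
patch's normal is the smallest principal direction of the centred point
cloud (total least squares), oriented to +z; D is the mean of |n̂·ẑ| over
fitted patches. Patches with fewer than 3 points or rank-deficient
covariance are skipped and counted in a QC field rather than imputed. D is
exactly 1 for flat sheets at any patching; for curved surfaces it converges
as patches refine relative to the surface wavelength. Because square tiling
is not rotation-covariant, D on curved surfaces is only approximately
invariant under z-rotation (exactly invariant for uniform-slope planes);
patch size is an exposed parameter, as any fixed choice trades noise
against curvature resolution. Distances use the minimum-image convention in
x and y when box extents are given; z is never wrapped. Input is a simple
CSV (frame, role, x, y, z [, box_x, box_y]) — parsing MD trajectory formats
is out of scope; users export coordinates upstream.

## Determinism

Every stochastic step (calibration, emission sampling, reverse
translation, background synthesis, placement) flows from explicit seeds;
model files embed their calibration seed; identical configurations produce
byte-identical FASTA, truth tables, hit tables, GFF3 and model files, and
the test suite asserts this at the byte level.

## Problem sizes

Defaults were chosen so a complete run is comfortable on one CPU: the
benchmark screen (two dozen Mb of six-frame translation against 1467 match
states across three models) completes in about a minute, and unit tests use
a scaled-down three-domain library (60/80/100 match states) with the same
construction path.
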