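# Methods

## Coordinate frame and the nick convention

All internal coordinates are 0-based, half-open, on the plus strand of the
supplied reference window; tables use the 1-based MAF-like dialect, and
anchor-base indel rows are left-aligned on parse (shared prefix stripped
with the position advanced, then shared suffix stripped). An insertion at
0-based `pos` places its bases immediately before `sequence[pos]`.

SpCas9 nicks the PAM strand 3 nt 5′ of the NGG PAM, i.e. between
protospacer positions 17 and 18. We call the first nucleotide 3′ of the
nick **+1**; the PAM occupies +4 (N), +5 and +6 (GG). "Distance to nick"
is the + position of the first edited base. An edit is *protospacer
disrupting* when it changes any of +1..+3 and *PAM disrupting* when it
changes the observed bases at +5/+6 (insertions and deletions upstream of
the PAM shift the downstream sequence and therefore count). An SNV at +4
never disrupts the PAM, because any base satisfies the N.

## pegRNA construction

For each variant we enumerate every NGG protospacer on both strands whose
nick leaves the whole edit at ≥ +1 and coverable by an RTT of at most 30 nt
with at least 1 nt of post-edit homology (a hard minimum we impose; the
ranking separately rewards longer homology). For each protospacer the
design grid is RTT ∈ {10, 15, 20, 25, 30} × PBS ∈ {10, 13, 15} nt. The RTT
is the reverse complement of the first `rtt_len` bases of the *edited* PAM
strand read 3′ from the nick; the PBS is the reverse complement of the
`pbs_len` reference bases 5′ of the nick; the 3′ extension is RTT then PBS,
5′→3′. A leading G is prepended to the 20-nt protospacer for U6
transcription (configurable). Consequently, for an SNV

    rtt_len = (dist_to_nick − 1) + |alt| + post_edit_homology.

Candidates from all of a variant's protospacers are pooled, filtered,
scored and truncated to 30 per variant (ties broken by smaller distance to
nick, larger homology, then lexicographic spacer — fully deterministic).

### Filters

- **POLYT** — ≥ 4 consecutive T in the transcribed cassette
  (spacer oligo + scaffold + extension). The shipped scaffold is the
  polyT-free "flip + extension" variant for exactly this reason.
- **ECORI / ESP3I** — GAATTC / CGTCTC on either strand of the variable
  region (spacer through sensor); these enzymes cut the cloning adapters
  and must not cut inside.
- **SPECIFICITY** — MIT aggregate score < 50, when a surrogate reference
  FASTA is supplied. Scoring enumerates every NGG site with ≤ 4 mismatches
  and applies the Hsu position weights; the mismatch-distance term uses the
  mean pairwise distance over all mismatch pairs, with distance and
  multiplicity terms equal to 1 for single-mismatch sites. Without a
  reference the filter is off and protospacers remain unscored.

### Composite score

The score is a linear combination over {on-target score (0–1, ×100; 0 when
absent), −distance to nick, post-edit homology capped at 10 nt, PAM
disruption, protospacer disruption, PBS GC ∈ [0.30, 0.60], extension not
starting with C}. Default weights (0.5, −1.0/nt, 0.5/nt, +5, +2, +2, +2)
encode the directionality of each term — edits closer to the nick, with
more homology, disrupting PAM/seed, and with a moderate-GC PBS score
higher — but the magnitudes are explicit tuning parameters; nothing
downstream depends on their exact values, only on the documented
monotonicities. Rule-Set-2-style on-target scores are consumed from an
input column or a pluggable scorer, never recomputed.

## Sensor frame

The sensor is the endogenous PAM-strand window [nick − 24, nick + 36),
reverse-complemented for storage (reverse orientation relative to the
cassette reduces lentiviral template-switch recombination between spacer
and sensor). The split guarantees the full protospacer plus ≥ 5 nt of
flank on one side and the longest RTT (30 nt) plus ≥ 5 nt on the other,
and — with the +1 eligibility rule — that no edit can ever reach the first
or last 5 stored nucleotides, which serve as recombination-detection
barcodes and are excluded from the quantification window. Designs whose
frame leaves the reference window are dropped with a reason. For deletions
the downstream context extends further into the reference so the stored
wild-type sensor is always exactly 60 nt; the edited reference is the same
frame with the variant applied (60 − del + ins nt).

Designs of one variant sharing a protospacer legitimately share an
identical sensor; that is not a collision. A *collision* is one barcode
pair mapping to different sensor references (possible for nearby
variants): those designs are flagged in the manifest and their sensors are
excluded from editing accounting (outcome `AMBIGUOUS_BARCODE`), while
recombination detection needs only barcode-pair membership and keeps
working. Two variants with identical (pos, ref, alt) would produce
indistinguishable cassettes; `dedupe_variants` removes them up front and
`export_library` treats a duplicate cassette as fatal.

## Silent controls

Synonymous single-nucleotide controls tile the CDS: eligible codons (those
admitting a synonymous single-nt change) are spread argmax-evenly, and
within a codon we prefer third-position transitions, breaking ties
alphabetically by alt allele. The procedure is fully deterministic; each
control is verified by direct translation in the test suite. These
controls are the screen's neutral null and later feed the empirical FDR.

## Deconvolution

The sequencing layout yields the protospacer, 3′ extension and sensor of
each cluster as separate reads (three parallel FASTQ files per sample).
Clusters with mean Phred < 30 across the declared regions are dropped and
counted. Assignment is exact: spacer and extension must both match the
same design; both matching different designs is a (lentiviral)
recombination event; either absent is unmatched. A unique-one-mismatch
rescue exists but is off by default. Every input read lands in exactly one
terminal category, so `total = assigned + recombined + unmatched +
low_quality` holds by construction and is asserted in the tests.

Sensor classification checks barcodes first (own pair → classify; another
design's pair → sensor-level recombination, discarded; unknown pair →
retained as a candidate indel), then compares the quantification window
(read minus 5-nt flanks) with the edited and wild-type windows: exact
matches are CORRECT/UNEDITED; a length differing from both references is
an INDEL; at matching length, a read is an INDEL only when the optimal
edlib alignment is strictly cheaper than the substitution-only (Hamming)
alignment, otherwise OTHER. This makes the treatment of substitution-only
non-WT, non-edited windows explicit and deterministic.

Per design and sample we report outcome fractions, flag designs under 100
sensor reads (efficiency reporting) and under 10 (calibration), and
subtract the plasmid-library correct percentage floored at zero.

## Screen statistics

Counts are normalized by median-of-ratios size factors (computed over
designs positive in all samples, scaled to geometric mean 1; total-count
fallback with a warning). Per design,
`lfc = log2(median(norm treated) + 1) − log2(median(norm control) + 1)`;
designs with a normalized control mean below 10 reads carry no LFC but are
retained and flagged. Z-scores standardize LFCs over the considered subset
with the population (n) standard deviation — at library scale the n vs
n−1 distinction is negligible. Significance uses a two-sided empirical
null from the silent controls, `p = (1 + #{silent: |lfc_s| ≥ |lfc_i|}) /
(1 + n_silent)`, Benjamini–Hochberg adjusted across considered designs; at
least 20 silent controls must be in the considered set or the call is
refused. Sensor calibration restricts the considered subset to designs
with a background-subtracted correct percentage at or above the threshold
(default 10%) and at least 10 sensor reads, recomputing Z and FDR on that
subset; the sweep mode tabulates considered and significant counts per
threshold over {0, 2, 5, 10, 15, 20, 30, 50}% by default. Variant-level
results take each variant's most efficient calibrated design (ties: more
sensor reads, then design rank); a mean-aggregation mode is deliberately
not the default. Feature–activity correlations use Spearman (average
ranks on ties) with pairs under 3 observations reported missing, and ΔZ
subtracts an external per-variant Z-score table (e.g. from a cDNA
overexpression screen), flagging rather than dropping unmatched variants.

## Simulator

The generator emulates the pooled screen: a control timepoint and
untreated/treated arms with three replicates. Each design draws an
asymptotic sensor-editing rate from Beta(0.35, 1.3) — right-skewed like
real pegRNA libraries (mean ≈ 21%, ~29% of designs under 2%), with enough
mass above 50% that the highest calibration bin still contains the ≥ 20
silent controls the empirical FDR requires at desk scale (a few hundred
designs). Editing accrues toward the rate as `e(t) = rate·(1 −
exp(−0.35·t))` passages, reflecting constitutive editor expression. Each
non-silent variant is null with probability 0.5 and otherwise carries a
Normal(0, 0.3) log2-per-passage fitness effect; silent controls are always
0. Crucially, fitness acts only on the *edited* subpopulation:
`abundance ∝ (1 − e) + e·2^(effect·selection·t)` with selection 1 in the
treated arm, 0.3 untreated, 0 at the control timepoint — this mechanism is
what makes sensor calibration informative, and it is the property the
monotonicity tests probe. Counts are multinomial over lognormal(σ = 0.3)
baseline abundances at a configurable expected depth per design; sensor
outcomes are multinomial with a configurable indel rate; pegRNA-level
recombination, sensor-barcode swaps, low-quality (Q25) and unmatched reads
are injected at configurable rates on top of the assigned counts. FASTQs
are written deterministically from the seed, alongside truth tables that
join pipeline outputs 1:1 on design id.

What the simulator does **not** model: position-dependent sequencing error,
PCR jackpotting, chimeric PCR artifacts, uneven lentiviral integration
beyond the lognormal baseline, and cell-to-cell editing-time variation
(editing is a per-design fraction, not a per-cell history). Passing tests
therefore demonstrate the correctness of the bookkeeping and statistics
under a faithful mechanism, not performance on any particular real screen.

## Problem sizes and numerical choices

The default test/acceptance conditions use a 2,400-nt all-CDS toy gene,
100 patient-style variants plus 95 silent controls, 3 designs per variant
(≈ 560 designs), depth 300 per design with 3 + 3 replicates for the
statistics, depth 500 × 500 designs for the conservation check and depth
1,000 × 150 designs for rate recovery; thresholds sweep {0, 2, 10, 20,
50}%. Calibration monotonicity and null FDR control are evaluated as means
over 10 simulated screens: per-screen FDR<0.05 counts can move by a design
or two at adjacent thresholds because Benjamini–Hochberg is discrete and
removing considered designs also shrinks its correction. The exact
99% binomial interval used for rate recovery has ~99.2–99.6% coverage, so
the ≥ 99%-of-designs bound is intentionally tight and evaluated at a fixed
simulation seed.

## Known limitations

- Only canonical NGG protospacers; no PE3/PE4 nicking guides, no
  mismatch-repair-evasive co-edits, no machine-learning efficiency model
  (features are exported for external model training instead).
- On-target (Rule Set 2) scores are consumed, not computed; without them
  the composite score's on-target term is 0 for every design.
- The MIT specificity search is brute force and meant for desk-scale
  surrogate references, not whole genomes.
- Equal-length coding DELINS is classified missense even though a
  synonymous multi-nucleotide replacement is theoretically possible.
- The empirical FDR is conservative at small silent-control counts
  (discrete null); it will not numerically match negative-binomial
  pipelines run on the same counts, though the ranking largely agrees.
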