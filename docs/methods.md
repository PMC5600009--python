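# Methods

## The problem

Ligation-based library preparation for nanopore sequencing can join two
unrelated molecules into one physical read (a *chimera*), and a pore that
reloads a second molecule quickly enough can make the base-caller merge two
physical reads into one record (an *in-silico* chimera).  In a barcoded
amplicon experiment — here, three murine amplicons (an Ifna family
consensus, Ifnb1, Actb) each carrying a batch-specific native barcode on
both ends, adapter-ligated in two batches (overnight at 4 °C vs quick
10-minute) — the barcode design turns chimera detection into a
combinatorial test on each read's annotation: which amplicons, which
barcodes, in which orientations.

`ampchimera` implements the full procedure as a reusable pipeline: a panel
aligner, a chimera classifier, a raw-signal segmenter that separates true
ligation chimeras from in-silico joins, a reporting layer, and a synthetic
library/signal generator so that every stage is testable without access to
a sequencing run.

## Read annotation (align)

Each read is scanned against every panel entry on both strands with an
affine-gap local aligner (Smith–Waterman with Gotoh's three-state
recurrence; a gap of length L costs `gap_open + L*gap_extend`).  Repeated
occurrences of the same target are found by iterative masking: after each
accepted hit the covered read interval is masked and the target re-aligned
until the score drops below threshold.  Long targets (≥ 100 bp) are
pre-screened with a shared 11-mer count (≥ 2 required) so a read is only
fully aligned against targets it plausibly contains; at the default 5/3/3%
sub/ins/del error rates a true amplicon hit retains hundreds of intact
11-mers, so the screen's miss probability is negligible, while unrelated
read/target pairs share an expected ≈ 0.1 seeds.

Hits are accepted per panel kind using three thresholds (defaults: score ≥
12 for 24-nt barcodes, ≥ 50 for amplicons; identity ≥ 0.70 everywhere —
chosen so a divergent Ifna family member still maps to the consensus, as
the human family spans 70–80% identity; and target coverage ≥ 0.70 for
barcodes).  The coverage threshold exists because a score-12 local hit of a
24-mer against ~600 bp of unrelated sequence is, analytically and
empirically, common enough (order 10⁻² per read) to corrupt classification,
while genuine error-eroded barcode ligations still cover nearly the full
barcode.  All coordinates are 0-based, half-open, on the forward strand of
the read; reverse-strand hits mirror their target interval instead.

Fragmented alignments of one physical element are merged when they hit the
same target in the same orientation, sit within `max_gap` (default 50,
smaller than any barcode+adapter spacer) on the read, and advance
consistently along the target; a second full copy of an amplicon restarts
the target and is therefore never merged — that separation is exactly what
makes a repeated-amplicon chimera callable.  Merging iterates single passes
to a fixpoint, which makes it idempotent.

After merging, two structural filters reflect the fact that one read
position holds one physical element: a short-element hit (barcode/adapter)
lying strictly inside an amplicon alignment (≥ 10 bp from either end) is a
chance similarity of the amplicon interior and is dropped, and when two
short-element hits overlap by ≥ 50% of the shorter one, only the
best-scoring hit survives.  Without these, spurious barcode lookalikes
produce false multi-barcode calls at roughly the same order of magnitude as
the true chimera rate; with them, the measured false-positive rate on
simulated clean libraries is zero at n = 4 × 10³ and detection
precision/recall on the default conditions are both ≈ 99%.

Precomputed alignments can be supplied in MAF; minus-strand read
coordinates are forward-oriented with `srcSize − start − size`.

## Classification (classify)

Four flags, not mutually exclusive, are computed from the merged matches:

1. **repeated_amplicon** — ≥ 2 amplicon matches with the same gene identity
   and the same orientation ("identical amplicons" means identical gene id:
   all Ifna family members collapse to Ifna);
2. **multi_amplicon** — ≥ 2 distinct gene identities;
3. **multi_barcode** — ≥ 2 distinct barcode targets;
4. **disagreement** — some barcode's assigned gene differs from some
   amplicon gene on the read, or two barcodes' assigned genes differ.

A read with any flag is *definitively chimeric*.  The one deliberate
exclusion: exactly two same-gene matches in opposite orientations — with or
without an intervening hairpin match — set no flag, because that pattern is
indistinguishable at the base level from a 2D read (template, hairpin,
complement).  The exclusion needs no special case in the implementation:
rule 1 demands a shared orientation, so the two-opposite pattern never
fires it, while three or more same-gene matches flag whenever any two share
a direction.  Hairpin, leader and control matches never contribute flags;
they are structural evidence only.

Non-chimeric reads receive exactly one class: `amplicon_and_barcode`,
`barcode_only` (barcode hit but no amplicon — unamplified cDNA),
`sequence_only` (amplicon but no detectable barcode), or `unmapped`.

Reads whose barcode batches span both ligation preparations
(`mixed_batch_reads`) are the candidates for in-silico chimerism: two
molecules from different preparations cannot have been ligated together,
so a mixed signature implies either cross-ligation of barcodes or a pore
reload, and only the raw signal can tell them apart.

## Raw-signal model and segmentation (signal)

A trace is a walk through four states: *open_pore* (high, uniform current
of an empty pore), *stall* (intermediate, uniform), *sequence* (variable,
one level per base held for `samples_per_base` samples), and *hairpin* (a
distinctive three-level bridge a little over halfway through a 2D trace,
modelling the upgraded chemistry's three-peak hairpin signal).  Defaults:
open pore 220 ± 5 pA, stall 110 ± 5 pA, sequence band 50–130 pA, hairpin
160/70/160 pA, 4 kHz sampling, 14 samples/base, leading open pore 2 s,
stall 0.3 s.  The published traces print durations (e.g. 7 s open pore,
0.3 s stall, 2.5 s + 2 s of sequence for a 2D molecule) but no current
values; the levels are typical R9.4 magnitudes and fully configurable.
An in-silico join inserts a very short open-pore blip (default 0.08 s)
plus a fresh 0.1 s stall between the two molecules.

Per-base sequence levels are a hash of the base's 3-mer context mapped into
the sequence band *excluding a guard zone of ± 14 pA around the stall
level*.  This is a deliberate simplification: it makes states
level-identifiable so that the segmenter's per-sample thresholds (open-pore
threshold midway between open-pore and sequence-max; stall band ± 12 pA;
hairpin band above sequence-max) are exact at zero noise and correct to a
few samples at default noise, with isolated noise excursions absorbed by
per-label minimum durations (open_pore 20 samples — short enough to keep
the reload blip detectable — stall 100, sequence 200, hairpin 30).  Real
R9.4 sequence signal does overlap the stall band, so passing round-trip
tests here demonstrates the segmentation logic, not performance on real
traces; on real data the stall/sequence boundary would need a
variance-based statistic rather than a level threshold.

`flag_reload` marks any open-pore segment occurring after the first
sequence (or hairpin) segment; leading open-pore/stall segments are the
pore waiting for, then holding, a molecule and are never flagged.  On
simulated mixed libraries at zero noise, reload flags recover every
in-silico join and no clean read; combined with the mixed-batch base-call
signature this separates in-silico chimeras from physical cross-ligation.

Traces are stored one dataset per read in an HDF5 container with
`sample_rate`/`read_id` attributes; an adapter also accepts the raw-signal
dataset layout of FAST5 files.

## Synthetic libraries (synth)

The generator emulates the study's library: three amplicons whose termini
are the published primers (degenerate bases resolved R→A, Y→C for
determinism) and whose lengths are 535 (Ifna), 600 (Ifnb1) and 524 (Actb)
bp with seeded-random interiors; six seeded-random 24-nt barcodes with
pairwise edit distance ≥ 8 (the actual kit sequences are not public); a
hairpin, leader and control strand.  The default barcode↔(gene, batch) map
is arbitrary but fixed and user-overridable.

Default conditions mirror the observed run where printed: 77.8% overnight
ligation, amplicon mix 42.7/23.7/33.6% (Ifna/Ifnb1/Actb), 40.8% 2D
molecules, 5/3/3% sub/ins/del error rates, chimera rate 2%.  Chimeras are
formed *after* barcoding — whole barcode-flanked constructs are
concatenated — matching the inference that concatenation of two barcoded
amplicons places the event at adapter ligation.  The four mechanisms are
mixed 55/20/15/10% (repeat / multi-amplicon / multi-barcode /
disagreement), echoing the dominance of repeated amplicons in the observed
category table.  The in-silico join rate defaults to 0.1%: the observed
rate (8 reads in ~2.6 × 10⁵) is too small to exercise at desk scale, so the
default is the smallest rate that still yields joins in a 10⁴-read library.
Each read is emitted on a uniformly random strand and corrupted with an iid
substitution/insertion/deletion model; ground truth records the construct
grammar, each segment's interval on the pre-corruption read, and in-silico
junction positions.

What the generator does **not** model: PCR-stage template switching (the
observed joins are post-amplification), quality-score realism (flat
qualities), homopolymer-biased errors, read truncation, or carrier DNA.
Recovery results on simulations therefore bound the procedure's behaviour
under its own assumptions, not its performance on arbitrary real runs.

## Reporting (report)

Definitive calls are grouped by signature — per-gene amplicon counts ×
batches seen × disagreement — into a count-descending table; signatures
seen fewer than `min_count` (default 5) times are suppressed from display
but retained in totals.  Headline rates are computed as exact rationals and
rounded half-up at one decimal place (the repeated-amplicon share of
definitive chimeras is conventionally a whole percent); this convention
reproduces every published percentage from its published count pair
(1.7, 75, 1.8, 2.6, 5.5, 0.3, 87.6, 99.7).  `evaluate` scores calls against
a truth table: truth-positives are the four ligation mechanisms plus
in-silico joins; clean 2D constructs count as negatives (their exclusion is
by design, not a miss), and the recovered chimera rate is compared with the
95% binomial interval of the truth fraction (scipy's exact interval).

## Numerical and design notes

* Alignment scoring defaults (+1/−1, gap open 2, extend 1) are declared,
  configurable choices; the original analysis used an external aligner
  whose parameters were not reported.
* Identical-interval duplicate hits keep the highest score, ties broken
  lexicographically by target name; all other cross-kind overlaps are
  retained (classification needs barcodes adjacent to the amplicons they
  disagree with).
* Degenerate inputs: empty sequences are rejected by the aligner; an
  all-mismatch pair scores at most one forced-match column (the empty
  alignment scores 0); zero-denominator rates raise with the rate's name;
  an empty library yields an empty table and no plot.
* Determinism: one config seed feeds per-stage generators by fixed
  offsets, so a stage rerun alone reproduces its outputs; fixed-seed runs
  are byte-identical including FASTQ output.
* Problem sizes in the test-suite and acceptance script (10⁴-read
  libraries, 10³ 2D constructs, 200 traces) were chosen as the smallest
  sizes at which the binomial checks have useful power.

## Known limitations

* The segmentation thresholds are tuned to the generator's
  level-identifiable model (see above), and hairpin detection relies on the
  bridge exceeding the sequence band.
* Whether the observed "disagreement" accounting also covers barcode-pair
  gene conflicts on amplicon-free reads is not specified in the source
  material; here two disagreeing barcodes flag with or without an amplicon
  present.
* The pipeline does not attempt to decide whether a repeated-amplicon
  chimera arose in ligation versus a transcribed gene cassette, and no
  statistical test is made of the overnight-vs-quick rate difference.
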