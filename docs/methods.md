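# Methods

## Model

A lysogen is a host chromosome with one or more integrated prophages. Each
prophage is described by its length `L`, its insertion coordinate `attB` in
the prophage-free host, an orientation, and packaging parameters. The att
core (default `ATCACCATGCAGTT`, 14 bp) is present once at attB and, after
integration, duplicated at attL and attR; excision fuses the junctions back
to a single attB copy, so excise→insert is an exact round trip. All
coordinates are 0-based, half-open.

Induced virions package DNA in one of two ways:

* **Excised-circle packaging** — one molecule covering exactly the prophage
  placement `[attL, attR)`. This is the default for every prophage and the
  only mode for non-*pac* phages.
* **In-situ headful packaging** (lateral transduction) — with probability
  `in_situ_prob` a packaging event of a *pac*-type prophage starts at the
  *pac* site, located `pac_offset` bp inside the prophage measured from the
  chromosome-proximal end on the side packaging exits (`orientation '-'` =
  attL/left side, `'+'` = attR/right). Headful k covers the k-th
  consecutive window of exactly `L` bp from the *pac* position outward, so
  headful 1 carries `L − pac_offset` bp of chromosome and every further
  headful is pure chromosome. The series continues past headful k with
  probability `continuation_prob` (geometric decay), capped at
  `max_headfuls`. Geometric decay is the minimal one-parameter model for the
  observed decreasing step heights, and it is the quantity the detector's
  decay-ratio output is validated against. Series running past the end of a
  linear reference are truncated and flagged; on circular references
  coordinates wrap.

Host DNA contamination is modelled as uniform random fragments (default
5,000 bp) of the lysogen. `host_contamination_frac` is a per-event
(molecule-level) probability; because host fragments are much shorter than
phage molecules, configs may instead give `host_read_share`, the target
share of *reads*, which is converted exactly via
`synthetic.host_fraction_for_read_share`. The two definitions of "percent
host" (share of molecules vs share of reads) therefore both remain
computable.

Reads (uniform length, default 100 bp) are sampled from molecules
proportionally to their number of valid start positions, with uniform start
and strand and i.i.d. substitution errors (default 0.001); qualities are a
constant 'I' and there are no indels — the error model is irrelevant to
coverage-level inference. Read names and a truth TSV carry the source,
molecule, headful index and origin of every read.

## Read mapping

The mapper is exact seed-and-extend: disjoint k-mer seeds (k = 21, one per
permitted mismatch plus one, pigeonhole-complete for reads ≥ (m+1)·k) over a
sorted-array index of the forward strand, followed by full-length
verification counting substitutions (`max_mismatch` = 2). The best placement
minimises mismatches; ties go to the lowest coordinate, then to the forward
strand, so mapping is deterministic without a seed. Reads containing N are
reported unmapped separately. Coverage is accumulated per base;
equal-depth runs (including zeros, so tracks round-trip exactly) are written
as 0-based half-open bedGraph, and a minimal single-segment SAM dialect is
emitted for interoperability. Externally produced SAM/BAM or bedGraph can
replace the built-in mapper as the coverage source.

## Induction quantification

Each mapped read is assigned to the prophage interval containing its
alignment midpoint (midpoint assignment avoids double counting at the att
junctions), otherwise to "host". Fractions over mapped reads sum to 1 over
{prophages} ∪ {host}; fractions over all reads are reported alongside, since
published "percent of total reads" figures may use either denominator. Note
that location-based assignment credits a prophage with any host-fragment
reads overlapping its interval; the effect scales with the
prophage-to-genome length ratio (<0.1% at realistic ratios).

Background depth is the per-base median over host positions at least 10 kb
(configurable) from any prophage interval. A prophage is **activated** when
its mean depth exceeds `fold_threshold` (default 5) times background; with
zero background (sparse data), nonzero prophage depth counts as activated,
and this convention is logged.

## Staircase fit and lateral-transduction detection

On the prophage-free reference, the flank (window `flank_bp`, clipped per
side to what is available) with the larger read mass within equal-width
comparison windows is selected; `asymmetry` is the larger/smaller mass
ratio. The chosen flank, oriented away from attB, is segmented by greedy
binary segmentation of `log2(depth+1)` (variance stabilisation for
Poisson-like depth) with a minimum segment of 5 kb and an SSE-reduction
stopping rule: a split is accepted while it removes more than
`penalty_frac` (default 2%) of the total initial SSE. On noise-free
piecewise-constant tracks this recovers breakpoints exactly (verified
against an exact dynamic-programming segmentation oracle).

Segments are trimmed to the maximal prefix that is strictly decreasing in
mean depth and above `background × 1.5`. The default background here is the
**maximum of two binned-median estimates** (median of 1-kb bin means):
outside the flanks, and over the opposite flank, which carries only
dispersed background once the side is chosen. A per-base median was
rejected because at the depth of a desk-scale run (<1× dispersed
background) it is 0 for any track with >50% empty positions, which lets a
trailing background segment masquerade as a final step and corrupt the
period estimate; bin means keep the estimator robust to peaks elsewhere
while remaining meaningful at sparse depth. An explicit background (e.g.
the induction estimate from a deep run) can be supplied via
`StaircaseParams.background`.

Outputs: step widths/heights, `n_steps`, `first_step_bp` (width of step 1),
`period_bp` (median width of steps 2..n — the median is robust to last-step
truncation at low depth), `decay_ratios` (successive height ratios, each an
estimate of the continuation probability), `pac_offset_bp = period_bp −
first_step_bp`, the flank `asymmetry`, the opposite-flank mass fraction,
and a score `R² × asymmetry/(1+asymmetry)` combining fit quality and
one-sidedness. By construction `period − first_step = pac_offset` and the
simulator truth satisfies `first_step = L − pac_offset`, so the estimator is
consistency-checkable against the truth JSON. If no step clears the
background floor the result is `side = "none"` ("no lateral transduction
detected"), not an exception.

The detector calls lateral transduction when `n_steps ≥ 2` and
`asymmetry ≥ 3` (both configurable). The *pac*-proximity motif scan reports
all exact occurrences of a motif (default `GCTAAA`, the terminase-end motif
associated with *pac* sites) on both strands within a window around the
inferred *pac* position, ranked by distance.

## In-silico MLVA

A VNTR locus is defined by two flanks (≥18 bp, each required to occur
exactly once per strand — the in-silico stand-in for PCR primer
specificity; sizing, not sequence chemistry, is modelled), the repeat unit
length, the non-repeat offset inside the amplicon, and a plausible maximum
repeat count. The allele is the rounded repeat count
`(amplicon − offset)/unit`; half-unit remainders are flagged. An amplicon
exceeding the largest plausible allele size — as produced by an inserted IS
element of ~1 kb or more — is a **null allele** (`NULL_IS`); flanks missing
or non-unique give `MISSING`.

Profiles are compared with the categorical coefficient: the share of
compared loci that differ, with loci excluded when either profile is
`MISSING` and `NULL_IS` treated as an ordinary category (a metric on
complete profiles; property-tested). Clustering is UPGMA with merge height
= half the average inter-cluster distance and a deterministic lexicographic
tie-break (validated against both a naive re-averaging oracle and scipy
average linkage). The conventional cluster rule — members share 12 of 14
alleles — is a dendrogram cut at cophenetic distance 2/14 (inclusive).

## Pipeline, seeding, determinism

A run is one TOML/JSON config validated by a strict schema (unknown keys
are errors). The global seed is expanded per stage via
`numpy.random.SeedSequence(seed, spawn_key=(stage_index,))` with the stage
order host/lysogen/virions/reads, so stages rerun standalone reproduce the
pipeline bit-for-bit; identical configs and seeds give byte-identical FASTQ
and truth tables. Stage failures are recorded in the report and downstream
stages are skipped.

## Bundled scenario calibration

* **lateral** — one 46-kb prophage, `pac_offset` 16 kb, left orientation, up
  to 4 headfuls at continuation 0.5, `in_situ_prob` 0.5; 30,000 packaging
  events, 200,000 reads of 100 bp, ~2% host reads; 450-kb host with attB at
  250 kb (enough left flank for the full ~168-kb staircase). This yields
  ~10⁵ lateral-transduction reads and a first-step depth of ~150×.
* **induction_two_phage / induction_five_phage** — excised-circle
  profiles with expected read shares 97/0.8% and 52/6.6/0.1/35.5/0.026%.
  `induction_weight` is an event rate while the published percentages are
  read shares, so weights are set to `percent/(L − read_len + 1)`; with
  ~one read sampled per molecule the read counts stay near-multinomial.
  Host sizes (3 Mb / 6 Mb) and prophage lengths (10–62 kb) are scaled-down
  stand-ins for ~7-Mb genomes chosen to preserve the depth ratios that make
  the weakest peak (0.026%) clear the 5× background threshold.
* **null** — the same prophage packaging only from the excised circle; the
  detector must stay negative.

## Numerical choices and degenerate inputs

Log-depth uses `log2(depth+1)`. Segmentation on a constant signal returns
no breakpoints (zero SSE). `period_bp`/`pac_offset_bp` are NaN when fewer
than two steps exist. Asymmetry with an empty opposite flank is +inf and
its score contribution saturates at 1. Equal flank masses choose "left" but
are immaterially followed by step trimming, which decides between a real
fit and `side="none"`. Zero mapped reads raise an error in quantification;
an empty prophage list makes the lysogen the host itself. UPGMA distance
ties are broken lexicographically, making dendrograms reproducible.

## What the tests do and do not show

Passing tests demonstrate correct geometry, calibration and inference on
i.i.d. genomes with uniform coverage and substitution-only errors. They do
not demonstrate robustness to real-genome features: repeats and IS elements
(multi-mapping), GC-dependent coverage bias, excision-junction (attP)
reads, partial prophage deletions, or non-geometric headful decay. The
mapper is exact and unsuitable for diverged references; use an external
aligner and feed the SAM/bedGraph in. The 170-kb total staircase extent is
reported only through its decomposition into steps.

## Problem sizes

Default test and acceptance runs use 450-kb–6-Mb references and 10⁴–3×10⁵
reads — sizes chosen so the complete suite runs in a couple of minutes on
one CPU while every estimator is still in its asymptotic regime (first-step
depth ≥20×). All sizes are config values; nothing in the code assumes them.
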