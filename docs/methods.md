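# Methods

## Background and model

Degenerate metabarcoding primers (IUPAC ambiguity codes, one synthesis
encoding many concrete oligo variants) can anneal productively a few bases
away from their intended binding site when the site's 3' terminus lies in a
low-complexity region — typically a homopolymer — that continues past the
site in the direction of elongation. After bioinformatic primer trimming
the amplicon then appears 1–several nt shorter (forward slip, deletion) or
1 nt longer (backward slip, insertion) than expected, even though neither
primer nor template carries an indel. The effect is template-specific: it
appears only in taxa whose binding-site context permits shifted anchoring,
so it skews per-taxon length distributions and can create spurious OTUs
when clustering counts terminal gaps.

`primerslip` implements this mechanism three ways, which check each other:

1. a **feasibility rule** deciding which shifted binding offsets are
   possible for a primer on a concrete site (`primers.feasible_slips`);
2. a **stochastic PCR model** propagating those offsets through cycles
   (`simulate`), with an analytic closed form for its simplest regime;
3. a **detection pipeline** recovering the footprint-length distributions
   from reads (`pipeline`), as one would on real amplicon data.

## Shifted-binding feasibility (the anchor rule)

A primer of length L occupies template positions `[start, start+L)` on the
strand it anneals to (0-based, half-open; reverse primers are assessed on
the reverse complement). A slip offset `+s` shifts the whole primer `s` nt
in the elongation direction (yielding an `s` nt deletion after trimming);
`-s` shifts away (insertion). An offset is *feasible* when at least one
expanded variant's 3'-terminal `anchor_len` bases match the template,
position by position, at the shifted location. Because IUPAC positions are
independent, this reduces to per-position code/base membership tests; a
brute-force oracle that expands every variant and compares characters is
kept in the test suite and acceptance script as the independent route.

Choices and rationale:

- **anchor_len = 5 (default).** Only the 3' tip needs to find complementary
  bases for the polymerase to extend; full-length matching at a shift would
  essentially never hold. The minimal productive match length is not an
  established constant, so it is a parameter, not a claim.
- **Search window [-1, +4] (default).** Single-base insertions and up to
  4 nt deletions (the tandem-repeat case) cover the behavior documented for
  the COI primer sets that motivated the tool; configurable.
- **Sign convention.** `+` = deletion is fixed here because prose
  descriptions of "upstream/downstream" slippage are ambiguous; the
  observable outcomes (deletions common, 1 bp insertions rare) pin the
  mapping.
- **Diagnostics.** `run_in_site` is the homopolymer run at the 3'-terminal
  site position (capped at the site), `run_extension` its continuation into
  the flank, and `distinct_3prime` is true iff the last two code sets are
  disjoint — i.e. *every* variant ends in two different bases (GC-clamp
  pattern). An interrupted run (`run_extension = 0`, no tandem repeat)
  makes all positive slips infeasible; a clamp does the same from the
  primer side.
- **Monotonicity caveat.** Inserting one more run base at the site/flank
  junction preserves every run-driven forward slip (s ≤ run_extension) and
  increments `run_extension`. It does *not* guarantee preservation of
  slips that were feasible only through coincidental matches further
  downstream, since those positions shift; the property test is scoped
  accordingly.

## PCR slippage simulation

Each cycle every molecule is copied with probability `efficiency` (e).
A copy inherits its parent's cumulative offset and, with probability
`slip_prob` (q) — given any nonzero offset is currently feasible — adds one
drawn offset (uniform over the feasible set by default; `offset_weights`
exposes length-dependent weighting without a default claim, since no
functional form of slip rate vs run length is established). Originals
persist; the pool grows by a factor `1 + e` per cycle in expectation.

- **Irreversibility / capacity.** A forward slip of `s` consumes `s` nt of
  the homopolymer continuation in every descendant, so molecules are
  tracked as `(offset, remaining capacity)` classes; capacity starts at the
  assessment's largest feasible forward slip (the run extension for
  homopolymer sites, the repeat length for tandem sites) and never
  increases along a lineage.
- **Backward coupling.** A shortened run also removes the room a primer
  needs to anchor one base early, so with `backward_coupling=True`
  (default) insertions are only available to molecules whose capacity is
  still at its initial value — the class-level expression of re-evaluating
  feasibility on the product sequence, since a class's product homopolymer
  is shortened exactly when its capacity has decreased. The control switch
  disables this, and paired runs show the coupled insertion/deletion ratio
  never exceeds the uncoupled one. Cumulative insertions are bounded by
  the window's insertion limit.
- **Closed form.** Forward-only with unlimited capacity, the unslipped
  count grows by `1 + e(1-q)` per cycle while the pool grows by `1 + e`,
  so the unslipped fraction after c cycles is
  `((1 + e(1-q)) / (1 + e))^c` — e.g. `(1 - q/2)^c` at e = 1. The Monte
  Carlo model reproduces this within 3 standard errors across a
  (q, e, c) grid in the acceptance checks; q itself is a free parameter
  (no measured per-event slip rate exists), so validation is against the
  recursion and qualitative patterns, not a fitted rate.
- **Pool cap.** The pool is multinomially resampled down to `pool_cap`
  (default 10,000) when it grows past it, with the scale factor recorded;
  only offset *fractions* are analyzed, which resampling preserves in
  expectation. Default founding pool: 1,000 template molecules.
- One copy event draws one offset; multi-base deletions arise by
  accumulation across cycles or by a single tandem-repeat offset. Both
  paths are allowed.

## Synthetic communities and reads

`synth` engineers haplotypes whose forward binding site realizes a
requested in-site run length (`h_in`), flank extension (`h_ext`),
interrupting base, or tandem repeat unit, around a slip-0 match to the
primer; cores are i.i.d. uniform ACGT with runs of 5+ rejected, so the
engineered site is the only low-complexity region and exact-core anchoring
is unambiguous. The reverse site is generated slip-protected (the built-in
demo reverse primer carries a GC clamp), mirroring the common design of
well-behaved reverse primers. Ground truth is *recomputed* through the
scanner after construction, never asserted, and templates whose random
parts accidentally enable unintended slips are redrawn.

Default community (the conditions the package's end-to-end checks use):
10 taxa, half slip-prone (`h_in=4`, `h_ext` alternating 2 and 3) and half
protected (`h_in=4`, `h_ext=0`, interrupted), uniform abundances, 120 nt
cores, q = 0.05, e = 1, 25 cycles, 2,000 error-free merged reads per
taxon. These sizes keep a full run under a second while leaving sampling
noise (SD of a per-taxon proportion ≈ 0.01 at 2,000 reads) far from the
10% affected threshold.

Reads carry the incorporated primer at the terminus with the footprint
shortened/lengthened by the molecule's offset; sequencing error is
substitution-only with a constant quality symbol (default "I"). Indel
errors are deliberately excluded: terminal length variation must come from
the primers. Consequently, passing tests demonstrate recovery of
primer-induced variation under clean anchoring; they do not probe indel
sequencing noise, chimeras, abundance bias, or per-taxon core-length
variation (the generator uses one core length per community).

## Detection pipeline

- **Merging.** A naive exact-overlap merger: longest overlap ≥ 10 nt with
  mismatch fraction ≤ 0.10 (inclusive — a 90%-identity overlap passes);
  disagreements resolved toward the higher quality symbol.
- **Anchoring.** A read is assigned to the *unique* reference whose full
  inter-primer core occurs as an exact, gap-free substring (either
  orientation); one substitution in the core unassigns the read, and cores
  shared by ≥ 2 references make it ambiguous. A 30 nt prefix index
  accelerates the scan with full-core verification, provably identical to
  the full scan.
- **Footprints.** The 5' overhang before the anchored core is the apparent
  forward-primer footprint (the 3' overhang serves the reverse primer in
  `mode="both"`). Footprints more than `artifact_margin = 2` nt *above*
  the expected length are excluded as sequencing artifacts (with a warning
  past 3 per taxon); +1/+2 insertions are genuine signal and retained, as
  are all shorter footprints. Proportions are computed after exclusion,
  and both counts are reported.
- **Calls.** A taxon is *affected* when deviating reads / retained reads
  ≥ 0.10, evaluated on integer counts so the boundary is exactly
  inclusive. Taxa with no retained reads are undefined and excluded from
  grouping.
- **Group test.** Two-sided Welch (unequal-variance) t-test on per-taxon
  proportion-at-expected-length between affected and unaffected groups —
  Welch because protected-group variances are typically orders of
  magnitude smaller (often exactly 0, a degenerate case handled
  explicitly: identical constant groups give p = 1). The test is
  undefined (NA) when either group is empty or has one member.
- **Reporting.** The summary row gives the signed variation range
  (footprint − expected, so insertions are positive: "-3 to -1 bp" means
  1–3 nt deletions), mean ± SD of per-taxon proportions over all analyzed
  taxa as percentages (2 decimals, half-even rounding), and the p value or
  NA. Histograms carry per-taxon percentages summing to 100. Accounting
  closes exactly: input = merge-failures + unassigned + ambiguous +
  assigned, and per taxon assigned = artifact + retained.

## Numerical and degenerate-input choices

- Threshold comparisons use integer counts (affected rule) or an epsilon
  on the count scale (merge identity), never raw float ratios, so stated
  boundaries are exact.
- `susceptibility_report` keeps templates without any slip-0 match as
  `unalignable` rows; empty template sets yield an empty table with a
  warning, not an error.
- All randomness flows through numpy Generators seeded from one master
  seed per run; identical seed + configuration reproduces trajectories,
  FASTA/FASTQ and TSVs byte-for-byte. Output TSVs embed a configuration
  hash.

## Known limitations

- No thermodynamics: feasibility is a string-matching rule, not a ΔG/Tm
  model; mismatch-tolerant shifted binding beyond the exact anchor is out
  of scope.
- The per-event slip probability q and any dependence on run length are
  unmeasured free parameters; simulator outputs are mechanistic
  illustrations, not quantitative predictions for a specific polymerase.
- The backward-coupling rule is a class-level approximation of product-
  sequence re-evaluation; it captures the suppression direction but not
  variant-specific product composition.
- OTU clustering, denoising, taxonomy and abundance correction are outside
  the package; real-data use assumes known haplotypes for the analyzed
  taxa.
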