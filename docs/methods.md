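# Methods

## Model and objective

A CpG island is operationalized as any interval satisfying a criteria set
(length, GC fraction, CpG observed/expected ratio). Two presets are built
in: GGF (200 bp, 0.50, 0.60) and TJ (500 bp, 0.55, 0.65); the TJ preset is
engaged automatically when a repeat (Alu) mask is supplied, because
unmasked Alu copies mimic island composition. O/E uses the composition-
independence expectation, O/E = (#CpG · N)/(#C · #G), with N the number of
unambiguous bases; O/E is defined as 0 when the interval contains no C or
no G, and statistics over all-N intervals are undefined (surfaced as an
`UndefinedStatistic` error in scalar code, fitness 0 in the optimizer).

N handling: Ns never enter the base tallies and always break a CpG dimer.
This keeps assembly gaps and masked repeats from counting as AT-rich
sequence, at the cost that a span's nominal length can exceed N.

Coordinates are 0-based half-open everywhere internally and in BED files;
1-based numbers appear only in prose reports.

## Search

Candidates are encoded as (Fs, Fl) with Fe derived, which makes the
feasibility constraints box constraints: Fs ∈ [0, L_w − len_lo],
Fl ∈ [len_lo, min(len_hi, L_w)] for a window of length L_w. The canonical
island length band is len_lo = 200, len_hi = 2000 bp.

Fitness is gated-additive: GC + O/E + (length − 200)/1800 clipped to [0,1]
when all three criteria components hold, else 0.1 per satisfied component.
The gate guarantees the optimizer's argmax satisfies the criteria whenever
any feasible segment exists (infeasible scores top out at 0.2, feasible
scores start at 1.1 under GGF); the per-component partial credit keeps a
gradient toward feasibility. The additive composition itself is a design
choice; any composition that is monotone in the three components and
respects the gate would rank feasible candidates similarly.

Swarm parameters: population 300, 100 iterations, c₁ = c₂ = 2, inertia
annealed linearly 0.9 → 0.4. Velocities are clipped to ±L_w/5 per
dimension — some bound is necessary on bp-scale coordinates — and
positions stay real-valued during flight, rounded to integer bp only when
fitness is evaluated. Boundary violations are repaired by clamping, length
first, then start. Per-particle uniform r₁, r₂ are drawn fresh each
iteration. All randomness flows through one `numpy` generator, so a seed
fixes the output exactly.

Stagnation and escape: when gbest fitness is bit-identical for 5
consecutive iterations (fitness is computed on rounded-bp intervals, so
exact equality is meaningful), ⌊population/2⌋ particles chosen uniformly
without replacement — excluding the gbest holder — are reflected through
the solution-space midpoint, x′ = X_max + X_min − x, with velocity zeroed
and personal bests retained. The reflection is an involution and maps the
feasible box onto itself.

Multiple islands per sequence: each window is searched repeatedly, masking
each feasible find with Ns before the next restart (deflation), up to 5
finds per window. Windows are 10 kb with 2 kb overlap — the overlap
exceeds the maximum island length, so an island crossing a seam is seen
whole by the next window; duplicate finds from seams are unioned during
pooling (if a union unexpectedly fails the criteria the higher-fitness
constituent is kept). Fitness evaluation is O(1) per candidate via
prefix-sum profiles of C, G, non-N and CpG counts, which is what makes the
300 × 100 swarm budget cheap.

## Refinement

A left-to-right scan merges adjacent islands with an inter-island gap
(next start − previous end) < 200 bp when the merged span, gap included,
still satisfies the active criteria; accepted merges immediately become
candidates for further merging, and passes repeat to a fixed point. The
rule is accept-iff-criteria-hold — there is no learned value function —
and is greedy in position order. Island count never increases, covered
length never decreases, and `refine` is idempotent. Extension of isolated
islands into flanking sequence without a neighbor is deliberately not
performed; only merge-driven extension is defined.

## Evaluation

Confusion counts are per-nucleotide, computed by interval arithmetic
(merge, then a two-pointer intersection) and cross-checked in tests
against an explicit per-base bitmap. SN, SP, ACC, PC = TP/(TP+FN+FP) and
the Matthews-style CC follow; any zero-denominator metric is reported as
NaN ("NA" in text output) rather than raising. ROC curves sweep the
island-fitness threshold; the area uses the trapezoid rule over the swept
range. Promoters are −1500/+500 bp around the TSS, read in transcript
orientation (the genomic window flips on the minus strand); promoter
overlap requires ≥ 1 shared bp, TSS overlap requires the site itself
inside an island.

Report display conventions: coverage to one decimal, methylation density
truncated (not rounded) at two decimals — matching how genome survey
tables print such densities — and mean island length floored to an
integer. Full precision is kept internally and in all return values.

## Synthetic data

Background sequence is a first-order Markov chain whose base distribution
sets the GC level and whose C→G transition probability is multiplied by a
suppression factor s and renormalized; realized O/E ≈ s/(1 − p_G(1 − s)).
Defaults GC = 0.41, s = 0.25 imitate bulk human genomic composition
(≈ 41 % GC, CpG at ~¼ of expectation). Islands are produced by the same
chain with the suppression inverted from the target O/E, rejection-sampled
until empirical GC and O/E are within ±0.03 of target, and spliced into
the background with a minimum inter-island gap so ground-truth islands can
never be merged by refinement. The generator models no isochore structure,
no repeats, and no methylation-deamination gradients; recovery results on
it demonstrate the optimizer and refinement logic, not performance on real
chromosomes, where repeat content and annotation uncertainty dominate.

The canonical benchmark is 100 kb of background with 8 islands covering
lengths 300–1800 bp, GC 0.55–0.65, O/E 0.70–0.90, inter-island gap
≥ 1 kb; one integer seed determines everything. Simulated methylation
sites are drawn at CpG positions at a lower rate inside islands (0.30)
than outside (0.80), reflecting island hypomethylation.

Two reference searchers serve as oracles: an exhaustive O(L²) best-segment
scan (guarded to ≤ 5 kb; ties broken toward smaller start, then smaller
length), itself validated in tests by full enumeration on a 60 bp toy; and
a minimal 200 bp sliding-window scanner of the classical kind.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale instances chosen
to exercise every code path with comfortable statistics: ≤ 2 kb windows
against the exhaustive oracle (20 seeds), a 6 kb two-optimum fixture for
the escape comparison (20 seeds), the 100 kb benchmark over 10 seeds in
tests and 5 derived seeds in the acceptance script. Stagnation equality is
exact float equality; BED output is sorted by (chrom, start); all report
SDs are population (not sample) standard deviations.

## Known limitations

* Boundary placement trades off length reward against composition
  dilution, so predictions often overhang planted islands by tens to a few
  hundred bp of flank; this costs specificity/PC while leaving
  sensitivity high.
* The gated fitness makes no distinction among feasible candidates with
  equal GC + O/E + length score; ties are resolved by search dynamics, not
  by the model.
* One swarm per window, sequential; no multi-swarm or asynchronous
  variants.
* Whether a stagnated particle's personal best should also be reset on
  complement is undetermined; it is retained here, which keeps the escape
  conservative.
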