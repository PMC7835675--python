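# Methods

`ploidmeth` reconstructs, as a tested pipeline, the analytical chain that
links promoter DNA methylation to expression heterosis in a triploid
hybrid formed from a tetraploid and a diploid parent: CpG-island
prediction on the promoter, clone-based bisulfite methylation calling in
the three plant cytosine contexts, cis-regulatory element scanning, and a
ploidy-weighted mid-parent comparison of both methylation and expression.
A seeded synthetic-data module generates study-shaped inputs so every
stage is testable without external sequence data.

## CpG-island prediction

Islands are called by the classic sliding-window rule: a window of
`window` bp (default 100) advanced by `step` (default 1) is marked when
its GC fraction is at least `min_gc` (default 0.50) and its
observed/expected CpG ratio — `#CpG x length / (#C x #G)`, 0 when C or G
is absent — is at least `min_oe` (default 0.60). Marked windows that
overlap or abut are merged; each merged interval is trimmed to its
longest sub-interval (leftmost on ties) that still clears both
thresholds when re-evaluated as a whole; intervals shorter than
`min_length` (default 100 bp) are dropped. Ambiguity codes never count
as C, G or CpG. The defaults are the published "island" defaults of the
MethPrimer-style online predictors; because such services do not
document their merge behaviour exactly, the merge/trim rule here is
chosen to be deterministic and is verified against a brute-force oracle
that enumerates every window and applies the same definitions from raw
string counts.

## Cis-element scanning

The packaged catalogue holds 24 promoter elements with their degenerate
motifs and functional categories (12 light-, 5 hormone-, 6
stress-responsive, 1 circadian filed under "other"). Alternation syntax
like `CC(G/A)CCC` is normalised to IUPAC (`CCRCCC`). A pattern position
matches a subject position when the subject base's IUPAC set is a
subset of the pattern symbol's set; an ambiguous subject base therefore
only matches a symbol that covers all its possibilities. Both strands
are scanned by default; minus-strand matches are located on the reverse
complement and reported in forward coordinates. All overlapping
occurrences are reported; the census step (`count_by_category`) counts
distinct element types by default, matching the convention by which the
catalogue's "12 light-responsive elements" are element types, not
occurrence totals.

## Bisulfite clone calling

The assay modelled is Sanger BSP: a bisulfite-converted amplicon is
cloned and individual clones are sequenced, 15 clones per island per
genotype. Calling is defined on the reference top strand under an
ungapped model: clones must match the amplicon length (otherwise
rejected as `indel_or_truncation`) and agree with the reference at
non-cytosine positions within a 10% mismatch tolerance (otherwise
`low_identity`); cytosine positions are exempt because conversion
legitimately changes them. At each reference C, clone C reads
methylated, clone T unmethylated, anything else ambiguous. Contexts are
assigned from the reference: CG, CHG, CHH with H in {A, C, T};
cytosines whose context window is truncated by the amplicon 3' end (or
interrupted by an ambiguous reference base) are UNKNOWN and excluded.

Summaries are micro-averages: methylated observations divided by
assayed observations (ambiguous excluded), pooled over clones, contexts
and — in the promoter-wide TOTAL — islands. Micro-averaging is the only
pooling under which counts are conserved and aggregation is associative
(the TOTAL does not depend on how calls are partitioned into islands);
it matches reporting a single "total methylation level of the
promoter". No conversion-efficiency filter is applied by default: in
plants CHG/CHH methylation is genuine signal, so non-CpG methylation
cannot be used as a proxy for incomplete conversion as it is in
mammalian BSP.

## Mid-parent value and heterosis classes

For a triploid from a tetraploid x diploid cross the mid-parent value
weights parents by genomic contribution:

    MPV = 2/3 * parent_4x + 1/3 * parent_2x

Weights are configurable but must be positive and sum to 1. Hybrid
traits (relative expression by 2^-ddCt with assumed 100% amplification
efficiency, or methylation fractions) are classified against the
parents into five classes — MPL (additive, at the MPV), HPL/LPL
(dominance, at the high/low parent), AHP/BLP (over-dominance, beyond
the high/low parent) — with AMBIGUOUS surfaced when no rule fits. The
decision order tests the strongest claims first:

1. hybrid mean > HP and one-sided test vs the high parent significant -> AHP
2. hybrid mean < LP and one-sided test vs the low parent significant -> BLP
3. two-sided test vs the high parent not significant -> HPL
4. two-sided test vs the low parent not significant -> LPL
5. one-sample two-sided test vs the MPV (a constant) not significant -> MPL
6. otherwise AMBIGUOUS

Default alpha is 0.05. Over-dominance is a directional claim, so rules
1-2 use one-sided tests at full alpha; the MPV is treated as a scalar
derived from parent means (variance propagation is deliberately not the
default).

**Choice of two-sample test.** With n = 3 replicates per group the test
is the power bottleneck. Pairwise comparisons are therefore computed on
the pooled residual variance of all three groups (the one-way-ANOVA
error term, df = N - k = 6), the classical protected-LSD approach;
Welch's test (df ~ 4) is available via `method="welch"`. A noncentral-t
power calculation at a true separation of 3 within-group SDs gives
one-sided power 0.943 for the pooled comparison versus 0.910 for Welch
(two-sided: 0.862 vs 0.783), and the pooled test's assumptions hold
exactly under the default synthetic noise model below. The same
analysis fixes the ceiling of class recovery at this design point: HPL
and LPL cannot exceed 1 - 0.05 (one-sided alpha spill into AHP/BLP) -
0.025 (two-sided rule-3 rejection) = 0.925, MPL is capped near
0.95 x P(reject vs both parents), and AHP/BLP by the 0.943 power, so no
level-0.05 procedure can push balanced five-class recovery at effect
size 3, n = 3 above roughly 93-94%. The recovery suite measures ~93% at
effect size 3 and ~95% at effect size 5 (where AHP/BLP power is 0.999),
which is exactly what the analysis predicts; the discrepancy at effect
3 is a property of triplicate designs, not of the implementation.

A classical one-way ANOVA utility (F, p) is provided for multi-group
trait comparisons; on two groups it reduces to the squared pooled t
statistic, which the tests verify. Degenerate inputs follow explicit
conventions: all-zero within-group variance with equal means gives
F = 0, p = 1; with unequal means the difference is called significant
(p = 0) and the classification is flagged `degenerate`.

## Methylation-vs-MPV trend

Per island and for the promoter TOTAL, and per context plus the pooled
ALL fraction, the parents' methylation fractions are combined by the
MPV formula and compared with the hybrid's fraction. The direction is
the sign of the difference with a configurable dead band (default 0 —
any nonzero difference counts, since the quantities compared are
pooled fractions, not replicate means).

## Synthetic data

The generators encode the study conditions and are not meant to be
retuned per test:

- **Promoter**: 2,475 bp; three islands of 151, 306 and 191 bp at
  positions 400, 1000 and 1800. Island interiors are sampled with a 0.20
  per-step CpG-dinucleotide emission plus uniform fill (expected GC
  ~0.67, obs/exp ~1.5) and resampled until the interval clears its
  targets (GC >= 0.55, obs/exp >= 0.75). The background is iid at GC
  0.35 with CpG dinucleotides suppressed entirely — the CpG-depleted
  composition typical of plant genomic DNA — which makes the
  observed/expected ratio zero outside planted islands and guarantees
  that no spurious island can arise by chance (at GC 0.35 without
  suppression, roughly two or three chance windows per promoter would
  clear both thresholds). Motifs from the catalogue are concretised and
  overwritten at random non-island, non-overlapping positions.
- **Clones**: per clone, each reference cytosine is methylated
  independently with its context's probability; conversion reads
  unmethylated Cs as T except for a retention probability
  (`conversion_failure`, default 0.005, the dominant bisulfite
  artifact — modelled as C-retention only); a per-base substitution
  probability (`seq_error`, default 0.001) applies everywhere. Defaults:
  15 clones per island per genotype.
- **Expression trios**: parent means default to 2.0 (high-dose parent)
  and 1.0; the hybrid mean is placed at the MPV, at HP/LP, or beyond
  them by `effect_size` within-group SDs. Replicates (n = 3) are normal
  on the linear scale, truncated at zero. The default noise model uses a
  common within-group SD of `cv x MPV` (default CV 0.05) so that "effect
  size in SD units" is a single well-defined quantity across groups and
  the pooled-variance test is exactly calibrated; per-group
  mean-proportional noise is available as `noise="per_mean_cv"`. The
  dispersion defaults are assumptions (the source study reports
  triplicate means without SDs).
- **Study bundle**: the default `simulate_study` uses the study's
  reported methylation levels — tetraploid parent 21.0%, diploid parent
  22.5% (MPV 21.50%), hybrids 17.56%, 18.33% and 17.84% — and an AHP
  expression plan at effect size 5 for the three hybrids, mirroring the
  over-dominant expression the study observed. Child seeds for the
  promoter, clone and expression stages are spawned from one master
  seed, so the whole bundle is a pure function of the configuration.

What the generators do not emulate: chromatogram-level sequencing
artifacts (errors are iid substitutions), PCR/cloning bias among clones
(clones are exchangeable draws), indels (the caller's ungapped model is
exercised by construction), linkage of methylation states along a clone
(per-cytosine independence), and lognormal qPCR noise (normal-on-linear
by default). Passing recovery tests therefore demonstrate estimator
correctness and calibration under these idealisations, not robustness
to correlated real-world artifacts.

## Problem sizes and numerical conventions

The rate-recovery experiments use 200 replicate simulations of the full
15-clone x 3-island design (~3,100 assayed cytosine observations per
replicate), which puts the standard error of the averaged estimate near
0.05 percentage points; the classifier-recovery suite uses 200 trios
per class. Property suites compare against independent brute-force
oracles on 200 random sequences (islands, motif scanning) and 1,000
random sequence/methylation-set pairs (round-trip conservation).
Output files print percentages to 2 decimals and fractions to 6;
island BED scores are `round(1000 x obs/exp)`. Pipeline re-runs with
identical inputs and seeds are byte-identical (manifests differ only in
timestamps). All randomness flows through `numpy` Generators seeded
from explicit integers or spawned `SeedSequence` children.

## Known limitations

- The real promoter of the source study is not publicly deposited, so
  the island lengths and motif census there are reproduced as design
  defaults of the simulator, not re-derived from sequence.
- The ungapped clone model rejects rather than aligns clones with
  indels; gapped alignment is out of scope.
- Five-class recovery at effect size 3 with triplicates is bounded near
  93% for any level-0.05 procedure (see above); studies needing >= 95%
  class recovery should plan for larger effects or more replicates.
- Primer-based amplicon location on converted templates is provided
  only as a helper; coordinates are the canonical interface.
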