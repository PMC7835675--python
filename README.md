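# ploidmeth

Promoter methylation and heterosis analysis for polyploid hybrid
studies: CpG-island prediction, clone-based bisulfite methylation
calling in the CG/CHG/CHH contexts, cis-regulatory element scanning,
ploidy-weighted mid-parent comparison and five-class expression-pattern
classification — plus a seeded simulator that generates complete
study-shaped input bundles.

## The problem

In a triploid hybrid formed from a tetraploid and a diploid parent,
trait expectations under additivity must weight the parents by genomic
contribution:

    MPV = 2/3 · P₄ₓ + 1/3 · P₂ₓ

A hybrid trait (relative expression by 2^−ΔΔCt, or a promoter
methylation fraction) is then classified against its parents:

| class | meaning |
|-------|---------|
| MPL   | additive — at the mid-parent value |
| HPL / LPL | dominance — at the high / low parent level |
| AHP / BLP | over-dominance — above the high / below the low parent |

Methylation is measured the BSP way: a bisulfite-converted promoter
amplicon spanning a CpG island is cloned and single clones are
Sanger-sequenced (15 per island per genotype). At each reference
cytosine, clone C = methylated, clone T = unmethylated; contexts CG,
CHG, CHH (H ∈ {A,C,T}) are assigned from the reference. Island and
promoter-wide levels are micro-averages, Σ methylated / Σ assayed. The
scientific question the pipeline addresses: does the hybrid's promoter
methylation fall below the parents' dose-weighted level, consistent
with over-dominant expression?

See `docs/methods.md` for the model details, the statistical design of
the classifier, and the simulator's assumptions.

## Worked example

Run the full pipeline on a simulated default study (two parents at
21.0% / 22.5% total promoter methylation, three hybrids below both,
over-dominant expression):

```sh
cat > study.yaml <<EOF
simulate: {seed: 1}
outdir: out
EOF
ploidmeth run --config study.yaml
```

`out/islands.tsv` — the detector recovers the three planted islands
(151/306/191 bp cores, boundaries extended by the window merge rule):

```
seq_id	start	end	length	gc_fraction	obs_exp_cpg
sim_promoter	332	591	259	0.525097	1.681818
sim_promoter	947	1371	424	0.608491	1.724624
sim_promoter	1743	2041	298	0.560403	1.796727
```

`out/heterosis.tsv` — all three hybrids are classified over-dominant
(AHP): each hybrid mean exceeds the high parent (2.04) and the
one-sided comparison is significant at α = 0.05:

```
hybrid	pattern	mpv	hp	lp	hybrid_mean	p_vs_hp	p_vs_lp	p_vs_mpv	alpha	degenerate
A-3	AHP	1.670943	2.037208	0.938412	2.558370	0.000465	0.000001	0.000124	0.05	0
A-5	AHP	1.670943	2.037208	0.938412	2.398541	0.012402	0.000007	0.013375	0.05	0
A-6	AHP	1.670943	2.037208	0.938412	2.419927	0.002977	0.000002	0.001766	0.05	0
```

`out/trend.tsv` (TOTAL rows) — each hybrid's pooled promoter
methylation estimate sits below the parents' dose-weighted combination
(estimated MPV 21.57%), a decreasing trend:

```
hybrid	scope	context	hybrid_percent	mpv_percent	direction
A-3	TOTAL	ALL	16.82	21.57	decrease
A-5	TOTAL	ALL	19.70	21.57	decrease
A-6	TOTAL	ALL	17.93	21.57	decrease
```

Each number is a pooled clone count: e.g. A-3's 16.82% is 557
methylated of 3,311 assayed cytosine observations across 15 clones ×
3 islands (`out/summary.tsv`). Re-running with the same seed reproduces
every TSV byte-for-byte.

The same stages are available individually (`ploidmeth islands`,
`scan`, `methcall`, `heterosis`, `trend`, `simulate`) and as library
functions (`find_cpg_islands`, `scan_motifs`, `call_clone`,
`classify_expression_pattern`, ...).

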