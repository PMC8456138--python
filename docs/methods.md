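# Methods

This note documents the models and procedures implemented in `asexpress`,
the parameters that matter, the numerical choices, and what the simulation
results do and do not show about real data.

## The generative model (`simdata`)

The simulator emulates a multi-lineage RNA-seq study: three sexual species
(males and females, two tissues, two biological replicates per sex × tissue
× lineage) and three asexual, female-only lineages, related by a fixed tree
in which the asexuals and their closest sexual relative form a clade of
near-zero branches:

```
root ─┬─ sinica (0.50)                        # outgroup, sex-bias reference
      └─┬─ urmiana (0.25)
        └─┬─ kazakhstan (0.01)                # closest sexual relative
          ├─ asex1 (0.01)  asex2 (0.01)  asex3 (0.01)
```

(internal branches: 0.25 above the urmiana split, 0.24 above the terminal
clade).

**Expression evolution.** Each gene × tissue has a root log2 mean drawn from
N(6, 1.5²) and evolves along each branch by Brownian steps
N(0, σ²_class · branch length). σ² defaults to 0.2 log2² per unit length
for all classes; the divergence analyses are validated by doubling the FBG
rate. Rates are indexed by the gene's root class; class changes along the
tree do not switch rate, a simplification that only matters for turnover
rates far above those studied here.

**Sex effects are centered on the base level.** A sex-biased gene carries an
effect Δ ~ N(2, 0.5²) log2 (truncated at 1): female-biased genes express at
base + Δ/2 in females and base − Δ/2 in males; male-biased genes mirrored.
15% of genes are female- and 15% male-biased at the root. Centering encodes
the mechanism that makes turnover masquerade as masculinization: when a
gene loses its bias, *both* sexes return to the base level, so females lose
expression at ancestrally female-high genes and gain it at ancestrally
female-low (male-biased) ones. An effect pinned entirely to one sex would
make loss of male bias invisible in female comparisons and the male-side
mirror undetectable — contrary to how sex-biased expression behaves, where
bias reflects divergence of both sexes from a shared optimum.

**Turnover** acts on currently sex-biased genes with probability
1 − (1−τ)^L per branch of length L (so τ is the per-unit-length rate and
the near-zero asexual branches evolve almost nothing, as the tree demands).
An affected gene is erased to unbiased (probability 0.5) or re-drawn
(new sex uniform, new magnitude). Unbiased genes do not gain bias: gains
would contaminate the unbiased reference class with shifted ratios and are
not needed to produce any of the signatures under study; this is the main
deliberate departure from full biological realism in the turnover process.

**Masculinization** m ∈ [0, 1] sets each asexual female mean to
(1−m)·female + m·male on the log2 scale, applied after turnover.

**Core and private asexuality genes.** 30 genes shared by all asexual
lineages and 20 further genes private to each, drawn from the unbiased
pool, receive ±3 log2 shifts in asexual females (same sign across lineages
for core genes). The magnitude is deliberately large — 8-fold — because the
individual contrasts have two replicates per side and shared DE genes in
such designs are precisely the high-fold-change outliers; at 4-fold the
shared-gene machinery sits at its detection boundary.

**Counts** are negative binomial with Var = μ + αμ² (α = 0.05; α = 0 is the
Poisson limit), scaled by per-library log-normal size factors (sd 0.3).
Gene lengths are log-normal with median ≈ 1.5 kb, so ~6% fall below the
500 bp reference filter and the pipeline's length filtering is exercised.

**Pooled allele depths.** Per site, an ancestral frequency p₀ ~ U(0.15,
0.85); each lineage draws its frequency from the Balding–Nichols beta with
mean p₀ and its own differentiation F (defaults mirror the tree: outgroup
0.3, mid species 0.15, terminal clade 0.01); depth ~ Poisson(50); ref reads
binomial. Site quality is a site property N(50, 8²), exercising the
QUAL ≥ 30 filter. Truth records the drawn per-site frequencies, so tests
can compare the pooled-read estimate against the same statistic on true
frequencies.

All generators are deterministic given `seed`.

## Normalization (`exprnorm`)

RPKM uses per-library column totals. Quantile normalization runs within
tissue across all lineages and both sexes jointly; tied values receive the
mean of the normalized values of their tied ranks (the limma convention).
With ties — zero counts, mostly — samples' sorted vectors then agree only
outside tie blocks; the exact identical-multiset property holds on tie-free
data and is tested there. Replicates are averaged arithmetically on the
normalized scale. Downstream log work uses log2(x + 1); the pseudocount
bounds ratios for low-expressed genes.

## Differential expression (`detest`)

A deliberately compact NB analogue of the standard count-based DE tools:

- size factors by median-of-ratios (fallback to column-total ratios when no
  gene is nonzero everywhere, with a warning);
- per-gene dispersion by method of moments on scaled counts, a trend
  α(μ) = a₀ + a₁/μ fitted by non-negative least squares with one outlier-
  trimming pass, and shrinkage α = w·trend + (1−w)·raw with
  w = n_eff/(n_eff + 4), n_eff = n − 2, floored at 1e−8;
- group means on scaled counts, delta-method standard error of the log
  fold change, Var(μ̂) = (μ̂·Σ1/s_j + n·αμ̂²)/n²;
- the Wald statistic referred to a **moderated t with df = 4·(n − 2)**
  rather than the normal. With 3v3 designs the residual df is tiny and the
  plug-in dispersion makes a normal reference overconfident (measured FDR
  ≈ 0.07 at q = 0.05); the inflated-df t acknowledges the extra information
  the dispersion trend contributes, in the spirit of limma's moderated t,
  and converges to the normal as n grows. Measured at the validation
  conditions (2000 genes, 3v3, α = 0.05, 10% spiked at |log2fc| = 2):
  null p < 0.05 fraction 0.033–0.049, FDR ≈ 0.02, power ≈ 0.94.
- BH correction over tested genes; all-zero genes are untested; a 0.5
  pseudo-mean replaces an exactly-zero group mean.

No Cox–Reid adjustment, no outlier refitting, no independent filtering; the
"combined" multi-lineage design is expressed by pooling samples into one
group, not by covariate modelling.

## Multi-set intersection test (`multiset`)

The pmf of the k-way intersection size is computed by iterated
hypergeometric mixing with scipy's log-space hypergeometric pmf, so a
20,888-gene universe does not underflow. Exactness is verified against
exhaustive enumeration (all size combinations at small n, rational
arithmetic) and against Monte Carlo at n = 200. Only the enrichment tail
P(X ≥ observed) is reported. The default universe is the set of genes
tested in all k comparisons.

## Sex bias, class shifts and the verdict (`sexbias`)

Classes come from the outgroup's M-vs-F contrast at padj < 0.05. Ratios are
log2((target mean + 1)/(outgroup mean + 1)) on quantile-normalized RPKM,
replicate-averaged. FBG and MBG ratio distributions are compared to UBG by
two-sided Wilcoxon rank-sum (scipy's exact method for small samples, normal
with tie correction otherwise). A lineage's pattern is `masculinized` iff
FBG median < UBG median and MBG median > UBG median with both p < 0.05;
`feminized` for the mirror; `none`/`mixed` otherwise.

**The winner's-curse artifact and the verdict's effect-size floor.** The
same outgroup samples classify genes and sit in the ratio denominator.
Genes classified FBG therefore have slightly overestimated outgroup female
means (and MBG underestimated), producing a spurious masculinization-shaped
shift of about −0.05/+0.06 log2 that is statistically significant at
genome scale and identical across target lineages. Real turnover and
masculinization signals measure −0.19 to −0.62 on the FBG axis. The
verdict aggregation therefore counts a lineage toward a pattern only if its
FBG median is displaced ≥ 0.1 log2 from UBG; the per-lineage pattern labels
themselves carry no floor. The artifact is intrinsic to any analysis that
classifies genes and measures relative expression against the same
reference samples — worth remembering when reading small shifts in real
data.

**Verdict rule.** With evidence aggregated as "majority of asexual
lineages" (female side, conserved subset) and "any sexual lineage, none
opposite" (male side):

- `true_masculinization`: female side masculinized, male side *not*
  feminized, conserved subset still masculinized, LD1 shifted toward males.
  The male control cannot itself be masculinized when masculinization is
  specific to asexuals (there are no asexual males), so the male block is
  used to rule the mirror out, not to confirm.
- `turnover_artifact`: female side masculinized, male side feminized (the
  mirror), conserved-subset MBG signal attenuated (lost significance or
  under half the full-set shift), LD1 female-like.
- `feminization`: the reversed mirror.
- `none`: no consistent female-side pattern; `mixed`/`undetermined`
  otherwise, with the full evidence table always emitted.

The conserved-sex-bias subset keeps genes with the same FBG/MBG call in
every sexual species; everything else tested becomes UBG.

**Expression divergence** is the per-gene Euclidean distance over
(tissue, sex) slots of replicate-averaged log2(x + 1) normalized
expression — log scale, so the distance reflects fold changes rather than
absolute abundance, and sex-biased-vs-unbiased comparisons are not
swamped by expression-level spread. Female-only targets use female slots;
sexual targets may add male slots. Classes are compared pairwise by
rank-sum.

## The maleness score (`maleness`)

Training samples (all sexual males and females of one tissue) are
log2(x + 1)-transformed, gene-centered (not variance-scaled: the input is
already quantile-normalized), decomposed by PCA with deterministic sign
fixing, and the first q PCs (90% variance, capped at n_train − 3) feed a
two-class Fisher discriminant, w ∝ S_pooled⁻¹(μ_M − μ_F), with a ridge of
1e−6·trace/q for small-sample stability. Three calibration choices matter
and were each forced by a measurable bias:

1. **LD1 is zeroed at the midpoint of the class means**, not the overall
   training mean: unbalanced refits otherwise shift every projection by
   (n_M − n_F)/(2n) of the class gap.
2. **w has unit norm in gene space**, so scores are log2-expression units
   along the discriminant and comparable across refits.
3. **Reference scores are held-out projections.** In-sample LD1 scores of a
   12-sample training set are optimistically over-separated; sample-wise
   leave-one-out still leaks each sample's lineage through its sibling
   replicate, so the pipeline holds out whole lineage × sex groups. Because
   projections of training samples attenuate differently across refits, the
   "female range" used for the overlap fraction is the envelope of
   in-sample and held-out female projections — they bracket where a
   female-like sample can score. Under these conventions asexuals simulated
   without masculinization fall inside the female envelope in 10/10 seeds
   and m = 0.3 asexuals leave it in 10/10.

Scoring new samples applies the stored centering and axes with no
refitting; scoring is affine on the log scale.

## Pooled Fst (`poolfst`)

Frequencies are pooled read proportions with no finite-pool correction.
Per-site Nei Fst is averaged unweighted over sites where both lineages pass
the filters (the mean-of-ratios estimator; ratio-of-sums is available
behind a flag). H_T ≥ H_S holds algebraically for two populations, so
negative values are asserted against rather than clamped; monomorphic pair
sites (H_T = 0) are excluded. Read sampling inflates the null by roughly
1/(2·depth) per site (~0.01 at depth 50); validation requires the null
mean < 0.02 at 5000 sites and monotone recovery over true F ∈
{0.02, 0.1, 0.3}, and the estimate stays within 0.02 of the same statistic
on the true simulated frequencies.

## Problem sizes and what the tests show

Validation runs use the generator defaults: 6000 genes (the scale of a
cross-species 1-to-1 orthologue set), 2 tissues, 2 replicates, 36 samples;
DE calibration uses 2000-gene null and spiked sets; Fst uses 5000 sites;
scenario recovery, the LDA checks and divergence use 10 seeds each. A full
scenario (simulate + normalize + DE + shifts + conserved subset + LDA +
divergence + verdict) runs in about half a second.

The simulator reproduces the statistical structure the analyses assume —
NB sampling, library-size variation, tree-structured drift, sex-bias
turnover, the asexual/sexual design asymmetry — but not several features of
real data: no mapping or orthology error, no tissue-specific sex effects
(one shared effect per gene), no gains of bias in unbiased genes, no
correlation between expression level and dispersion beyond the NB form, and
lineage relationships fixed to one topology. Passing tests therefore show
the *inference chain* is correct and well calibrated under its stated
assumptions, not that any particular biological dataset will satisfy those
assumptions.

## Known limitations

- The DE test is a two-group Wald test only; multi-factor designs are out
  of scope and the combined analysis pools samples.
- The turnover process does not create newly sex-biased genes from unbiased
  ones; real turnover includes gains, which would dilute (not create) the
  signatures detected here.
- The winner's-curse floor (0.1 log2) in the verdict is calibrated to this
  design's noise level; datasets with many more replicates could justify a
  lower floor.
- The verdict formalizes a narrative inference; borderline evidence
  combinations return `mixed` rather than forcing a call.
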