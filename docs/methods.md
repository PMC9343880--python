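# Methods

This note documents the models, rules and numerical choices behind
`medito`, the defaults and why they were chosen, and what the synthetic
cohort does and does not emulate.

## Editing quantification

Editing efficiency at a site is the fraction of edited transcripts,
estimated as `alt / (ref + alt)` where `ref`/`alt` are the counts of the
unedited/edited base of the canonical pair (C/T for sense amplicons, G/A
for antisense ones).  Bases outside the pair and deletions are excluded
from both numerator and denominator, so a stray G at a C-site neither
edits nor dilutes.  From SAM/BAM input, reads below mapping quality 20 and
bases below base quality 20 are excluded (conventional Illumina-era
thresholds; both are parameters).  A genotype-site cell is reported
missing when its depth falls below `min_call_depth` (default 50 reads) —
the per-cell floor below which a proportion estimate of a 0–1 quantity is
too noisy to classify; site-level coverage in the emulated design averages
> 500×, so the floor removes only dropout cells.  Exact 0 and exact 1 are
preserved, because the informative filter depends on them.

Amplicon references are gene-sense sequences with 1-based closed
coordinates, matching the field's `gene-position` site naming (e.g.
`rps4-926`).  G→A sites are handled symmetrically to C→T at count time; no
reverse-complementing is performed.

Clone validation (`validate_against_clones`) correlates amplicon-based
efficiencies with Sanger-clone fractions (edited clones / total clones,
typically 30 clones) over shared sites; fewer than 3 shared sites is an
error, and a zero-variance vector yields an NA correlation with a warning.

## Informative-site filter

A site is informative when (1) its conversion is canonical C→T or G→A;
(2) the fraction of observed genotype values lying at exactly 0 or exactly
1, pooled over both conditions, is below 95%; (3) the fraction of missing
genotype × condition cells is below 10%.  The pooled reading of (2) is the
stricter of the two possible readings and matches the criterion's purpose
(excluding invariant sites); a per-condition variant is available
(`per_condition_invariant=True`).  Relaxing either threshold can only grow
the informative set (tested as a monotonicity property).

## Site classification

* **Drought response** — two-sided paired *t*-test of DT − CK differences
  per site across genotypes; pairs with either value missing are dropped;
  sites with < 10 pairs (`min_pairs`) or zero difference variance get NA.
  Direction is the sign of the mean difference when flagged.
* **Ecotype differentiation** — two-sided Welch *t*-test, upland vs
  lowland, per site within each condition; < 10 non-missing values in a
  group (`min_group`) gives NA.  Welch is chosen because group variances
  cannot be assumed equal; the pooled-variance form differs negligibly at
  these group sizes.
* No multiple-testing correction by default — raw p < 0.05 defines the
  flags; Benjamini–Hochberg is available behind the `classify.bh` config
  flag for users who want FDR control over the 426 tests.
* **Patterns** — the alteration ratio `(E_d − E_w)/E_w` per genotype-site
  combination: upregulated > 0.2, downregulated < −0.2, boundaries
  inclusive into unchanged ("between −0.2 and 0.2").  `E_w = 0` leaves the
  ratio undefined; the call is upregulated when `E_d ≥ 0.05` (a real
  appearance of editing) and unchanged otherwise, preserving the
  classifier's intent without dividing by zero.  Testing and pattern
  calling are restricted to informative sites.
* **Consequence** — the codon containing the site is rebuilt from the gene
  reference, the canonical substitution applied in place, and both codons
  translated (NCBI table selectable; table 1, which plant mitochondria
  use, is the default).  The implementation is checked against brute-force
  translation of the fully mutated CDS.

## Trait association

Pearson correlations between per-site efficiencies and each trait use
pairwise-complete genotypes (maximizing n per pair; listwise deletion
would discard a genotype entirely for one missing cell).  Significance is
the dual criterion |PCC| > 0.2 AND p < 0.05; site-trait records with < 20
complete pairs are NA.  Gene-level aggregation takes the site with the
largest |PCC| and retains its sign — a signed maximum would preclude the
negative gene-level correlations that motivate the analysis; ties prefer
the positive value, then the lower gene position (a documented,
deterministic tie-break).  Correlations with post-harvest agronomic traits
carry a caveat label (booting-stage editing vs post-harvest trait) rather
than being dropped.  The site-pair structure analysis labels pairs
adjacent (consecutive panel sites of a gene), same-gene or unrelated and
compares PCC distributions with two-sided Mann–Whitney tests
(distribution-free; a Fisher-z t-test would add normality assumptions the
pair PCCs do not obviously meet).

## Population genetics

Genotypes follow the inbred-line convention: haploid 0/1 calls;
heterozygous VCF records collapse to missing with a warning, multiallelic
records are skipped.  π is Nei's average pairwise difference per SNP with
the unbiased n/(n−1) factor, summed over the window and divided by the
window length (not the SNP count), so π and π ratios are comparable across
genes; missing genotypes are handled per SNP by pairwise-complete counts.
F_ST defaults to the Hudson estimator combined over the window as a ratio
of averages (robust to rare variants and estimator-of-choice in modern
practice); a haploid Weir–Cockerham θ is available behind
`estimator="weir-cockerham"`.  Values are reported unclamped — small
negatives are legitimate sampling noise — with a clamped convenience
column.  Outliers are genes above the linear-interpolation empirical
quantile (default 95th percentile) of a ≥ 100-gene background; the scan
also reports a two-sample Kolmogorov–Smirnov comparison of the focal gene
set against the background (a one-sample KS would need a named reference
distribution, which the empirical background replaces).  Haplotype
grouping is exact-string identity over the window's SNPs; accessions with
any missing genotype are dropped rather than imputed, haplotypes with
count ≥ 2 are labeled Hap-1, Hap-2, … by descending total frequency
(lexicographic tie-break for determinism), and each population's most
frequent haplotype is its dominant allele.  Gene windows are the
−2000..+2000 bp convention; BED input (0-based half-open) is converted to
the internal 1-based closed convention on read.

## DEG rules

`flag_deg` implements |log2FC| > 1 AND p < 0.05 with strict inequalities
at both thresholds; the p-value column is the table's raw p by default
(point `p_column` at an adjusted column for FDR mode).  Core DEGs across
the four knockout lines of two PPR genes: Type I = DEG in at least one
line of *each* mutant gene; Type II = DEG in ≥ 1 line and |log2FC| > 2 in
all four lines, without requiring a consistent sign (the absolute-value
reading); Type I takes precedence.

## Synthetic cohort

The generator plants ground truth at the emulated study's scale: 64 upland
+ 60 lowland genotypes in CK and DT, 426 sites over 31 mitochondrial
genes.  True efficiencies live on the logit scale:

```
logit(E[g,s,CK]) = logit(base_s) + jitter_{g,s} + gene_factor_{g,gene(s)}
                   + global_g + upland_g · ecotype_shift_s
logit(E[g,s,DT]) = logit(E[g,s,CK]) + drought_shift_s
```

* `base_s ~ Beta(2, 2)` — broad, symmetric baseline efficiencies.
* `jitter` (sd 0.4), `gene_factor` (sd 0.3) and `global` (sd 0.25) are
  independent normals.  The gene factor makes same-gene sites co-regulated
  and the global factor gives each genotype an overall editing propensity;
  both are required for a realistic correlation landscape — with fully
  independent sites, no trait could correlate at |PCC| > 0.2 with a third
  of the panel (the squared correlations of orthogonal predictors with one
  variable cannot exceed 1).
* Default planted effects mirror the emulated editing landscape: drought
  shifts of +0.4 logits at 240 sites and −0.4 at 2; ecotype shifts of
  ±0.35 at 57 sites (40 up, 17 down); one genotype-level RWC(DT)
  correlation of −0.35.  On panels smaller than the planted counts the
  shift spec scales down proportionally, so reduced-scale runs keep the
  landscape's shape.
* Depth is negative-binomial (mean 550, dispersion 8) so the mean exceeds
  500× while depths remain realistically uneven across amplicons and
  samples; the dispersion is a free choice (no per-site depth distribution
  is specified by the design being emulated).  Edited counts are
  `Binomial(depth, p(1−e) + (1−p)e)` with sequencing error `e = 0.001`.
  Missingness is cell-wise Bernoulli (default 2%), with per-site overrides
  that blank an exact fraction of cells (used to plant filter failures).
* Traits are drawn around field-realistic means with multiplicative
  drought penalties; a driven trait is `r·Z + sqrt(1−r²)·ε` with Z the
  standardized mean efficiency of its driver sites (or the all-site mean
  for the genotype-level "global" driver), so the population PCC equals
  the target by construction.  RWC is clipped to [0, 1].
* The SNP panel draws per-gene upland–lowland divergence from Beta(0.8, 6)
  for 200 background genes (a moderately differentiated genomic
  background whose 95th-percentile F_ST lands near 0.25–0.3) and fixes the
  two focal PPR genes at divergences 0.74 and 0.62, which produce window
  F_ST ≈ 0.71 and ≈ 0.59 — strongly differentiated outliers.  Population
  frequencies are `p1 = (1−d)p`, `p2 = (1−d)p + d`, so d = 0 shares
  frequencies and d = 1 fixes differences (F_ST = 1).  Wild rice drifts
  from the landrace pool with divergence 0.25.
* The DE table plants 90 Type I genes, 35 Type II genes (125 core DEGs)
  and 300 ordinary single-line DEGs among 2,000 genes.

**What passing tests do and do not show.**  The generator produces
independent binomial counts given the truth; it does not model PCR
chimeras, index hopping, strand bias, reference-alignment artifacts,
population structure within ecotypes, kinship, or coalescent demography.
Calibration and power results therefore validate the statistical rules
and estimators under clean sampling noise, not robustness to library
artifacts; the popgen estimators are validated against exact brute-force
oracles, which does transfer to real panels.

## Determinism, problem sizes, and degenerate inputs

All randomness flows from one seed through tagged `numpy` Generator
streams, so identical (config, seed) reproduces byte-identical outputs;
the pipeline manifest records output checksums and a rerun can resume from
completed stages.  Tabular floats are written at 10 significant digits.

Validation experiments use deliberately chosen problem sizes: calibration
and power at the full 426 × 124 design over 20 seeds; the pair-structure
experiment at 20 genes × 6 sites, where the Mann–Whitney comparison is the
same statistic with amply many pairs (~7k) while pair dependence (pairs
sharing a site) stays mild; oracle equivalence for π on ≤ 10 haplotypes
where all-pairs enumeration is exact; and end-to-end determinism at a
reduced 48-site scale, which exercises every code path.

Degenerate inputs resolve explicitly rather than by exception: zero-depth
cells become missing (never division by zero); zero-variance difference
vectors give NA p-values; constant clone vectors give NA correlations with
a warning; genes with no defined pattern combinations or no valid
correlation records yield NA rows; empty gene windows are flagged; ratio
denominators of zero yield NA ratios.

## Known limitations

Panel-driven only — no de novo editing-site discovery, no U-to-C or indel
editing.  The DE rules consume a fitted differential-expression table; the
package does not normalize counts or fit expression models.  Gene-level
trait records inherit the max-|PCC| site's p-value without selection
correction (by design, matching the rule it implements).  The haplotype
module groups and counts; network layout is out of scope.
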