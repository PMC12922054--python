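# Methods

## The microarray game

The package analyzes a genes × samples matrix of normalized, preprocessed
expression values with a two-group design (controls $S_C$, cases $S_E$;
at least two controls, since the control standard deviation is a sample
statistic). Each expression property — over- and under-expression — is
encoded against the control distribution of the same gene:

* control summary: per-gene mean $\mu_i^C$ and **sample** SD $\sigma_i^C$
  (divisor $n-1$). The sample divisor is forced by the worked example: at
  one sensitive cell the population divisor would flip the reference
  under-expression matrix.
* indicators: $B^+_{ij} = \mathbf 1[X_{ij} \ge \mu_i^C + \sigma_i^C]$ and
  $B^-_{ij} = \mathbf 1[X_{ij} \le \mu_i^C - \sigma_i^C]$, inclusive at
  the boundary, applied to *all* samples (the control-side games and the
  selection threshold need the control columns too).

Each column of a group-restricted Boolean matrix is a winning coalition
$C_j$; its unit utility is split equally, so gene $i$ earns $1/|C_j|$ when
it is a member. The per-condition Shapley value is the mean of these
shares over the condition's samples, **including** samples with empty
coalitions in the divisor — that convention is what reproduces the worked
example's values (e.g. $(1 + 1/3)/5 = 0.267$ with three empty columns).

The aggregate game behind this closed form is the average of the
unanimity games of the nonempty supports,
$v(T) = \frac{1}{|S|}\#\{j: \emptyset \ne C_j \subseteq T\}$. The package
carries a brute-force classical Shapley implementation (subset
enumeration with factorial weights, capped at 20 players) used purely as
an independent oracle; tests confirm agreement with the closed form to
1e-10 on random instances.

## ADSV, CASh and selection

The effect statistic is $\mathrm{ADSV}_i = |\phi_i^C - \phi_i^E|$.
Significance comes from relabeling:

* **Resampling mode.** Default `permute_labels`: a uniformly random
  relabeling preserving the observed group sizes. Group sizes enter the
  game's divisors, so holding them fixed isolates sample exchangeability.
  A `bootstrap_labels` mode (independent relabeling with the observed
  control proportion, rejecting draws with <2 controls or <1 case) is
  provided for users who want literal with-replacement semantics.
* **Recomputation.** Default `recompute_binarization=True`: the encoding
  thresholds are functions of whichever samples are currently labeled
  control, so each resample re-runs the full pipeline from raw
  expression. A fixed-matrix mode (re-partition the original Boolean
  columns only) exists for comparison; on the worked example it produces
  far flatter null distributions and is not recommended.
* **p-value.** $p_i = \frac1B \sum_b \mathbf 1(\mathrm{ADSV}^*_{ib} \ge
  \mathrm{ADSV}_i)$ with an inclusive indicator; ties are counted using an
  absolute tolerance of 1e-12 so that mathematically equal resampled
  statistics count as exceedances regardless of floating-point summation
  order. A gene with observed ADSV = 0 therefore always gets $p = 1$.
  The literal estimator can return 0; an optional add-one correction
  $(1+\text{count})/(B+1)$ bounds it away from zero and is off by
  default. Optional Benjamini–Hochberg adjustment across genes within a
  direction is available (off by default; the worked example's reference
  values are uncorrected).
* **Determinism.** Resample $b$ is a pure function of `(seed, b)` via
  spawned seed sequences; identical seed and config give identical
  p-vectors.
* **Selection.** Candidates satisfy $p_i \le \alpha$ (default 0.05) and
  $\mathrm{ADSV}_i \ge$ mean + sample SD of the game's **pooled** $2n$
  Shapley values. The pooled-Shapley statistic is a deliberate
  interpretation: the prose description ("mean plus SD for the group")
  is ambiguous, and the mean + SD of the ADSV column itself reproduces
  neither reference cutoff (it gives 0.158/0.199 instead of 0.130/0.181),
  while the pooled reading reproduces both. The literal ADSV-based
  statistic remains available via `adsv_threshold(..., stat="adsv")`.
  Directions are analyzed independently; the reported candidate set is
  their union.

### On the reference p-values of the worked example

The deterministic stages of the worked example (both Boolean matrices,
all four Shapley tables, the ADSV columns, both thresholds) are
reproduced exactly. The resampling p-values are not exactly
reproducible by any documented variant: with 5 + 5 samples there are only
$\binom{10}{5} = 252$ balanced relabelings, and exhaustive enumeration
(rational arithmetic) gives inclusive p-values of 13/252 ≈ 0.052 for
gene7 and 10/252 ≈ 0.040 for gene8 in the under game, versus the
reference 0.04 and 0.02. Monte-Carlo estimates at B = 1000 concentrate
around these exhaustive values. Consequently gene8 clears α = 0.05 for
nearly all seeds, while gene7 — whose true exceedance probability sits
just above α — crosses 0.05 in either direction depending on the seed;
the candidate set {gene7, gene8} is obtained for roughly half of seeds
rather than all. One acceptance-suite test encodes the stricter
expectation and documents this gap as a known failure.

Because the null ADSV distribution is discrete with many ties, the
inclusive estimator is mildly conservative: on null simulations the
fraction of genes with $p \le 0.05$ measures ≈ 0.043, within the binomial
3σ band of the nominal level used by the calibration test.

## Synthetic data

The generator emulates the structure the encoding detects: per-gene
Gaussian baselines (means uniform in [3, 7], SDs uniform in [0.05, 0.3],
the ranges spanned by the packaged example), with a *coordinated* shift
of `effect_size` × (gene's own SD) applied to all signal genes in the
same randomly chosen fraction of case samples (defaults: 3 SD, 60%,
downward). Coordinating the affected samples is what creates joint
coalitions — cooperative rather than merely marginal signal. It does not
emulate heavy tails, zero inflation, counts, or batch effects, so passing
tests demonstrate correctness of the method's mechanics and calibration
under Gaussian exchangeability, not robustness to RNA-seq or single-cell
distributions.

At the default signal strength, null genes that happen to be
under-expressed in a single case sample form singleton coalitions worth
1/5 = 0.2 — about the planted genes' typical ADSV — so planted genes
dominate in rank on average without always occupying the top two slots.

## Numerical and design choices

* Genes with zero control SD are encoded literally (threshold collapses
  onto the mean, a value equal to the mean is coded 1 in both
  directions); a warning lists them.
* Missing or non-numeric cells are rejected at load with positions; no
  imputation, because an imputed cell would silently change coalitions.
* Gene and sample order is preserved from the input everywhere; no
  sorting.
* Shapley values are kept at full precision internally; display tables
  round to 3 decimals.
* Inclusive boundaries throughout (encoding thresholds, $p \le \alpha$,
  ADSV ≥ threshold), with 1e-12 guards on float comparisons.
* Problem sizes in the test suite: oracle checks up to 10 genes × 6
  samples (exact enumeration), calibration at 200 null replicates of the
  9 × 10 default design with B = 200, rank-recovery across 50 seeds.

## Limitations

* Exact brute-force Shapley is exponential and capped at 20 players; the
  closed form is linear and is the production path. The method overall
  presumes a preselected feature space — genome-wide matrices dilute
  coalitions and are out of scope.
* Balanced permutation p-values on small designs are coarse (multiples of
  1/252 here) and tie-heavy; B beyond ~1000 buys precision of the
  estimate, not finer granularity of the truth.
* The two-criterion selection has no joint error control; BH adjustment,
  when enabled, applies to the p-criterion only.
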