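# Methods

## Model

`countseg` segments a genome into k chromatin states from a bins × marks
matrix of raw ChIP-seq read counts. Each chromosome is one observation
sequence of a hidden Markov model; the b-th observation is the b-th count
row. Emissions are negative multinomial (NM): the per-bin total count is
negative binomial, NB(μₛ, rₛ) in the mean/size parameterisation
(Var = μ + μ²/r), and the split across marks given the total is multinomial
with state-specific probabilities pₛ. This captures the two properties that
make independent-Poisson or binarised models a poor fit for ChIP-seq:
overdispersion of every marginal and positive correlation between all mark
pairs within a state. The log density is computed entirely with log-gamma
functions; a mark with pᵢ = 0 contributes −∞ only when its count is
positive.

Two dispersion regimes are supported. In *dependent* mode (the default) one
r is shared by every state — k·n + 1 emission parameters — which rules out
implausible fits where states differ wildly in dispersion. *Independent*
mode gives each state its own r (k·(n + 1) parameters).

## Training

1. **Initialisation.** k-means (10 restarts, fixed seed) on ln(1 + counts);
   each cluster is fitted by unit-weight maximum likelihood. Transitions
   start at 0.9 on the diagonal with the remainder uniform; the initial
   distribution starts uniform. The procedure is deterministic for a fixed
   seed, and `k` may not exceed the number of distinct count rows.
2. **Baum-Welch.** The E-step is a scaled (not log-space) forward-backward
   pass: per-bin emission densities are exponentiated after subtracting
   their row maximum, and both the scaling constants and the maxima are
   accumulated into the log-likelihood, so the likelihood is exact to
   floating point at any coverage. Expected transition counts are pooled
   across chromosomes; the initial distribution is re-estimated from the
   bin-0 posteriors (pooled across sequences). The M-step uses closed
   forms, pᵢ = Σ w·xᵢ / Σ w·x₊ and μ = Σ w·x₊ / Σ w, and profiles r
   numerically: a bounded Brent search on ln r over [ln 10⁻³, ln 10⁶]
   (tolerance 10⁻⁸), maximising the weighted NB log-likelihood of the
   totals — summed over all states in dependent mode. Weighted statistics
   are collapsed onto unique totals first, which makes the search cost
   independent of genome size.
3. **Decoding.** Posterior decoding by default (per-bin argmax of the state
   posterior, ties to the lower state index) or Viterbi in log space.

Numerical guards: p and μ are floored at 10⁻¹⁰ after each M-step (a state
may transiently own no reads of a mark); transition and initial
probabilities are floored at 10⁻¹² and renormalised; a bin with zero density
under every state raises an error naming the bin. The EM objective is
asserted non-decreasing (absolute slack 10⁻⁶, absorbing the numeric r-step)
at every iteration. Convergence is declared when the relative improvement
drops below 10⁻⁶, with a 200-iteration cap; both are configurable. The
final model's states are sorted by decreasing μ so labels are reproducible
and interpretable across runs. Computation is single-threaded and
deterministic; the CLI's `--threads` flag is accepted for interface
compatibility and never affects results.

## From reads to counts

Bins are half-open, non-overlapping, and tile every base pair; the last bin
of a chromosome may be truncated, and an offset grid (first bin [0, offset))
supports the bin-shift robustness analysis. Read positions are the 5′
mapping coordinate shifted 75 bp (configurable per mark) in the 5′→3′
direction — a proxy for the fragment midpoint — and clamped to the
chromosome. Unmapped, secondary and supplementary records are skipped, as
are reads under a configurable mapping-quality floor (default 0, since no
particular filter is canonical) and, for paired-end data, everything but
first-in-pair reads (the shift heuristic assumes single-end semantics).
Duplicate marking and fragment-length estimation are out of scope; the
shift is a user parameter.

## Evaluation machinery

* **Average Jaccard.** Segmentations are compared per state as base-pair
  sets: J_s = |I₁∩I₂| / |I₁∪I₂|, averaged over max(k_A, k_B) states under
  the one-to-one matching that maximises the sum, solved exactly as a
  linear assignment. Base-pair units keep offset-shifted binnings
  comparable; a bin-unit option exists for identical schemes.
* **Classifier scores.** Precision = TP / bins in state (0 for an empty
  state), sensitivity = TP / positives; the reported state maximises
  precision, ties to the lower index.
* **Categorical R².** 1 − SS_within/SS_total with per-state means as fitted
  values — the exact OLS solution for a categorical predictor.
* **Mutual information.** Plug-in estimate in bits from the empirical
  contingency table, no bias correction; gap and unannotated bins are
  excluded by default.
* **Posterior entropy.** Shannon entropy (bits) of each bin's state
  posterior, summarised against per-bin total coverage by greedily merging
  adjacent sorted coverage values until every group holds ≥ 500 bins
  (trailing remainder merged backwards).
* **Supervised annotation.** Rule-based evaluation labels from DNase and
  RNA signal quantiles (over non-gap bins), TSS proximity and gap masks, in
  a fixed order: gap; DNase bins above the stringent DNase quantile, split
  into DNase+TSS / DNase−TSS at distance d_tss; RNA bins above the
  stringent RNA quantile with DNase below the permissive DNase quantile, at
  least d_rna inside the contiguous run where that joint condition holds;
  intergenic bins at least d_int from any DNase bin or any bin above the
  permissive RNA quantile; the rest unannotated. Defaults (DNase stringent
  0.95, both permissive 0.50, RNA stringent 0.90, d_tss = 1 kb,
  d_rna = 2 kb, d_int = 10 kb) are the package's own choices and fully
  configurable — no canonical values exist. The permissive RNA threshold
  enters only the intergenic exclusion zone; the RNA-bin rule itself pairs
  the stringent RNA threshold with the permissive DNase threshold, which we
  judged the internally consistent reading of the procedure.

## Synthetic data

The generator draws hidden paths from the Markov chain (inverse-CDF, so
fixed seeds reproduce bit-identically) and counts from the state's NM. It
is the exact generative counterpart of the fitted model: passing tests show
the estimator recovers its own data-generating process, not that real
chromatin follows it — real data add mappability artefacts, duplicate
reads, copy-number and input biases that are deliberately not modelled.
Optional gap intervals force zero counts (truth label: the lowest-μ state),
mimicking assembly gaps. `simulate_reads_bam` inverts counting: every
counted unit becomes an aligned read whose shifted position falls back in
its source bin (strand chosen at random, flipped or clamped only where a
chromosome edge leaves no valid placement), so BAM → count round trips are
exact and the binning/counting path is testable end to end.

The default benchmark is 3 states × 4 marks, dependent mode, shared r = 5,
diagonal transitions 0.98, two chromosomes of 10,000 bins of 200 bp, with
archetypes chosen to span the regimes that matter: near-empty (μ = 0.5,
uniform split), background (μ = 20, mildly repressive-skewed), and
promoter-like (μ = 400, concentrated on two active marks). Separations are
wide because the benchmark's job is to verify estimator correctness and
determinism, not to probe hard statistical limits; the replicate- and
shift-robustness analyses run on this same scale (20,000 bins), which keeps
the full suite and the acceptance script to seconds on one CPU.

## Design choices on genuinely open points

* Transcript-body rescaling to the reference grid uses floor
  (nearest-index) proportional mapping; profiles are tallied per base pair
  with minus-strand transcripts flipped so upstream is left. Default grid:
  5,000 bp flanks at 1 bp, body of 1,000 units; plots aggregate flanks to
  10 bp bins.
* Mark-level heatmaps use natural log of (1 + mean count); the log base is
  a display choice and is documented here.
* Each chromosome is an independent sequence sharing one pooled
  initial-state distribution.
* Model files are JSON with full double precision; loading re-validates
  stochasticity and the shared-r constraint in dependent mode.
* Model-order selection (AIC/BIC) is deliberately absent; k is a user
  input.

## Known limitations

* The NM cannot represent negative inter-mark correlation within a state;
  anti-correlated marks must be separated by the state structure itself.
* The r search is bounded above at 10⁶; equi- or under-dispersed data pin r
  at the bound, which is the intended Poisson-limit behaviour, not an
  estimate of a finite dispersion.
* The supervised annotation's thresholds have no canonical values; results
  using it should report the configuration.
* Plug-in mutual information is biased upward on small tables; with
  genome-scale bin counts this is negligible.
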