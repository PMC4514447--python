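# countseg

Chromatin-state segmentation directly from ChIP-seq read counts.

Genome-wide panels of histone-modification ChIP-seq experiments are commonly
summarised by dividing the genome into fixed-size bins and assigning each bin
to one of a small number of *chromatin states* — recurrent patterns of mark
abundance associated with promoters, transcribed gene bodies, repressed
domains, and so on. Popular tools binarise the counts first, which throws
away the distinction between weak and strong signal and requires an arbitrary
threshold. `countseg` instead models the raw count vectors: each bin's
bins × marks count row is an observation of a hidden Markov model whose
emission distribution is the **negative multinomial**, a count distribution
that is overdispersed in every mark and positively correlated between marks —
both ubiquitous features of real ChIP-seq data.

## The model

The genome is partitioned into non-overlapping bins of 200 bp (configurable).
For a panel of *n* marks, the count vector of a bin in state *s* follows

X = (X₁, …, Xₙ) ~ NM(μₛ, rₛ, p₁ₛ, …, pₙₛ)

defined hierarchically: the total X₊ = ΣᵢXᵢ is negative binomial with mean μₛ
and dispersion rₛ (Var X₊ = μₛ + μₛ²/rₛ), and given X₊ the counts split
multinomially across marks with probabilities pₛ. Marginals are
overdispersed, all pairwise correlations are positive, and the independent
Poisson model is recovered in the r → ∞ limit. In the default **dependent**
mode a single dispersion r is shared by all k states (k·n + 1 emission
parameters); the **independent** mode gives each state its own r (k·(n + 1)).

States evolve along each chromosome as a first-order Markov chain. Training
is standard: k-means initialisation on ln(1 + counts), Baum-Welch EM with
closed-form updates for p and μ and a one-dimensional profile-likelihood
search for r, then posterior decoding (default) or Viterbi.

Evaluation utilities cover everything needed to compare segmentations:
base-pair average Jaccard index under the optimal one-to-one state matching,
state-as-classifier precision/sensitivity, categorical-predictor R²,
mutual information against an external annotation, posterior-entropy
diagnostics, a rule-based DNase/RNA/TSS "supervised" annotation, and
genome-wide reports (state frequencies, cross-segmentation overlap,
transcript-anchored state profiles, log-mean mark heatmaps).

## Worked example

Simulate the built-in 3-state / 4-mark benchmark (two chromosomes of 10,000
bins; a high-coverage promoter-like state, a background state, and a
near-empty gap-like state; shared r = 5) and refit it:

```python
from countseg import ChromatinHMM, average_jaccard, match_accuracy
from countseg.synthetic import make_default_fixture, simulate

spec = make_default_fixture(seed=1)
counts, truth = simulate(spec)
results = ChromatinHMM(counts, n_states=3, mode="dependent").fit(seed=1)
print(results.summary())
segmentation = results.decode()
print(f"label accuracy vs truth: {match_accuracy(segmentation, truth):.4f}")
print(f"average Jaccard vs truth: {average_jaccard(segmentation, truth).jaccard:.4f}")
```

prints

```
Negative-multinomial HMM segmentation
======================================================
states:            3
marks:             4 ['H3K4me3', 'H3K27ac', 'H3K36me3', 'H3K27me3']
dispersion mode:   dependent (13 emission parameters)
bin size:          200 bp
EM iterations:     4
log-likelihood:    -180873.290

            mu      r  p[H3K4me3]  p[H3K27ac]  p[H3K36me3]  p[H3K27me3]  self_transition  frequency
state
0     398.2532 4.9414      0.4498      0.4001       0.1001       0.0499           0.9786     0.3249
1      19.9130 4.9414      0.1515      0.1497       0.3006       0.3982           0.9791     0.3456
2       0.5122 4.9414      0.2372      0.2505       0.2555       0.2568           0.9806     0.3296

label accuracy vs truth: 0.9999
average Jaccard vs truth: 0.9997
```

The generating values (μ = 400/20/0.5, r = 5, self-transitions 0.98) are
recovered within a percent or two, and 99.99 % of bins get their true state
back. States are always reported in order of decreasing expected coverage μ.

The same workflow from the shell:

```sh
countseg simulate --seed 1 -o fixture/
countseg segment --counts fixture/counts.tsv --nstates 3 --seed 1 -o run/
countseg validate jaccard --sega run/segmentation.bed --segb fixture/truth.bed
countseg report --seg run/segmentation.bed --counts fixture/counts.tsv -o report/
```

`countseg getcounts --bam H3K4me3=k4.bam ... --chromsizes hg.sizes -o counts.tsv`
builds the count matrix from coordinate-sorted, indexed BAM files, shifting
each read's 5′ end 75 bp downstream (configurable per mark) before binning.

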