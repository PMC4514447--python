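"""Quantitative evaluation of segmentations.

* robustness: average Jaccard index between two segmentations under the
  optimal one-to-one state matching (linear assignment), measured in base
  pairs so that offset-shifted binning schemes remain comparable;
* states as binary classifiers (precision / sensitivity against a positive
  bin set such as assembly gaps or DNase+TSS bins);
* variance explained (R^2) of a per-bin response by the categorical state
  label;
* mutual information between a segmentation and an external annotation;
* posterior-entropy diagnostics against read coverage;
* the rule-based "supervised" annotation built from DNase / RNA quantiles
  and TSS proximity, used only for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .binning import BinningScheme, CountMatrix
from .hmm import Posterior, Segmentation

__all__ = [
    "StateMatching",
    "ANNOTATION_LABELS",
    "AnnotationConfig",
    "average_jaccard",
    "match_accuracy",
    "classifier_scores",
    "categorical_r2",
    "mutual_information",
    "posterior_entropy_profile",
    "supervised_annotate",
]

ANNOTATION_LABELS = (
    "gap",
    "DNase+TSS",
    "DNase-TSS",
    "RNA",
    "intergenic",
    "unannotated",
)


@dataclass
class StateMatching:
    """Optimal one-to-one state correspondence and its average Jaccard index."""

    mapping: dict[int, int]  # state of segmentation A -> state of segmentation B
    jaccard: float
    per_state: dict[int, float]


def _bp_labels(seg: Segmentation) -> np.ndarray:
    """Per-base-pair state labels, concatenated over chromosomes."""
    parts = []
    for chrom in seg.scheme.chrom_names:
        widths = seg.scheme.bin_widths(chrom)
        parts.append(np.repeat(seg.labels[chrom], widths))
    return np.concatenate(parts)


def _contingency(seg_a: Segmentation, seg_b: Segmentation, unit: str) -> np.ndarray:
    if unit == "bp":
        genomes_a = {c: seg_a.scheme.chrom_length(c) for c in seg_a.scheme.chrom_names}
        genomes_b = {c: seg_b.scheme.chrom_length(c) for c in seg_b.scheme.chrom_names}
        if genomes_a != genomes_b:
            raise ValueError("segmentations cover different genomes")
        a, b = _bp_labels(seg_a), _bp_labels(seg_b)
    elif unit == "bin":
        if seg_a.scheme != seg_b.scheme:
            raise ValueError("bin-unit comparison needs identical schemes")
        a, b = seg_a.stacked(), seg_b.stacked()
    else:
        raise ValueError("unit must be 'bp' or 'bin'")
    flat = np.bincount(a * seg_b.k + b, minlength=seg_a.k * seg_b.k)
    return flat.reshape(seg_a.k, seg_b.k).astype(float)


def average_jaccard(
    seg_a: Segmentation, seg_b: Segmentation, unit: str = "bp"
) -> StateMatching:
    """Average Jaccard index under the maximising one-to-one state matching.

    Per matched state pair, J_s = |I1 and I2| / |I1 or I2| over the base pairs
    (or bins) each segmentation assigns to that state; the matching maximises
    sum_s J_s (linear assignment) and the score averages over
    max(kA, kB) states, unmatched states contributing 0.
    """
    table = _contingency(seg_a, seg_b, unit)
    size_a = table.sum(axis=1)
    size_b = table.sum(axis=0)
    union = size_a[:, None] + size_b[None, :] - table
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, table / union, 0.0)
    rows, cols = linear_sum_assignment(jac, maximize=True)
    n_states = max(seg_a.k, seg_b.k)
    per_state = {int(i): float(jac[i, j]) for i, j in zip(rows, cols)}
    return StateMatching(
        mapping={int(i): int(j) for i, j in zip(rows, cols)},
        jaccard=float(sum(per_state.values()) / n_states),
        per_state=per_state,
    )


def match_accuracy(seg: Segmentation, truth: Segmentation, unit: str = "bin") -> float:
    """Fraction of units labelled correctly after the optimal state matching."""
    table = _contingency(truth, seg, unit)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / table.sum())


def classifier_scores(seg: Segmentation, positive_mask: dict[str, np.ndarray]):
    """Treat each state as a binary classifier of a positive bin set.

    precision(s) = TP / bins labelled s (0 for empty states);
    sensitivity(s) = TP / total positives.  Returns (per-state array of
    (precision, sensitivity), best state = argmax precision, ties to the
    lower index).
    """
    labels = seg.stacked()
    mask = np.concatenate([np.asarray(positive_mask[c], dtype=bool) for c in seg.scheme.chrom_names])
    if mask.shape != labels.shape:
        raise ValueError("mask does not align with the segmentation")
    total_pos = int(mask.sum())
    if total_pos == 0:
        raise ValueError("positive mask is empty")
    scores = np.zeros((seg.k, 2))
    for s in range(seg.k):
        in_state = labels == s
        tp = int((in_state & mask).sum())
        n_state = int(in_state.sum())
        scores[s, 0] = tp / n_state if n_state else 0.0
        scores[s, 1] = tp / total_pos
    best = int(np.argmax(scores[:, 0]))
    return scores, best


def categorical_r2(seg: Segmentation, response: dict[str, np.ndarray]) -> float:
    """R^2 of OLS with the state label as (the only) categorical predictor.

    With per-state means as fitted values this is 1 - SS_within / SS_total,
    the exact least-squares solution.
    """
    labels = seg.stacked()
    y = np.concatenate([np.asarray(response[c], dtype=float) for c in seg.scheme.chrom_names])
    if y.shape != labels.shape or not np.all(np.isfinite(y)):
        raise ValueError("response must align with the segmentation and be finite")
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("response has zero variance")
    ss_within = 0.0
    for s in range(seg.k):
        ys = y[labels == s]
        if ys.size:
            ss_within += float(((ys - ys.mean()) ** 2).sum())
    return 1.0 - ss_within / ss_total


def mutual_information(
    seg: Segmentation,
    annotation: dict[str, np.ndarray],
    exclude: tuple[str, ...] = ("gap", "unannotated"),
) -> float:
    """Plug-in mutual information (bits) between states and annotation labels.

    ``annotation[chrom]`` holds one label string per bin; bins carrying an
    excluded label (by default assembly gaps and unannotated bins) are
    dropped before building the contingency table.
    """
    labels = seg.stacked()
    ann = np.concatenate([np.asarray(annotation[c]) for c in seg.scheme.chrom_names])
    if ann.shape != labels.shape:
        raise ValueError("annotation does not align with the segmentation")
    keep = ~np.isin(ann, list(exclude))
    labels, ann = labels[keep], ann[keep]
    if labels.size == 0:
        raise ValueError("no bins left after exclusion")
    cats, ann_codes = np.unique(ann, return_inverse=True)
    table = np.bincount(labels * cats.size + ann_codes, minlength=seg.k * cats.size)
    joint = table.reshape(seg.k, cats.size) / labels.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / (px * py)), 0.0)
    return float(terms.sum())


def posterior_entropy_profile(
    posterior: Posterior, counts: CountMatrix, min_group: int = 500
):
    """Per-bin posterior entropies and a mean-entropy-vs-coverage curve.

    Coverage is the per-bin total read count over all marks.  Bins are sorted
    by coverage and adjacent coverage values are merged greedily (left to
    right) until each group holds at least ``min_group`` bins; a trailing
    short group is merged into its predecessor.  Returns (entropies,
    coverage, curve) with curve columns (mean coverage, mean entropy, bins).
    """
    ent_by_chrom = posterior.entropies()
    chroms = list(counts.scheme.chrom_names)
    entropies = np.concatenate([ent_by_chrom[c] for c in chroms])
    coverage = np.concatenate([counts.counts[c].sum(axis=1) for c in chroms])
    order = np.argsort(coverage, kind="stable")
    cov_sorted, ent_sorted = coverage[order], entropies[order]
    # group boundaries at changes of coverage value, then greedy accumulation
    uniq, starts = np.unique(cov_sorted, return_index=True)
    starts = list(starts) + [cov_sorted.size]
    groups: list[tuple[int, int]] = []
    lo = 0
    for i in range(len(uniq)):
        hi = starts[i + 1]
        if hi - lo >= min_group:
            groups.append((lo, hi))
            lo = hi
    if lo < cov_sorted.size:
        if groups:
            groups[-1] = (groups[-1][0], cov_sorted.size)
        else:
            groups.append((0, cov_sorted.size))
    curve = np.array(
        [
            (cov_sorted[a:b].mean(), ent_sorted[a:b].mean(), b - a)
            for a, b in groups
        ]
    )
    return entropies, coverage, curve


@dataclass
class AnnotationConfig:
    """Quantiles and distances of the rule-based evaluation annotation.

    Quantiles are taken over non-gap bins; distances are in base pairs.
    The exact values are a documented choice and fully configurable.
    """

    dnase_stringent_q: float = 0.95
    dnase_permissive_q: float = 0.50
    rna_stringent_q: float = 0.90
    rna_permissive_q: float = 0.50
    d_tss: int = 1000  # DNase bin within this distance of a TSS -> promoter-like
    d_rna: int = 2000  # RNA bins must sit this far inside their region
    d_int: int = 10000  # intergenic bins must sit this far from any signal region

    def __post_init__(self) -> None:
        for name in ("dnase_stringent_q", "dnase_permissive_q", "rna_stringent_q", "rna_permissive_q"):
            q = getattr(self, name)
            if not (0.0 < q < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {q}")


def _distance_to_true(mask: np.ndarray, bin_size: int) -> np.ndarray:
    """Per-bin distance in bp to the nearest True bin (0 where True)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.full(mask.size, np.inf)
    pos = np.arange(mask.size)
    right = np.searchsorted(idx, pos)
    left = np.clip(right - 1, 0, idx.size - 1)
    right = np.clip(right, 0, idx.size - 1)
    dist = np.minimum(np.abs(pos - idx[left]), np.abs(pos - idx[right]))
    return dist * bin_size


def supervised_annotate(
    dnase_counts: dict[str, np.ndarray],
    rna_coverage: dict[str, np.ndarray],
    tss_positions: dict[str, np.ndarray],
    gap_mask: dict[str, np.ndarray],
    scheme: BinningScheme,
    config: AnnotationConfig | None = None,
) -> dict[str, np.ndarray]:
    """Rule-based per-bin labels from DNase, RNA, TSS and gap evidence.

    Steps, in order: (1) gap bins; (2) DNase bins = DNase count above the
    stringent quantile threshold; (3) split into DNase+TSS / DNase-TSS by
    distance to the nearest TSS; (4) RNA bins = RNA above its stringent
    threshold AND DNase below its permissive threshold, at least ``d_rna``
    inside the contiguous region where that joint condition holds; (5)
    intergenic bins lie at least ``d_int`` from any DNase bin or any bin above
    the permissive RNA threshold; (6) the rest stay unannotated.  Returns one
    label-string array per chromosome.
    """
    cfg = config or AnnotationConfig()
    chroms = list(scheme.chrom_names)
    if all(np.asarray(tss_positions.get(c, ())).size == 0 for c in chroms):
        raise ValueError("empty TSS list")
    gaps = {c: np.asarray(gap_mask[c], dtype=bool) for c in chroms}
    dnase_all = np.concatenate([np.asarray(dnase_counts[c])[~gaps[c]] for c in chroms])
    rna_all = np.concatenate([np.asarray(rna_coverage[c])[~gaps[c]] for c in chroms])
    dnase_stringent = np.quantile(dnase_all, cfg.dnase_stringent_q)
    dnase_permissive = np.quantile(dnase_all, cfg.dnase_permissive_q)
    rna_stringent = np.quantile(rna_all, cfg.rna_stringent_q)
    rna_permissive = np.quantile(rna_all, cfg.rna_permissive_q)

    out: dict[str, np.ndarray] = {}
    for chrom in chroms:
        dnase = np.asarray(dnase_counts[chrom], dtype=float)
        rna = np.asarray(rna_coverage[chrom], dtype=float)
        gap = gaps[chrom]
        nb = scheme.n_bins(chrom)
        labels = np.full(nb, "unannotated", dtype=object)
        starts, ends = scheme.bin_edges(chrom)

        is_dnase = (dnase > dnase_stringent) & ~gap
        tss = np.sort(np.asarray(tss_positions.get(chrom, ()), dtype=np.int64))
        if tss.size:
            # distance from the bin interval to the nearest TSS (0 if inside)
            right = np.searchsorted(tss, starts)
            left = np.clip(right - 1, 0, tss.size - 1)
            right = np.clip(right, 0, tss.size - 1)
            d_left = np.maximum(starts - tss[left], tss[left] - (ends - 1))
            d_right = np.maximum(starts - tss[right], tss[right] - (ends - 1))
            tss_dist = np.maximum(np.minimum(d_left, d_right), 0)
        else:
            tss_dist = np.full(nb, np.inf)
        labels[is_dnase & (tss_dist <= cfg.d_tss)] = "DNase+TSS"
        labels[is_dnase & (tss_dist > cfg.d_tss)] = "DNase-TSS"

        rna_cond = (rna > rna_stringent) & (dnase < dnase_permissive) & ~gap
        boundary_dist = _distance_to_true(~rna_cond, scheme.bin_size)
        is_rna = rna_cond & (boundary_dist >= cfg.d_rna) & ~is_dnase
        labels[is_rna] = "RNA"

        signal = is_dnase | rna_cond | ((rna > rna_permissive) & ~gap)
        far = _distance_to_true(signal, scheme.bin_size) >= cfg.d_int
        is_inter = far & ~is_dnase & ~rna_cond & ~gap
        labels[is_inter & (labels == "unannotated")] = "intergenic"

        labels[gap] = "gap"
        out[chrom] = labels.astype(str)
    return out
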