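"""Hidden Markov machinery for count-based segmentation.

A k-state HMM whose time steps are genomic bins and whose emissions are
negative multinomial distributions over the marks.  Training follows the
usual three steps: initialise (k-means on ln(1 + counts)), fit by Baum-Welch
over one observation sequence per chromosome, then decode each chromosome by
posterior decoding (the default) or Viterbi.

The forward-backward pass uses per-bin scaling rather than log space: the
per-bin emission log-densities are exponentiated after subtracting their row
maximum, and both the scaling constants and the row maxima are accumulated
into the log-likelihood, so the result is exact up to floating point at any
coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .binning import BinningScheme, CountMatrix
from .negmultinom import NMParams, nm_fit_weighted, nm_log_pmf_matrix, shared_r_fit

__all__ = [
    "HMMModel",
    "Posterior",
    "Segmentation",
    "initialize_model",
    "forward_backward",
    "baum_welch",
    "posterior_decode",
    "viterbi",
    "save_model",
    "load_model",
]

_PROB_FLOOR = 1e-12  # transition/initial floor after each M-step
_EM_SLACK = 1e-6  # absolute slack on the monotonicity of the EM objective


@dataclass
class HMMModel:
    """k states with initial, transition and NM emission parameters.

    ``mode`` is "dependent" (one dispersion r shared by every state; k*n + 1
    emission parameters) or "independent" (one r per state; k*(n + 1)).
    """

    initial: np.ndarray
    transitions: np.ndarray
    emissions: list[NMParams]
    mode: str = "dependent"
    mark_names: tuple[str, ...] = ()
    bin_size: int = 200

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        k = self.k
        if k < 1:
            raise ValueError("need at least one state")
        if self.initial.shape != (k,) or self.transitions.shape != (k, k):
            raise ValueError("initial/transitions shapes inconsistent with k")
        if np.any(self.initial < 0) or np.any(self.transitions < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        rows = self.transitions.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("every transition row must sum to 1")
        if self.mode not in ("dependent", "independent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        n = {e.n_marks for e in self.emissions}
        if len(n) != 1:
            raise ValueError("all states must have the same number of marks")
        if self.mode == "dependent":
            rs = [e.r for e in self.emissions]
            if max(rs) - min(rs) > 1e-12:
                raise ValueError("dependent mode requires a single shared r")
        if self.mark_names and len(self.mark_names) != self.n_marks:
            raise ValueError("mark_names length does not match emissions")

    @property
    def k(self) -> int:
        return len(self.emissions)

    @property
    def n_marks(self) -> int:
        return self.emissions[0].n_marks

    def n_emission_params(self) -> int:
        """Distinct emission parameters: k*n + 1 (dependent) or k*(n + 1)."""
        if self.mode == "dependent":
            return self.k * self.n_marks + 1
        return self.k * (self.n_marks + 1)

    def emission_log_probs(self, counts: np.ndarray) -> np.ndarray:
        """(bins, k) matrix of per-state NM log-densities."""
        return np.stack([nm_log_pmf_matrix(counts, e) for e in self.emissions], axis=1)

    def permute_states(self, order: Sequence[int]) -> "HMMModel":
        """Relabel states so new state ``i`` is old state ``order[i]``."""
        order = list(order)
        return replace(
            self,
            initial=self.initial[order].copy(),
            transitions=self.transitions[np.ix_(order, order)].copy(),
            emissions=[self.emissions[i] for i in order],
        )

    def sorted_by_coverage(self) -> "HMMModel":
        """States reordered by decreasing expected total count mu."""
        order = np.argsort([-e.mu for e in self.emissions], kind="stable")
        return self.permute_states(order)


@dataclass
class Posterior:
    """Per-sequence bins x k state-membership probabilities and log-likelihoods."""

    gamma: dict[str, np.ndarray] = field(repr=False)
    log_likelihood: dict[str, float] = field(default_factory=dict)

    @property
    def total_log_likelihood(self) -> float:
        return float(sum(self.log_likelihood.values()))

    def entropies(self, base: float = 2.0) -> dict[str, np.ndarray]:
        """Per-bin Shannon entropy of the state posterior (default: bits)."""
        out = {}
        for name, g in self.gamma.items():
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(g > 0, g * np.log(g), 0.0)
            out[name] = -terms.sum(axis=1) / np.log(base)
        return out


@dataclass
class Segmentation:
    """Per-chromosome state labels (0..k-1) on a binning scheme."""

    scheme: BinningScheme
    k: int
    labels: dict[str, np.ndarray] = field(repr=False)
    posterior: Posterior | None = None

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.scheme.chrom_names):
            raise ValueError("labels do not cover the scheme's chromosomes")
        for chrom in self.scheme.chrom_names:
            lab = np.asarray(self.labels[chrom], dtype=np.int64)
            if lab.shape != (self.scheme.n_bins(chrom),):
                raise ValueError(f"label vector of {chrom!r} does not match the scheme")
            if lab.size and (lab.min() < 0 or lab.max() >= self.k):
                raise ValueError(f"labels of {chrom!r} outside 0..{self.k - 1}")
            self.labels[chrom] = lab

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.labels[c] for c in self.scheme.chrom_names])


def _emission_probs_scaled(model: HMMModel, counts: np.ndarray):
    logb = model.emission_log_probs(counts)
    bmax = logb.max(axis=1)
    if np.any(~np.isfinite(bmax)):
        bad = int(np.flatnonzero(~np.isfinite(bmax))[0])
        raise ValueError(f"bin {bad} has zero emission density under every state")
    return np.exp(logb - bmax[:, None]), bmax


def forward_backward(
    counts: np.ndarray, model: HMMModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward pass over one observation sequence.

    Returns (gamma, xi_sum, log_likelihood): the (T, k) posterior state
    probabilities, the (k, k) expected transition counts summed over steps,
    and the exact log-likelihood of the sequence.
    """
    B, bmax = _emission_probs_scaled(model, counts)
    T, k = B.shape
    A = model.transitions
    alpha = np.empty((T, k))
    c = np.empty(T)

    a = model.initial * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, k))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        xi_sum = A * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
    else:
        xi_sum = np.zeros((k, k))
    loglik = float(np.log(c).sum() + bmax.sum())
    return gamma, xi_sum, loglik


def initialize_model(
    count_matrices: Sequence[np.ndarray],
    k: int,
    mode: str = "dependent",
    seed: int | None = 0,
    mark_names: tuple[str, ...] = (),
    bin_size: int = 200,
) -> HMMModel:
    """Initial model: k-means clusters of ln(1 + counts) define the states.

    Each cluster is fitted with unit weights (shared r in dependent mode);
    transitions start at 0.9 on the diagonal with the rest uniform, and the
    initial distribution starts uniform.  Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    data = np.concatenate([np.asarray(m) for m in count_matrices], axis=0)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(data, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct count rows")
    if k == 1:
        assign = np.zeros(data.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assign = km.fit_predict(np.log1p(data))
    groups = [data[assign == s] for s in range(k)]
    if any(g.shape[0] == 0 for g in groups):
        raise ValueError("k-means produced an empty cluster; reduce k")
    if mode == "dependent":
        r, mu_p = shared_r_fit([(g, np.ones(g.shape[0])) for g in groups])
        emissions = [NMParams(mu=mu, r=r, p=p) for mu, p in mu_p]
    else:
        emissions = [nm_fit_weighted(g, np.ones(g.shape[0])) for g in groups]
    if k == 1:
        transitions = np.ones((1, 1))
    else:
        transitions = np.full((k, k), 0.1 / (k - 1))
        np.fill_diagonal(transitions, 0.9)
    model = HMMModel(
        initial=np.full(k, 1.0 / k),
        transitions=transitions,
        emissions=emissions,
        mode=mode,
        mark_names=tuple(mark_names),
        bin_size=bin_size,
    )
    return model.sorted_by_coverage()


def _as_matrices(counts: CountMatrix | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(counts, CountMatrix):
        return counts.matrices()
    return [np.asarray(m) for m in counts]


def baum_welch(
    counts: CountMatrix | Sequence[np.ndarray],
    k: int,
    mode: str = "dependent",
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = 0,
    initial_model: HMMModel | None = None,
) -> tuple[HMMModel, list[float]]:
    """Baum-Welch EM over one observation sequence per chromosome.

    Transition expectations are pooled across sequences; the initial
    distribution is re-estimated from the bin-0 posteriors; emissions are
    refit by weighted NM maximum likelihood (shared r in dependent mode).
    Stops when the relative log-likelihood improvement drops below ``tol`` or
    after ``max_iter`` iterations.  Returns the fitted model (states sorted by
    decreasing mu) and the log-likelihood trace; the trace is checked to be
    non-decreasing (slack 1e-6) at every step.
    """
    mats = _as_matrices(counts)
    if not mats or any(m.shape[0] < 1 for m in mats):
        raise ValueError("need at least one non-empty observation sequence")
    mark_names = counts.mark_names if isinstance(counts, CountMatrix) else ()
    bin_size = counts.scheme.bin_size if isinstance(counts, CountMatrix) else 200
    model = initial_model or initialize_model(
        mats, k, mode=mode, seed=seed, mark_names=mark_names, bin_size=bin_size
    )
    stacked = np.concatenate(mats, axis=0)
    trace: list[float] = []
    for _ in range(max_iter):
        gammas, first_bins = [], []
        xi_total = np.zeros((model.k, model.k))
        loglik = 0.0
        for m in mats:
            gamma, xi_sum, ll = forward_backward(m, model)
            gammas.append(gamma)
            first_bins.append(gamma[0])
            xi_total += xi_sum
            loglik += ll
        if trace and loglik < trace[-1] - _EM_SLACK:
            raise RuntimeError(
                f"EM log-likelihood decreased: {trace[-1]:.6f} -> {loglik:.6f}"
            )
        converged = bool(
            trace and (loglik - trace[-1]) < tol * abs(trace[-1])
        )
        trace.append(loglik)
        if converged:
            break

        initial = np.maximum(np.mean(first_bins, axis=0), _PROB_FLOOR)
        initial /= initial.sum()
        if model.k > 1:
            transitions = np.maximum(xi_total, _PROB_FLOOR)
            transitions /= transitions.sum(axis=1, keepdims=True)
        else:
            transitions = np.ones((1, 1))
        weights = np.concatenate(gammas, axis=0)
        if mode == "dependent":
            r, mu_p = shared_r_fit(
                [(stacked, weights[:, s]) for s in range(model.k)]
            )
            emissions = [NMParams(mu=mu, r=r, p=p) for mu, p in mu_p]
        else:
            emissions = [
                nm_fit_weighted(stacked, weights[:, s]) for s in range(model.k)
            ]
        model = replace(
            model, initial=initial, transitions=transitions, emissions=emissions
        )
    return model.sorted_by_coverage(), trace


def _posterior_for(counts: CountMatrix, model: HMMModel) -> Posterior:
    gamma, ll = {}, {}
    for chrom in counts.scheme.chrom_names:
        g, _, l = forward_backward(counts.counts[chrom], model)
        gamma[chrom] = g
        ll[chrom] = l
    return Posterior(gamma=gamma, log_likelihood=ll)


def posterior_decode(counts: CountMatrix, model: HMMModel) -> Segmentation:
    """Assign each bin its maximum-posterior state (ties -> lowest index)."""
    post = _posterior_for(counts, model)
    labels = {c: np.argmax(g, axis=1) for c, g in post.gamma.items()}
    return Segmentation(scheme=counts.scheme, k=model.k, labels=labels, posterior=post)


def viterbi(counts: CountMatrix, model: HMMModel) -> Segmentation:
    """Maximum-probability state path per chromosome (log-space recursion)."""
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transitions)
        log_init = np.log(model.initial)
    labels: dict[str, np.ndarray] = {}
    for chrom in counts.scheme.chrom_names:
        logb = model.emission_log_probs(counts.counts[chrom])
        T, k = logb.shape
        delta = log_init + logb[0]
        back = np.zeros((T, k), dtype=np.int64)
        for t in range(1, T):
            scores = delta[:, None] + log_a
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(k)] + logb[t]
        path = np.empty(T, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        labels[chrom] = path
    return Segmentation(scheme=counts.scheme, k=model.k, labels=labels)


def save_model(model: HMMModel, path: str) -> None:
    """Serialise a model to JSON at full double precision."""
    doc = {
        "k": model.k,
        "mode": model.mode,
        "bin_size": model.bin_size,
        "mark_names": list(model.mark_names),
        "initial": model.initial.tolist(),
        "transitions": model.transitions.tolist(),
        "emissions": [
            {"mu": e.mu, "r": e.r, "p": e.p.tolist()} for e in model.emissions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> HMMModel:
    """Load and validate a JSON model file."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("k", "mode", "bin_size", "mark_names", "initial", "transitions", "emissions"):
        if key not in doc:
            raise ValueError(f"model file missing field {key!r}")
    emissions = [
        NMParams(mu=float(e["mu"]), r=float(e["r"]), p=np.asarray(e["p"], dtype=float))
        for e in doc["emissions"]
    ]
    if len(emissions) != doc["k"]:
        raise ValueError("field 'emissions' does not match field 'k'")
    return HMMModel(
        initial=np.asarray(doc["initial"], dtype=float),
        transitions=np.asarray(doc["transitions"], dtype=float),
        emissions=emissions,
        mode=doc["mode"],
        mark_names=tuple(doc["mark_names"]),
        bin_size=int(doc["bin_size"]),
    )
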