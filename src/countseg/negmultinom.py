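"""The negative multinomial (NM) emission distribution.

A count vector X = (X_1, ..., X_n) over n histone marks follows
NM(mu, r, p_1, ..., p_n) when the total X_+ = sum_i X_i is negative binomial
with mean mu and dispersion (size) r, and, given X_+ = x_+, the split across
marks is Multinom(x_+, p).  The log pmf is therefore

    lnGamma(r + x_+) - lnGamma(r) - ln(x_+!)
        + x_+ ln(mu / (r + mu)) + r ln(r / (r + mu))        [NB total]
    + ln(x_+!) + sum_i [x_i ln p_i - ln(x_i!)]              [multinomial split]

Marginals are overdispersed (Var X_i = mu p_i + (mu p_i)^2 / r > E X_i) and
every pair of marks is positively correlated; the independent-Poisson model
is the r -> infinity limit.  Weighted maximum-likelihood fitting here is the
M-step of the segmentation EM: p and mu have closed forms, r is profiled by a
1-D bounded search on ln r.  In "dependent" mode a single r is shared by all
states (k*n + 1 emission parameters instead of k*(n + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "NMParams",
    "PARAM_FLOOR",
    "nm_log_pmf",
    "nm_log_pmf_matrix",
    "nm_sample",
    "nm_fit_weighted",
    "shared_r_fit",
]

# floor for p_i and mu after an M-step: keeps the log pmf finite when a state
# transiently owns no reads of a mark
PARAM_FLOOR = 1e-10

# profile search bounds for ln r; the upper end is the effectively-Poisson regime
_LN_R_LO = np.log(1e-3)
_LN_R_HI = np.log(1e6)
_LN_R_TOL = 1e-8


@dataclass
class NMParams:
    """One state's emission parameters: total mean mu, dispersion r, mark split p."""

    mu: float
    r: float
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be finite and > 0, got {self.mu}")
        if not (np.isfinite(self.r) and self.r > 0):
            raise ValueError(f"r must be finite and > 0, got {self.r}")
        if self.p.ndim != 1 or np.any(self.p < 0):
            raise ValueError("p must be a 1-D vector with non-negative entries")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError(f"p must sum to 1, got {self.p.sum()!r}")

    @property
    def n_marks(self) -> int:
        return self.p.size

    def mean(self) -> np.ndarray:
        """Per-mark expected counts mu * p_i."""
        return self.mu * self.p


def _nb_log_pmf_total(x_plus: np.ndarray, mu: float, r: float) -> np.ndarray:
    """Negative binomial log pmf of the total count (mean mu, size r)."""
    return (
        gammaln(r + x_plus)
        - gammaln(r)
        - gammaln(x_plus + 1)
        + x_plus * np.log(mu / (r + mu))
        + r * np.log(r / (r + mu))
    )


def nm_log_pmf_matrix(x: np.ndarray, params: NMParams) -> np.ndarray:
    """Vectorised NM log pmf for a (bins, n) matrix of count vectors."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.n_marks:
        raise ValueError(f"expected {params.n_marks} marks, got {x.shape[1]}")
    xp = x.sum(axis=1)
    out = _nb_log_pmf_total(xp, params.mu, params.r) + gammaln(xp + 1) - gammaln(x + 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(params.p)
        # x_i = 0 contributes 0 even when p_i = 0; p_i = 0 with x_i > 0 -> -inf
        out = out + np.where(x > 0, x * logp, 0.0).sum(axis=1)
    return out


def nm_log_pmf(x: np.ndarray, params: NMParams) -> float:
    """NM log pmf of a single count vector."""
    return float(nm_log_pmf_matrix(np.asarray(x)[None, :], params)[0])


def nm_sample(params: NMParams, count: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``count`` NM vectors via the NB-total / multinomial-split hierarchy."""
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if count == 0:
        return np.zeros((0, params.n_marks), dtype=np.int64)
    totals = rng.negative_binomial(params.r, params.r / (params.r + params.mu), size=count)
    return rng.multinomial(totals, params.p).astype(np.int64)


def _nb_suff_stats(counts: np.ndarray, weights: np.ndarray):
    """Collapse (total count, weight) pairs onto unique totals for the r search."""
    xp = np.asarray(counts).sum(axis=1)
    uniq, inv = np.unique(xp, return_inverse=True)
    w = np.bincount(inv, weights=weights, minlength=uniq.size)
    keep = w > 0
    return uniq[keep].astype(float), w[keep]


def _weighted_nb_profile(r: float, stats: list[tuple[np.ndarray, np.ndarray, float]]) -> float:
    """Sum over states of the weighted NB log-likelihood of the totals at fixed mu."""
    total = 0.0
    for uniq, w, mu in stats:
        total += float(
            np.dot(
                w,
                gammaln(r + uniq)
                - gammaln(r)
                + uniq * np.log(mu / (r + mu))
                + r * np.log(r / (r + mu)),
            )
        )
    return total


def _optimize_r(stats: list[tuple[np.ndarray, np.ndarray, float]]) -> float:
    res = minimize_scalar(
        lambda lnr: -_weighted_nb_profile(np.exp(lnr), stats),
        bounds=(_LN_R_LO, _LN_R_HI),
        method="bounded",
        options={"xatol": _LN_R_TOL},
    )
    return float(np.exp(res.x))


def _closed_form_mu_p(counts: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    wsum = float(weights.sum())
    per_mark = weights @ counts  # sum_b w_b x_{b,i}
    total = float(per_mark.sum())
    mu = max(total / wsum, PARAM_FLOOR)
    if total > 0:
        p = per_mark / total
    else:
        p = np.full(counts.shape[1], 1.0 / counts.shape[1])
    p = np.maximum(p, PARAM_FLOOR)
    p = p / p.sum()
    return mu, p


def nm_fit_weighted(
    counts: np.ndarray, weights: np.ndarray, r_fixed: float | None = None
) -> NMParams:
    """Weighted maximum-likelihood NM fit.

    p_i and mu are the weighted closed forms; r maximises the weighted NB
    log-likelihood of the totals unless ``r_fixed`` is given.
    """
    counts = np.asarray(counts)
    weights = np.asarray(weights, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a (bins, marks) matrix")
    if weights.shape != (counts.shape[0],) or np.any(weights < 0):
        raise ValueError("weights must be non-negative, one per bin")
    if not np.any(weights > 0):
        raise ValueError("all weights are zero")
    mu, p = _closed_form_mu_p(counts, weights)
    if r_fixed is not None:
        return NMParams(mu=mu, r=float(r_fixed), p=p)
    uniq, w = _nb_suff_stats(counts, weights)
    r = _optimize_r([(uniq, w, mu)])
    return NMParams(mu=mu, r=r, p=p)


def shared_r_fit(
    per_state: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, list[tuple[float, np.ndarray]]]:
    """Fit one dispersion r shared across states ("dependent" mode M-step).

    ``per_state`` holds (counts, weights) per state; each state's mu and p stay
    at their closed-form weighted values while r maximises the pooled weighted
    NB log-likelihood of the totals.  Returns (r, [(mu, p), ...]).  States with
    zero total weight contribute nothing to the r fit.
    """
    stats = []
    mu_p: list[tuple[float, np.ndarray]] = []
    for counts, weights in per_state:
        counts = np.asarray(counts)
        weights = np.asarray(weights, dtype=float)
        if np.any(weights > 0):
            mu, p = _closed_form_mu_p(counts, weights)
            uniq, w = _nb_suff_stats(counts, weights)
            stats.append((uniq, w, mu))
        else:
            mu, p = PARAM_FLOOR, np.full(counts.shape[1], 1.0 / counts.shape[1])
        mu_p.append((mu, p))
    if not stats:
        raise ValueError("all states have zero total weight")
    return _optimize_r(stats), mu_p
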