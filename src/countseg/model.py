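"""Model / Results surface over the segmentation machinery.

``ChromatinHMM`` holds the data (a bins x marks count matrix per chromosome)
and the model configuration; ``fit`` runs initialisation plus Baum-Welch and
returns a ``ChromatinHMMResults`` carrying the fitted parameters, the
log-likelihood trace, decoders, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .binning import CountMatrix, read_count_matrix
from .hmm import (
    HMMModel,
    Posterior,
    Segmentation,
    baum_welch,
    posterior_decode,
    save_model,
    viterbi,
)
from .validation import posterior_entropy_profile

__all__ = ["ChromatinHMM", "ChromatinHMMResults"]


class ChromatinHMM:
    """A k-state negative-multinomial HMM over binned read counts.

    Parameters
    ----------
    counts
        Per-chromosome bins x marks integer matrices (each chromosome is one
        observation sequence).
    n_states
        Number of chromatin states k.
    mode
        "dependent" for a single dispersion r shared by all states (the
        default, k*n + 1 emission parameters) or "independent" for one r per
        state (k*(n + 1)).
    """

    def __init__(self, counts: CountMatrix, n_states: int, mode: str = "dependent"):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        if mode not in ("dependent", "independent"):
            raise ValueError(f"unknown mode {mode!r}")
        self.counts = counts
        self.n_states = int(n_states)
        self.mode = mode

    @classmethod
    def from_tsv(cls, path: str, n_states: int, mode: str = "dependent") -> "ChromatinHMM":
        """Build a model from a count-matrix TSV (chrom, start, end, marks...)."""
        return cls(read_count_matrix(path), n_states, mode=mode)

    def fit(
        self,
        max_iter: int = 200,
        tol: float = 1e-6,
        seed: int = 0,
        initial_model: HMMModel | None = None,
    ) -> "ChromatinHMMResults":
        """Run Baum-Welch EM and return the fitted results."""
        model, trace = baum_welch(
            self.counts,
            self.n_states,
            mode=self.mode,
            max_iter=max_iter,
            tol=tol,
            seed=seed,
            initial_model=initial_model,
        )
        return ChromatinHMMResults(self, model, trace)


class ChromatinHMMResults:
    """Fitted segmentation model: parameters, likelihood trace, decoders."""

    def __init__(self, spec: ChromatinHMM, model: HMMModel, loglik_trace: list[float]):
        self.model_spec = spec
        self.model = model
        self.loglik_trace = list(loglik_trace)
        self._posterior_seg: Segmentation | None = None

    @property
    def llf(self) -> float:
        """Final training log-likelihood."""
        return self.loglik_trace[-1]

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    @property
    def counts(self) -> CountMatrix:
        return self.model_spec.counts

    def decode(self, method: str = "posterior") -> Segmentation:
        """Segment the training data ("posterior", the default, or "viterbi")."""
        if method == "posterior":
            if self._posterior_seg is None:
                self._posterior_seg = posterior_decode(self.counts, self.model)
            return self._posterior_seg
        if method == "viterbi":
            return viterbi(self.counts, self.model)
        raise ValueError(f"unknown decoding method {method!r}")

    @property
    def posterior(self) -> Posterior:
        return self.decode("posterior").posterior

    def entropy_profile(self, min_group: int = 500):
        """Posterior entropies and the mean-entropy-vs-coverage curve."""
        return posterior_entropy_profile(self.posterior, self.counts, min_group=min_group)

    def params_frame(self) -> pd.DataFrame:
        """Per-state table: mu, r, mark split p, self-transition, frequency."""
        seg = self.decode("posterior")
        freq = np.bincount(seg.stacked(), minlength=self.model.k) / seg.stacked().size
        marks = self.model.mark_names or tuple(
            f"mark_{i}" for i in range(self.model.n_marks)
        )
        rows = []
        for s, e in enumerate(self.model.emissions):
            row = {"state": s, "mu": e.mu, "r": e.r}
            row.update({f"p[{m}]": p for m, p in zip(marks, e.p)})
            row["self_transition"] = float(self.model.transitions[s, s])
            row["frequency"] = float(freq[s])
            rows.append(row)
        return pd.DataFrame(rows).set_index("state")

    def summary(self) -> str:
        """Readable fit report: configuration, likelihood, per-state table."""
        buf = io.StringIO()
        m = self.model
        buf.write("Negative-multinomial HMM segmentation\n")
        buf.write("=" * 54 + "\n")
        buf.write(f"states:            {m.k}\n")
        buf.write(f"marks:             {m.n_marks} {list(m.mark_names)}\n")
        buf.write(f"dispersion mode:   {m.mode} ({m.n_emission_params()} emission parameters)\n")
        buf.write(f"bin size:          {m.bin_size} bp\n")
        buf.write(f"EM iterations:     {self.n_iter}\n")
        buf.write(f"log-likelihood:    {self.llf:.3f}\n\n")
        with pd.option_context("display.width", 120, "display.float_format", "{:.4f}".format):
            buf.write(self.params_frame().to_string())
        buf.write("\n")
        return buf.getvalue()

    def save(self, path: str) -> None:
        """Write the fitted model to a JSON file."""
        save_model(self.model, path)
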