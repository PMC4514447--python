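"""Genome-wide summaries of a segmentation.

State frequencies and cross-segmentation overlap, transcript-anchored state
occupancy profiles (flanks at base-pair resolution, transcript bodies
rescaled to a common reference length), and log-mean mark heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .binning import CountMatrix
from .hmm import Segmentation

__all__ = [
    "StateProfile",
    "state_frequencies",
    "state_overlap",
    "transcript_profile",
    "mean_marks",
    "plot_state_frequencies",
    "plot_transcript_profile",
    "plot_mean_marks",
]

logger = logging.getLogger(__name__)


def state_frequencies(seg: Segmentation) -> pd.DataFrame:
    """Bin counts and genome fractions per state."""
    labels = seg.stacked()
    counts = np.bincount(labels, minlength=seg.k)
    return pd.DataFrame(
        {"state": np.arange(seg.k), "bins": counts, "fraction": counts / labels.size}
    )


def state_overlap(seg_a: Segmentation, seg_b: Segmentation) -> np.ndarray:
    """kA x kB matrix of bins jointly labelled (a, b) by the two segmentations."""
    if seg_a.scheme != seg_b.scheme:
        raise ValueError("segmentations must share one binning scheme")
    a, b = seg_a.stacked(), seg_b.stacked()
    flat = np.bincount(a * seg_b.k + b, minlength=seg_a.k * seg_b.k)
    return flat.reshape(seg_a.k, seg_b.k)


@dataclass
class StateProfile:
    """State occurrence counts on the transcript-anchored reference grid.

    The grid runs over ``flank`` upstream base pairs, ``body_units`` rescaled
    body positions, and ``flank`` downstream base pairs; minus-strand
    transcripts are flipped so upstream is always on the left.  Row ``g`` of
    ``counts`` tallies, per state, how many transcripts are annotated with
    that state at grid position ``g``.
    """

    flank: int
    body_units: int
    counts: np.ndarray = field(repr=False)
    n_transcripts: int = 0

    @property
    def grid_size(self) -> int:
        return 2 * self.flank + self.body_units

    def relative_positions(self) -> np.ndarray:
        """Grid labels: -flank..-1, body 0..body_units-1, body_units..+flank."""
        return np.arange(self.grid_size) - self.flank

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=[f"state_{s}" for s in range(self.counts.shape[1])]
        )
        df.insert(0, "grid_position", self.relative_positions())
        return df


def transcript_profile(
    seg: Segmentation,
    transcripts: pd.DataFrame,
    flank: int = 5000,
    body_units: int = 1000,
) -> StateProfile:
    """Count state occurrences around transcripts on a common reference grid.

    ``transcripts`` needs columns chrom, start, end, strand (0-based,
    half-open).  Each transcript contributes one tally per covered grid
    position: flanks are read base pair by base pair; the TSS-TES body is
    mapped onto ``body_units`` reference positions by proportional
    nearest-index (floor) rescaling.  Positions truncated by chromosome edges
    are skipped; transcripts on chromosomes absent from the segmentation are
    skipped with a warning.
    """
    if len(transcripts) == 0:
        raise ValueError("no transcripts given")
    if flank < 0 or body_units < 1:
        raise ValueError("need flank >= 0 and body_units >= 1")
    grid = 2 * flank + body_units
    counts = np.zeros((grid, seg.k), dtype=np.int64)
    used = 0
    grid_idx_template = np.arange(grid)
    for row in transcripts.itertuples(index=False):
        chrom = row.chrom
        if chrom not in seg.labels:
            logger.warning("transcript on unknown chromosome %r skipped", chrom)
            continue
        start, end, strand = int(row.start), int(row.end), row.strand
        if end - start < 1:
            raise ValueError("transcript with empty body")
        body_len = end - start
        if strand == "-":
            tss, tes = end - 1, start
            sign = -1
        else:
            tss, tes = start, end - 1
            sign = 1
        up = tss - sign * np.arange(flank, 0, -1)
        body = tss + sign * ((np.arange(body_units) * body_len) // body_units)
        down = tes + sign * np.arange(1, flank + 1)
        pos = np.concatenate([up, body, down])
        length = seg.scheme.chrom_length(chrom)
        valid = (pos >= 0) & (pos < length)
        states = seg.labels[chrom][seg.scheme.bin_index(pos[valid])]
        np.add.at(counts, (grid_idx_template[valid], states), 1)
        used += 1
    if used == 0:
        raise ValueError("no transcript overlapped the segmented genome")
    return StateProfile(flank=flank, body_units=body_units, counts=counts, n_transcripts=used)


def mean_marks(counts: CountMatrix, seg: Segmentation) -> pd.DataFrame:
    """k x n matrix of ln(1 + mean count) per state and mark."""
    if counts.scheme != seg.scheme:
        raise ValueError("counts and segmentation must share one binning scheme")
    labels = seg.stacked()
    data = counts.stacked()
    out = np.zeros((seg.k, counts.n_marks))
    for s in range(seg.k):
        mask = labels == s
        if not mask.any():
            logger.warning("state %d labels no bin; mean set to 0", s)
            continue
        out[s] = np.log1p(data[mask].mean(axis=0))
    return pd.DataFrame(out, columns=list(counts.mark_names)).rename_axis("state")


def _agg_flank(profile: StateProfile, step: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-bp flank rows into ``step``-bp plot bins (body kept as is)."""
    f, L = profile.flank, profile.body_units
    frac = profile.counts / max(profile.n_transcripts, 1)
    up = frac[:f].reshape(-1, step, profile.counts.shape[1]).mean(axis=1) if f else frac[:0]
    down = frac[f + L :].reshape(-1, step, profile.counts.shape[1]).mean(axis=1) if f else frac[:0]
    body = frac[f : f + L]
    xs = np.concatenate(
        [
            np.arange(-f, 0, step) + step / 2,
            np.arange(L),
            L + np.arange(0, f, step) + step / 2,
        ]
        if f
        else [np.arange(L)]
    )
    return xs, np.concatenate([up, body, down], axis=0)


def plot_state_frequencies(seg: Segmentation, ax=None):
    """Bar plot of the genome fraction occupied by each state."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    freq = state_frequencies(seg)
    ax.bar(freq["state"], freq["fraction"])
    ax.set_xlabel("state")
    ax.set_ylabel("genome fraction")
    return ax


def plot_transcript_profile(profile: StateProfile, step: int = 10, ax=None):
    """Stacked occupancy around the average transcript (flanks in 10 bp bins)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    xs, frac = _agg_flank(profile, step=step)
    ax.stackplot(xs, frac.T, labels=[f"state {s}" for s in range(frac.shape[1])])
    ax.set_xlabel("position (bp upstream | body units | bp downstream)")
    ax.set_ylabel("fraction of transcripts")
    ax.legend(fontsize="small")
    return ax


def plot_mean_marks(table: pd.DataFrame, ax=None):
    """Heatmap of ln(1 + mean count) per state (rows) and mark (columns)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), [f"state {s}" for s in table.index])
    plt.colorbar(im, ax=ax, label="ln(1 + mean count)")
    return ax
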