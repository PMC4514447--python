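"""Synthetic data: count matrices and read sets drawn from a known NM-HMM.

This is the generative counterpart of the segmentation model — hidden states
follow the Markov chain, each bin's count vector is drawn from that state's
negative multinomial — so the whole stack (binning, training, decoding,
validation) can be exercised end to end with known ground truth.  Optional
"gap" intervals force zero counts over contiguous bin ranges, mimicking
assembly gaps where no reads can be mapped; their truth label is the
lowest-coverage state, which is what a segmentation should assign there.

``simulate_reads`` inverts read counting: it turns each counted unit into an
aligned read whose shifted 5' position falls back into the originating bin,
so counting the simulated reads reproduces the input matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinningScheme, CountMatrix, count_positions, make_bins
from .hmm import HMMModel, Segmentation
from .negmultinom import NMParams

__all__ = [
    "SimulationSpec",
    "simulate",
    "simulate_replicates",
    "simulate_read_positions",
    "simulate_reads_bam",
    "make_default_fixture",
    "DEFAULT_MARKS",
]

DEFAULT_MARKS = ("H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3")


@dataclass
class SimulationSpec:
    """Ground-truth model plus genome geometry for a simulation run."""

    model: HMMModel
    chrom_bins: dict[str, int]
    seed: int = 0
    # per-chromosome (start_bin, end_bin) half-open ranges forced to zero counts
    gap_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, nb in self.chrom_bins.items():
            if nb < 1:
                raise ValueError(f"chromosome {chrom!r} needs >= 1 bins")
        for chrom, ivs in self.gap_intervals.items():
            nb = self.chrom_bins[chrom]
            for a, b in ivs:
                if not (0 <= a < b <= nb):
                    raise ValueError(f"gap interval ({a}, {b}) outside {chrom!r}")

    def scheme(self) -> BinningScheme:
        bs = self.model.bin_size
        return make_bins({c: nb * bs for c, nb in self.chrom_bins.items()}, bin_size=bs)


def _sample_states(model: HMMModel, length: int, rng: np.random.Generator) -> np.ndarray:
    states = np.empty(length, dtype=np.int64)
    # inverse-CDF draws keep the path reproducible for a fixed generator state
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transitions, axis=1)
    u = rng.random(length)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, length):
        states[t] = np.searchsorted(cum_trans[states[t - 1]], u[t], side="right")
    return np.minimum(states, model.k - 1)


def _sample_counts(
    params: NMParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.zeros((0, params.n_marks), dtype=np.int64)
    totals = rng.negative_binomial(params.r, params.r / (params.r + params.mu), size=n)
    return rng.multinomial(totals, params.p).astype(np.int64)


def simulate(spec: SimulationSpec) -> tuple[CountMatrix, Segmentation]:
    """Draw (counts, true segmentation) from the spec's model.

    Gap intervals overwrite counts with zeros and truth labels with the
    lowest-mu state.  Reproducible for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme()
    model = spec.model
    gap_state = int(np.argmin([e.mu for e in model.emissions]))
    counts: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for chrom in scheme.chrom_names:
        nb = spec.chrom_bins[chrom]
        states = _sample_states(model, nb, rng)
        mat = np.zeros((nb, model.n_marks), dtype=np.int64)
        for s in range(model.k):
            idx = np.flatnonzero(states == s)
            mat[idx] = _sample_counts(model.emissions[s], idx.size, rng)
        for a, b in spec.gap_intervals.get(chrom, []):
            mat[a:b] = 0
            states[a:b] = gap_state
        counts[chrom] = mat
        labels[chrom] = states
    cm = CountMatrix(scheme=scheme, mark_names=model.mark_names or DEFAULT_MARKS[: model.n_marks], counts=counts)
    seg = Segmentation(scheme=scheme, k=model.k, labels=labels)
    return cm, seg


def simulate_replicates(
    spec: SimulationSpec, n_replicates: int = 2
) -> tuple[Segmentation, list[CountMatrix]]:
    """One hidden state path, several independent emission draws.

    Emulates replicate experiments of the same underlying chromatin: the
    truth segmentation is shared, only the count noise differs.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme()
    model = spec.model
    gap_state = int(np.argmin([e.mu for e in model.emissions]))
    states = {c: _sample_states(model, nb, rng) for c, nb in spec.chrom_bins.items()}
    for chrom, ivs in spec.gap_intervals.items():
        for a, b in ivs:
            states[chrom][a:b] = gap_state
    reps: list[CountMatrix] = []
    marks = model.mark_names or DEFAULT_MARKS[: model.n_marks]
    for _ in range(n_replicates):
        counts: dict[str, np.ndarray] = {}
        for chrom in scheme.chrom_names:
            st = states[chrom]
            mat = np.zeros((st.size, model.n_marks), dtype=np.int64)
            for s in range(model.k):
                idx = np.flatnonzero(st == s)
                mat[idx] = _sample_counts(model.emissions[s], idx.size, rng)
            for a, b in spec.gap_intervals.get(chrom, []):
                mat[a:b] = 0
            counts[chrom] = mat
        reps.append(CountMatrix(scheme=scheme, mark_names=marks, counts=counts))
    truth = Segmentation(scheme=scheme, k=model.k, labels=states)
    return truth, reps


def simulate_read_positions(
    counts: CountMatrix, rng: np.random.Generator | int
) -> dict[str, dict[str, np.ndarray]]:
    """Turn each counted unit into a uniform base-pair position inside its bin.

    Returns ``positions[mark][chrom]``, compatible with
    :func:`countseg.binning.count_positions`; re-binning under the original
    scheme reproduces ``counts`` exactly, and re-binning under an
    offset-shifted scheme yields the shifted count matrix of the same reads.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: dict[str, dict[str, np.ndarray]] = {m: {} for m in counts.mark_names}
    for chrom in counts.scheme.chrom_names:
        starts, ends = counts.scheme.bin_edges(chrom)
        mat = counts.counts[chrom]
        for j, mark in enumerate(counts.mark_names):
            reps = mat[:, j]
            lo = np.repeat(starts, reps)
            width = np.repeat(ends - starts, reps)
            out[mark][chrom] = lo + rng.integers(0, width, size=lo.size)
    return out


def simulate_reads_bam(
    counts: CountMatrix,
    path: str,
    fragment_length: int = 150,
    read_length: int = 36,
    rng: np.random.Generator | int = 0,
    force_strand: str | None = None,
) -> dict[str, str]:
    """Write one sorted, indexed BAM per mark whose counts round-trip.

    Each counted unit becomes a read on a random (or forced) strand whose
    5' position shifted by ``fragment_length // 2`` lands at a uniform target
    inside the originating bin; near chromosome edges the target is moved to
    the nearest position for which a valid alignment exists.  Returns
    mark -> BAM path.
    """
    import os

    import pysam

    if not (1 <= read_length <= fragment_length):
        raise ValueError("need fragment_length >= read_length >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shift = fragment_length // 2
    scheme = counts.scheme
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": int(scheme.chrom_length(c))} for c in scheme.chrom_names
        ],
    }
    targets = simulate_read_positions(counts, rng)
    paths: dict[str, str] = {}
    for mark in counts.mark_names:
        records = []
        for chrom_id, chrom in enumerate(scheme.chrom_names):
            length = scheme.chrom_length(chrom)
            starts, ends = scheme.bin_edges(chrom)
            for t in targets[mark][chrom]:
                t = int(t)
                b = scheme.bin_index(t)
                lo, hi = int(starts[b]), int(ends[b])
                if force_strand is not None:
                    want_rev = force_strand == "-"
                else:
                    want_rev = bool(rng.integers(0, 2))
                # feasible shifted-target range per strand: the 5' coordinate
                # and the full alignment must fit inside the chromosome while
                # the shifted position stays inside the originating bin
                placed = False
                for reverse in (want_rev, not want_rev):
                    if reverse:
                        tlo = max(lo, read_length - 1 - shift)
                        thi = min(hi - 1, length - 1 - shift)
                    else:
                        tlo = max(lo, shift)
                        thi = min(hi - 1, length - read_length + shift)
                    if tlo <= thi:
                        t2 = min(max(t, tlo), thi)
                        five = t2 + shift if reverse else t2 - shift
                        placed = True
                        break
                if not placed:
                    # bin unreachable under either strand: nearest valid read
                    reverse = False
                    five = min(max(t - shift, 0), length - read_length)
                a = pysam.AlignedSegment()
                a.query_name = f"{mark}_{chrom}_{len(records)}"
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.cigarstring = f"{read_length}M"
                a.reference_id = chrom_id
                a.mapping_quality = 60
                a.flag = 16 if reverse else 0
                if reverse:
                    a.reference_start = five - read_length + 1
                else:
                    a.reference_start = five
                records.append(a)
        bam_path = os.path.join(path, f"{mark}.bam")
        unsorted = bam_path + ".unsorted"
        with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
            for a in records:
                bam.write(a)
        pysam.sort("-o", bam_path, unsorted)
        os.remove(unsorted)
        pysam.index(bam_path)
        paths[mark] = bam_path
    return paths


def make_default_fixture(seed: int = 0) -> SimulationSpec:
    """The standard 3-state / 4-mark benchmark model.

    States (dependent mode, shared r = 5, 0.98 diagonal transitions, two
    chromosomes of 10,000 bins of 200 bp):

    * gap-like: mu = 0.5, near-uniform split — regions with almost no reads;
    * background: mu = 20, mild enrichment of the repressive mark;
    * promoter-like: mu = 400, split concentrated on two active marks.
    """
    p_gap = np.array([0.25, 0.25, 0.25, 0.25])
    p_bg = np.array([0.15, 0.15, 0.30, 0.40])
    p_prom = np.array([0.45, 0.40, 0.10, 0.05])
    emissions = [
        NMParams(mu=0.5, r=5.0, p=p_gap),
        NMParams(mu=20.0, r=5.0, p=p_bg),
        NMParams(mu=400.0, r=5.0, p=p_prom),
    ]
    k = 3
    transitions = np.full((k, k), 0.01)
    np.fill_diagonal(transitions, 0.98)
    model = HMMModel(
        initial=np.full(k, 1.0 / k),
        transitions=transitions,
        emissions=emissions,
        mode="dependent",
        mark_names=DEFAULT_MARKS,
        bin_size=200,
    ).sorted_by_coverage()
    return SimulationSpec(
        model=model, chrom_bins={"chr1": 10_000, "chr2": 10_000}, seed=seed
    )
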