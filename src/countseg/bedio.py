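"""BED-format input/output (0-based, half-open coordinates).

Segmentations are written as BED9 with consecutive same-state bins merged
into single records and one colour per state; transcripts are read from BED6
(or minimal GTF "transcript" lines) for the transcript-anchored reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import BinningScheme
from .hmm import Segmentation

__all__ = [
    "state_palette",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "read_transcripts_bed",
    "read_transcripts_gtf",
    "write_mask_bed",
    "read_mask_bed",
]


def state_palette(k: int) -> list[str]:
    """Deterministic "r,g,b" colour strings, one per state."""
    import matplotlib

    cmap = matplotlib.colormaps["tab20"]
    return [
        ",".join(str(int(round(255 * v))) for v in cmap(i % 20)[:3]) for i in range(k)
    ]


def write_segmentation_bed(seg: Segmentation, path: str, palette: list[str] | None = None) -> None:
    """Write BED9 records, run-length merging consecutive same-state bins."""
    palette = palette or state_palette(seg.k)
    with open(path, "w") as fh:
        for chrom in seg.scheme.chrom_names:
            starts, ends = seg.scheme.bin_edges(chrom)
            labels = seg.labels[chrom]
            change = np.flatnonzero(np.diff(labels)) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [labels.size]])
            for a, b in zip(run_starts, run_ends):
                s = int(labels[a])
                fh.write(
                    f"{chrom}\t{starts[a]}\t{ends[b - 1]}\tstate_{s}\t0\t.\t"
                    f"{starts[a]}\t{ends[b - 1]}\t{palette[s]}\n"
                )


def read_segmentation_bed(path: str, scheme: BinningScheme, k: int | None = None) -> Segmentation:
    """Read a segmentation BED back onto a binning scheme."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"]
    )
    states = df["name"].str.removeprefix("state_").astype(int)
    if k is None:
        k = int(states.max()) + 1
    labels = {
        c: np.zeros(scheme.n_bins(c), dtype=np.int64) for c in scheme.chrom_names
    }
    for chrom, start, end, state in zip(df["chrom"], df["start"], df["end"], states):
        if chrom not in labels:
            raise ValueError(f"BED chromosome {chrom!r} absent from the scheme")
        b0 = scheme.bin_index(int(start))
        b1 = scheme.bin_index(int(end) - 1)
        labels[chrom][b0 : b1 + 1] = state
    return Segmentation(scheme=scheme, k=k, labels=labels)


def read_transcripts_bed(path: str) -> pd.DataFrame:
    """Read transcripts from BED6 into (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3, 4, 5],
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if not set(df["strand"]) <= {"+", "-"}:
        raise ValueError("transcript strands must be '+' or '-'")
    if (df["end"] - df["start"] < 1).any():
        raise ValueError("transcript with non-positive length")
    return df


def read_transcripts_gtf(path: str) -> pd.DataFrame:
    """Read "transcript" features from a minimal GTF (1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7 or f[2] != "transcript":
                continue
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "name": f[8] if len(f) > 8 else ".",
                    "score": 0,
                    "strand": f[6],
                }
            )
    if not rows:
        raise ValueError("no transcript features found")
    return pd.DataFrame(rows)


def write_mask_bed(mask: dict[str, np.ndarray], scheme: BinningScheme, path: str) -> None:
    """Write the True bins of a per-bin boolean mask as merged BED3 records."""
    with open(path, "w") as fh:
        for chrom in scheme.chrom_names:
            starts, ends = scheme.bin_edges(chrom)
            m = np.asarray(mask[chrom], dtype=bool)
            change = np.flatnonzero(np.diff(m.astype(int))) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [m.size]])
            for a, b in zip(run_starts, run_ends):
                if m[a]:
                    fh.write(f"{chrom}\t{starts[a]}\t{ends[b - 1]}\n")


def read_mask_bed(path: str, scheme: BinningScheme) -> dict[str, np.ndarray]:
    """Read BED intervals into a per-bin boolean mask (bin True if overlapped)."""
    mask = {c: np.zeros(scheme.n_bins(c), dtype=bool) for c in scheme.chrom_names}
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom not in mask:
            continue
        b0 = scheme.bin_index(int(start))
        b1 = scheme.bin_index(int(end) - 1)
        mask[chrom][b0 : b1 + 1] = True
    return mask
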