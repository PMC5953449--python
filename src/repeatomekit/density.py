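"""Windowed repeat density along chromosomes, in bp per megabase.

Each chromosome is tiled with fixed windows (default 1 Mb); every repeat
interval is clipped to the windows it overlaps and the clipped bp are
accumulated. The final partial window is normalized by its actual length so
values stay in bp/Mb rather than showing a spurious edge dip. Exports are a
heatmap-ready TSV matrix and bedGraph tracks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GenomeIndex, RepeatHit

__all__ = ["DensityTrack", "window_density", "density_matrix", "write_bedgraph"]


@dataclass
class DensityTrack:
    """Per-window repeat density (bp/Mb) on one sequence."""

    sequence: str
    window_size: int
    seq_length: int
    values: np.ndarray

    def window_span(self, index: int) -> tuple[int, int]:
        """Genomic [start, end) of a window; the last may be partial."""
        start = index * self.window_size
        return start, min(start + self.window_size, self.seq_length)


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def window_density(
    hits: Iterable[RepeatHit],
    genome: GenomeIndex,
    category: str | None = None,
    window_size: int = 1_000_000,
    overlap_mode: str = "raw",
) -> list[DensityTrack]:
    """Density tracks for every sequence in the genome.

    ``category`` filters hits by repeat class, class prefix, or repeat name
    (``None`` keeps all). ``overlap_mode="merged"`` unions intervals per
    sequence before counting, capping densities at 1e6 bp/Mb; ``"raw"``
    counts annotated bp as-is (overlaps can exceed that cap). A hit on a
    sequence absent from the genome index is an error.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if overlap_mode not in ("raw", "merged"):
        raise ValueError(f"overlap_mode must be 'raw' or 'merged', got {overlap_mode!r}")

    def keep(hit: RepeatHit) -> bool:
        if category is None:
            return True
        return category in (
            hit.repeat_class,
            hit.repeat_class.split("/", 1)[0],
            hit.repeat_name,
        )

    per_seq: dict[str, list[tuple[int, int]]] = {name: [] for name in genome.names}
    for hit in hits:
        if not keep(hit):
            continue
        if hit.query not in per_seq:
            raise ValueError(f"hit on sequence {hit.query!r} absent from the genome index")
        per_seq[hit.query].append((hit.qstart, min(hit.qend, genome.length(hit.query))))

    tracks: list[DensityTrack] = []
    for name in genome.names:
        length = genome.length(name)
        n_windows = max(1, -(-length // window_size))
        bp = np.zeros(n_windows)
        intervals = per_seq[name]
        if overlap_mode == "merged":
            intervals = _union(intervals)
        for start, end in intervals:
            first = start // window_size
            last = (end - 1) // window_size
            for w in range(first, last + 1):
                w_start = w * window_size
                w_end = min(w_start + window_size, length)
                bp[w] += max(0, min(end, w_end) - max(start, w_start))
        spans = np.minimum(
            window_size, length - np.arange(n_windows) * window_size
        ).astype(float)
        tracks.append(
            DensityTrack(
                sequence=name,
                window_size=window_size,
                seq_length=length,
                values=bp / (spans / 1e6),
            )
        )
    return tracks


def density_matrix(tracks: Sequence[DensityTrack]) -> str:
    """TSV matrix: one row per sequence (natural-sorted), one column per
    window index; ragged rows padded with ``NA``."""
    header_cols = ["sequence"]
    if tracks:
        sizes = {t.window_size for t in tracks}
        if len(sizes) > 1:
            raise ValueError("tracks have mixed window sizes")
        n = max(len(t.values) for t in tracks)
        header_cols += [f"w{i}" for i in range(n)]
    lines = ["\t".join(header_cols)]
    for track in sorted(tracks, key=lambda t: _natural_key(t.sequence)):
        row = [track.sequence]
        row += [f"{v:g}" for v in track.values]
        row += ["NA"] * (len(header_cols) - 1 - len(track.values))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def write_bedgraph(track: DensityTrack) -> str:
    """bedGraph text for one track: 0-based half-open window intervals with
    their bp/Mb value; the final interval ends at the sequence length."""
    lines = []
    for i, value in enumerate(track.values):
        start, end = track.window_span(i)
        lines.append(f"{track.sequence}\t{start}\t{end}\t{value:g}")
    return "\n".join(lines) + "\n"
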