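"""Jukes-Cantor divergence correction and divergence landscapes.

The observed divergence D of a repeat copy (percent of sites differing from
the family consensus) underestimates the true number of substitutions per
site because of multiple hits. The one-parameter Jukes-Cantor correction on
the percent scale is

    K = -(300/4) * ln(1 - 4 D / 300) = -75 * ln(1 - D/75),

which is defined for D in [0, 75) (the saturation bound: with four equally
likely bases, at most 3/4 of sites can differ in expectation). K stays on
the same percent-like scale as D.

A divergence landscape bins repeat bp by divergence and expresses each bin
as a percentage of the genome — a proxy for the element family's activity
history (mass at low divergence = recent copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GenomeIndex, RepeatHit, JC_SATURATION_BOUND

__all__ = [
    "DivergenceLandscape",
    "WeightedK",
    "jc_distance",
    "jc_inverse",
    "weighted_mean_K",
    "divergence_histogram",
    "landscape_table",
]


@dataclass
class DivergenceLandscape:
    """Binned divergence histogram for one family (or the whole repeatome).

    ``bin_edges`` has one more entry than ``bin_values``; bins are
    left-closed right-open. Values are percent of genome (bp in bin /
    genome bp x 100), so the landscape's total mass equals the family's
    percent of the genome.
    """

    family: str
    bin_edges: np.ndarray
    bin_values: np.ndarray

    @property
    def total_pct_genome(self) -> float:
        return float(self.bin_values.sum())


@dataclass
class WeightedK:
    """Length-weighted mean Jukes-Cantor distance of a set of elements.

    Each element's K is weighted by its length in bp:
    mean_K = sum(K_i * L_i) / sum(L_i). Percent scale, like D.
    """

    family: str
    mean_K: float
    total_length: int
    n_elements: int


def _check_domain(d: np.ndarray) -> None:
    if np.any(d < 0) or np.any(d >= JC_SATURATION_BOUND):
        raise ValueError(
            f"divergence must lie in [0, {JC_SATURATION_BOUND}) — the Jukes-Cantor "
            f"transform saturates at {JC_SATURATION_BOUND}% observed divergence"
        )


def jc_distance(d):
    """Jukes-Cantor corrected distance K (percent scale) for observed D.

    Accepts a scalar or array; K = -75 ln(1 - D/75), strictly increasing,
    convex, and >= D on the domain [0, 75).
    """
    arr = np.asarray(d, dtype=float)
    _check_domain(arr)
    k = -75.0 * np.log1p(-arr / 75.0)
    return float(k) if np.isscalar(d) or arr.ndim == 0 else k


def jc_inverse(k):
    """Observed divergence D for a given Jukes-Cantor distance K (percent scale).

    D = 75 (1 - exp(-K/75)); inverse of :func:`jc_distance`, approaching the
    75% saturation asymptote as K grows.
    """
    arr = np.asarray(k, dtype=float)
    if np.any(arr < 0):
        raise ValueError("K must be non-negative")
    d = 75.0 * -np.expm1(-arr / 75.0)
    return float(d) if np.isscalar(k) or arr.ndim == 0 else d


def weighted_mean_K(
    elements: Iterable[tuple[float, int]], family: str = ""
) -> WeightedK:
    """Length-weighted mean K over ``(divergence, length)`` pairs.

    Each element's observed divergence is JC-corrected, multiplied by the
    element's length, summed, and divided by the total length.
    """
    pairs = list(elements)
    if not pairs:
        raise ValueError("cannot average an empty element list")
    d = np.array([p[0] for p in pairs], dtype=float)
    lengths = np.array([p[1] for p in pairs], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("all element lengths must be positive")
    k = jc_distance(d)
    mean = float(np.sum(k * lengths) / np.sum(lengths))
    return WeightedK(
        family=family,
        mean_K=mean,
        total_length=int(lengths.sum()),
        n_elements=len(pairs),
    )


def _matches_family(hit: RepeatHit, family: str) -> bool:
    return family in (
        hit.repeat_class,
        hit.repeat_class.split("/", 1)[0],
        hit.repeat_name,
    )


def divergence_histogram(
    hits: Iterable[RepeatHit],
    genome: GenomeIndex,
    family: str | None = None,
    bin_width: float = 1.0,
    axis: str = "D",
) -> DivergenceLandscape:
    """Bin repeat bp by divergence, normalized to percent of genome.

    Each hit contributes its full genomic length to the single bin containing
    its divergence value — observed D, or the JC-corrected K when
    ``axis="K"``. ``family`` filters hits by repeat class, class prefix, or
    repeat name; ``None`` uses all hits.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if axis not in ("D", "K"):
        raise ValueError(f"axis must be 'D' or 'K', got {axis!r}")
    selected = [h for h in hits if family is None or _matches_family(h, family)]
    values = np.array([h.divergence for h in selected], dtype=float)
    lengths = np.array([h.length() for h in selected], dtype=float)
    if axis == "K" and values.size:
        values = jc_distance(values)
    top = JC_SATURATION_BOUND
    if values.size:
        top = max(top, float(values.max()) + bin_width)
    n_bins = int(np.ceil(top / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    if values.size:
        counts, _ = np.histogram(values, bins=edges, weights=lengths)
    else:
        counts = np.zeros(n_bins)
    return DivergenceLandscape(
        family=family if family is not None else "all",
        bin_edges=edges,
        bin_values=100.0 * counts / genome.total_size,
    )


def landscape_table(landscapes: Sequence[DivergenceLandscape]) -> str:
    """Render landscapes as TSV: rows = bins, one column per family.

    Landscapes may have different numbers of bins (same width required);
    shorter columns are padded with zeros.
    """
    if not landscapes:
        return "bin_start\tbin_end\n"
    widths = {round(float(l.bin_edges[1] - l.bin_edges[0]), 12) for l in landscapes}
    if len(widths) > 1:
        raise ValueError("landscapes have mixed bin widths")
    n = max(len(l.bin_values) for l in landscapes)
    ref = max(landscapes, key=lambda l: len(l.bin_values))
    lines = ["bin_start\tbin_end\t" + "\t".join(l.family for l in landscapes)]
    for i in range(n):
        row = [f"{ref.bin_edges[i]:g}", f"{ref.bin_edges[i + 1]:g}"]
        for l in landscapes:
            v = float(l.bin_values[i]) if i < len(l.bin_values) else 0.0
            row.append(f"{v:.6g}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
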