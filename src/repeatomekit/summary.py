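"""Category-level aggregation of repeat annotations.

Produces the classic repeatome summary table — total bp, copy count,
percent of the repeatome and percent of the genome per repeat class or
family — plus microsatellite motif-length profiling and A/T content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import GenomeIndex, RepeatHit

__all__ = [
    "CategorySummary",
    "MotifClassCount",
    "summarize_by_category",
    "summary_table",
    "classify_microsatellite_motif",
    "microsatellite_length_profile",
    "at_content",
]

_MOTIF_RE = re.compile(r"^\(([ACGT]{1,8})\)n$", re.IGNORECASE)


@dataclass
class CategorySummary:
    """Aggregate for one repeat category.

    ``pct_repeatome`` is the share of all annotated repeat bp (the
    repeatome); ``pct_genome`` the share of total genome bp.
    """

    category: str
    total_bp: int
    copies: int
    pct_repeatome: float
    pct_genome: float


@dataclass
class MotifClassCount:
    """Microsatellite bp aggregated by repeat-unit (motif) length."""

    motif_length: int
    total_bp: int
    pct_of_microsatellite_bp: float


def _category_label(hit: RepeatHit, level: str) -> str:
    label = hit.repeat_class
    if label in ("Unknown", "Unclassified"):
        return "Unclassified"
    if level == "class":
        return label.split("/", 1)[0]
    return label


def _merge_intervals(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by the union of intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def summarize_by_category(
    hits: Iterable[RepeatHit],
    genome: GenomeIndex,
    level: str = "family",
    overlap_mode: str = "raw",
    include_flagged: bool = True,
) -> list[CategorySummary]:
    """Aggregate hits per repeat category, sorted by total bp descending.

    Parameters
    ----------
    level:
        ``"family"`` keeps the full RepeatMasker class/family string
        (``DNA/TcMar-Tc1``); ``"class"`` truncates at the ``/``.
    overlap_mode:
        ``"raw"`` sums hit lengths as annotated; ``"merged"`` unions
        intervals within a category per sequence first, so overlapping
        annotations are not double-counted.
    include_flagged:
        Whether overlap-shadowed (asterisk-marked) records count.

    Hits of class ``Unknown`` are reported as ``Unclassified``; the
    percent-of-repeatome denominator includes them.
    """
    if level not in ("class", "family"):
        raise ValueError(f"level must be 'class' or 'family', got {level!r}")
    if overlap_mode not in ("raw", "merged"):
        raise ValueError(f"overlap_mode must be 'raw' or 'merged', got {overlap_mode!r}")
    if genome.total_size <= 0:
        raise ValueError("genome total size must be positive")

    kept = [h for h in hits if include_flagged or not h.overlap_flagged]
    bp: dict[str, int] = {}
    copies: dict[str, int] = {}
    by_cat_seq: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for hit in kept:
        cat = _category_label(hit, level)
        copies[cat] = copies.get(cat, 0) + 1
        if overlap_mode == "raw":
            bp[cat] = bp.get(cat, 0) + hit.length()
        else:
            by_cat_seq.setdefault((cat, hit.query), []).append((hit.qstart, hit.qend))
    if overlap_mode == "merged":
        for (cat, _seq), intervals in by_cat_seq.items():
            bp[cat] = bp.get(cat, 0) + _merge_intervals(intervals)

    repeatome_bp = sum(bp.values())
    out = [
        CategorySummary(
            category=cat,
            total_bp=total,
            copies=copies[cat],
            pct_repeatome=100.0 * total / repeatome_bp if repeatome_bp else 0.0,
            pct_genome=100.0 * total / genome.total_size,
        )
        for cat, total in bp.items()
    ]
    out.sort(key=lambda s: (-s.total_bp, s.category))
    return out


def summary_table(summaries: Sequence[CategorySummary]) -> str:
    """Render summaries as a TSV table."""
    lines = ["category\ttotal_bp\tcopies\tpct_repeatome\tpct_genome"]
    for s in summaries:
        lines.append(
            f"{s.category}\t{s.total_bp}\t{s.copies}\t"
            f"{s.pct_repeatome:.4f}\t{s.pct_genome:.4f}"
        )
    return "\n".join(lines) + "\n"


def classify_microsatellite_motif(repeat_name: str) -> int | None:
    """Motif (repeat-unit) length of a simple-repeat name like ``(CA)n``.

    The length is reduced to the smallest period: ``(CACA)n`` classifies as a
    dinucleotide. Names that are not simple-repeat patterns over A/C/G/T with
    unit length 1-8 return ``None``.
    """
    match = _MOTIF_RE.match(repeat_name.strip())
    if match is None:
        return None
    motif = match.group(1).upper()
    n = len(motif)
    for period in range(1, n + 1):
        if n % period == 0 and motif == motif[:period] * (n // period):
            return period
    return n


def microsatellite_length_profile(hits: Iterable[RepeatHit]) -> list[MotifClassCount]:
    """bp-weighted microsatellite composition by motif length.

    Only hits whose names classify as microsatellites contribute; the
    percentages are over the microsatellite bp represented, so they sum to
    100 whenever any microsatellite bp is present.
    """
    bp: dict[int, int] = {}
    for hit in hits:
        period = classify_microsatellite_motif(hit.repeat_name)
        if period is None:
            continue
        bp[period] = bp.get(period, 0) + hit.length()
    total = sum(bp.values())
    if total == 0:
        return []
    return [
        MotifClassCount(
            motif_length=length,
            total_bp=bp[length],
            pct_of_microsatellite_bp=100.0 * bp[length] / total,
        )
        for length in sorted(bp)
    ]


def at_content(sequence: str) -> float:
    """Fraction (A+T)/(A+C+G+T) of a sequence, case-insensitive.

    IUPAC ambiguity codes (including N) are excluded from both numerator and
    denominator. A sequence with zero unambiguous bases is an error.
    """
    upper = sequence.upper()
    a = upper.count("A")
    t = upper.count("T")
    c = upper.count("C")
    g = upper.count("G")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (a + t) / denom
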