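"""Substitution-rate estimation from mean divergence and a divergence time.

Given a mean Jukes-Cantor distance K between repeat copies and their
consensus (a stand-in for the distance accumulated since two lineages
split), and a species divergence time T with a credibility interval, the
per-year substitution rate is

    r = K / (2 T)

(the factor 2 because both lineages accumulate substitutions). The lower
rate bound comes from the upper time bound and vice versa.

Two unit conventions are supported. In the default "as-printed" mode K
enters on its percent-like scale, which is how rates of this kind are
conventionally quoted against cDNA-derived reference ranges; ``per_site=True``
divides K by 100 first for a strict substitutions-per-site reading (a factor
of 100 smaller). The percent-scale convention and the resulting unit tension
are documented rather than silently corrected.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

__all__ = [
    "RateEstimate",
    "ReferenceRanges",
    "RateClassification",
    "CDNA_REFERENCE_RANGES",
    "substitution_rate",
    "rate_interval",
    "classify_rate",
    "format_rate",
    "parse_time_years",
]

RATE_LABELS = ("below_orf", "within_orf", "between_orf_utr", "within_utr", "above_utr")


@dataclass
class RateEstimate:
    """Substitution rate with bounds propagated from a time interval.

    ``r_low = K/(2 T_high)`` and ``r_high = K/(2 T_low)``: the rate decreases
    with assumed divergence time. Stored at full precision; use
    :func:`format_rate` for the conventional 2-significant-figure display.
    """

    r_point: float
    r_low: float
    r_high: float
    K_used: float
    T_point: float
    T_low: float
    T_high: float
    per_site: bool = False


@dataclass
class ReferenceRanges:
    """Reference per-year substitution-rate ranges for coding (ORF) and
    untranslated (UTR) regions, e.g. derived from cDNA divergence between
    sister species."""

    orf_low: float
    orf_high: float
    utr_low: float
    utr_high: float

    def __post_init__(self) -> None:
        if not (self.orf_low <= self.orf_high and self.utr_low <= self.utr_high):
            raise ValueError("reference ranges must be ordered low <= high")


#: cDNA-derived ranges for channel vs blue catfish: ORF 2.5e-8..7.6e-8,
#: UTR 1.3e-7..1.9e-7 substitutions per site per year.
CDNA_REFERENCE_RANGES = ReferenceRanges(2.5e-8, 7.6e-8, 1.3e-7, 1.9e-7)


@dataclass
class RateClassification:
    """Where a rate estimate falls relative to ORF/UTR reference ranges.

    ``label`` classifies the point estimate; ``band_above_orf`` /
    ``band_below_utr`` report whether the full [r_low, r_high] band clears
    the ORF upper bound and stays under the UTR upper bound.
    """

    label: str
    band_above_orf: bool
    band_below_utr: bool
    band_overlaps_orf: bool
    band_overlaps_utr: bool


def substitution_rate(K: float, T_years: float, per_site: bool = False) -> float:
    """r = K / (2 T). ``per_site=True`` converts percent-scale K to per-site."""
    if K < 0:
        raise ValueError("K must be non-negative")
    if T_years <= 0:
        raise ValueError("divergence time must be positive")
    k = K / 100.0 if per_site else K
    return k / (2.0 * T_years)


def rate_interval(
    K: float,
    T_low: float,
    T_high: float,
    T_point: float | None = None,
    per_site: bool = False,
) -> RateEstimate:
    """Rate estimate with bounds from a divergence-time credibility interval.

    Times are in years. ``T_point`` defaults to the interval midpoint.
    """
    if T_point is None:
        T_point = 0.5 * (T_low + T_high)
    if not (0 < T_low <= T_point <= T_high):
        raise ValueError(
            f"need 0 < T_low <= T_point <= T_high, got {T_low}, {T_point}, {T_high}"
        )
    return RateEstimate(
        r_point=substitution_rate(K, T_point, per_site),
        r_low=substitution_rate(K, T_high, per_site),
        r_high=substitution_rate(K, T_low, per_site),
        K_used=K,
        T_point=T_point,
        T_low=T_low,
        T_high=T_high,
        per_site=per_site,
    )


def classify_rate(
    estimate: RateEstimate, ref: ReferenceRanges = CDNA_REFERENCE_RANGES
) -> RateClassification:
    """Classify the point rate against ORF and UTR reference ranges.

    The four reference bounds partition the rate axis into five categories;
    a point exactly on a bound goes to the lower category (tie rule). The
    full [r_low, r_high] band is compared alongside: ``band_above_orf`` means
    even the lowest plausible rate exceeds the ORF upper bound, and
    ``band_below_utr`` means even the highest stays under the UTR upper
    bound — together, the "faster than coding, slower than untranslated"
    pattern.
    """
    bounds = [ref.orf_low, ref.orf_high, ref.utr_low, ref.utr_high]
    if bounds != sorted(bounds):
        raise ValueError("ORF range must lie below the UTR range")
    label = RATE_LABELS[bisect_left(bounds, estimate.r_point)]
    return RateClassification(
        label=label,
        band_above_orf=estimate.r_low > ref.orf_high,
        band_below_utr=estimate.r_high < ref.utr_high,
        band_overlaps_orf=estimate.r_low <= ref.orf_high and estimate.r_high >= ref.orf_low,
        band_overlaps_utr=estimate.r_low <= ref.utr_high and estimate.r_high >= ref.utr_low,
    )


def format_rate(r: float) -> str:
    """Rate rounded to two significant figures, e.g. ``8.9e-08``."""
    return f"{r:.1e}"


def parse_time_years(text: str | float) -> float:
    """Parse a time like ``16.6Myr``, ``16600000``, or ``2.1kyr`` into years.

    Recognized suffixes (case-insensitive): ``yr``/``y`` (years), ``kyr``
    (thousand years), ``Myr`` (million years), ``Gyr``/``byr`` (billion
    years). A bare number is taken as years.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip().lower().replace(" ", "")
    factors = {"gyr": 1e9, "byr": 1e9, "myr": 1e6, "kyr": 1e3, "yr": 1.0, "y": 1.0}
    for suffix, factor in factors.items():
        if s.endswith(suffix):
            return float(s[: -len(suffix)]) * factor
    return float(s)
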