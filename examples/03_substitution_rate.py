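"""Substitution rate of a young satellite family from mean K and a
divergence time.

Uses the catfish-style worked numbers: mean Jukes-Cantor distance 3.53 and
a species divergence time of 16.6 Myr with 95% credibility interval
13.3-19.9 Myr, then places the rate against cDNA-derived ORF/UTR ranges.
"""

from repeatomekit import (
    CDNA_REFERENCE_RANGES,
    classify_rate,
    format_rate,
    rate_interval,
)

est = rate_interval(
    K=3.53,
    T_low=13.3e6,
    T_high=19.9e6,
    T_point=16.6e6,
)
cls = classify_rate(est, CDNA_REFERENCE_RANGES)

print(f"r = K/(2T) with K = {est.K_used} and T = {est.T_point / 1e6:.1f} Myr")
print(f"  point estimate: {format_rate(est.r_point)} substitutions/site/year")
print(f"  band from time interval: {format_rate(est.r_low)} .. {format_rate(est.r_high)}")
print(f"  vs ORF range  [{CDNA_REFERENCE_RANGES.orf_low:.1e}, {CDNA_REFERENCE_RANGES.orf_high:.1e}]")
print(f"  vs UTR range  [{CDNA_REFERENCE_RANGES.utr_low:.1e}, {CDNA_REFERENCE_RANGES.utr_high:.1e}]")
print(f"  classification: {cls.label}")
print(f"  band above ORF: {cls.band_above_orf}; band below UTR ceiling: {cls.band_below_utr}")
print("\nFaster than coding sequence but slower than untranslated regions:")
print("the family evolves under some constraint, but less than protein genes.")
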