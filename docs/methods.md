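# Methods

`repeatomekit` characterizes a genome's repeatome from repeat-annotation
tables: category composition, divergence landscapes, substitution rates,
chromosomal density profiles, and identity clustering of repeat models,
plus a simulator that generates genomes with planted repeat truth so every
stage can be validated end to end. This note records the models, the
conventions, and the choices made where the design was open.

## Coordinates and formats

All intervals are 0-based half-open internally; RepeatMasker `.out` and
GFF3 are 1-based inclusive on disk and converted only at the I/O boundary.
The `.out` reader accepts the standard 15-column dialect (two banner lines,
a blank line, whitespace-separated records); `C` in the strand column maps
to `-`, and for complement-strand records the repeat coordinates are read
as `(left) end begin`. Records carrying the trailing `*` (overlap-shadowed
by a higher-scoring hit) are kept but flagged, and summaries can include or
exclude them — annotation tools differ across versions in how they count
these, so the raw data is preserved and the choice surfaced. Records
without the optional ID column receive a running index so joins stay
stable.

GFF3 repeat annotations use a small self-describing attribute dialect,
`Target=<name>;Class=<class>;Divergence=<D>;ID=<id>`, with feature type
`tandem_repeat` for simple/satellite/low-complexity classes and
`dispersed_repeat` otherwise. This dialect is a project convention chosen
to be lossless for the pipeline's fields; round-tripping is exact for the
fields it carries (alignment percentages and consensus coordinates are
`.out`-only).

## Category summaries

`summarize_by_category` aggregates hit bp and copy counts per repeat
class/family string (`level="class"` truncates at the `/`). Hits of class
`Unknown` are reported as `Unclassified` and stay inside the
percent-of-repeatome denominator, so known + unclassified shares sum to
100%. Two bp-counting modes exist because annotations can overlap: `raw`
sums annotated bp as reported, `merged` unions intervals within a category
per sequence first. Merged totals are never larger than raw, with equality
exactly when no within-category overlaps exist.

Microsatellites are classified by repeat-unit length 1–8 from names of the
form `(motif)n`, reduced to the smallest period (`(CACA)n` counts as
dinucleotide). Reverse complements and rotations are *not* merged —
classification is by unit length only, which is how composition-by-type
tables are conventionally built. A/T content is (A+T)/(A+C+G+T),
case-insensitive, with ambiguity codes excluded from both numerator and
denominator.

## Jukes-Cantor correction and landscapes

Observed divergence D (percent of sites differing from the family
consensus) underestimates the substitutions per site because of multiple
hits. The one-parameter Jukes-Cantor correction, kept on the percent
scale, is

    K = -(300/4) ln(1 - 4D/300) = -75 ln(1 - D/75),   0 <= D < 75.

K is strictly increasing, convex, and >= D; the domain boundary at 75% is
the four-letter saturation limit and is enforced with a descriptive error.
The closed-form inverse D = 75(1 - e^(-K/75)) is provided and round-trips
to 1e-9. The length-weighted family mean is
K̄ = Σ K_i·L_i / Σ L_i over elements i, so long fragments dominate short
ones in proportion to the sites they contribute.

A divergence landscape bins repeat bp by divergence (left-closed bins,
default width 1.0) and normalizes to percent of genome, so a family's
landscape mass equals its percent of the genome. Each hit is assigned
whole to the bin containing its divergence — per-base divergence is not
available in `.out` — and the X axis can show raw D or corrected K. No
smoothing is applied; bin width is the only display parameter.

## Substitution rates

r = K/(2T), with T the divergence time in years and the factor 2 for the
two lineages. The lower rate bound uses the upper time bound and vice
versa. By default K enters on its percent-like scale, the convention under
which rates of this kind are quoted against cDNA-derived reference ranges;
this is a factor of 100 away from a strict per-site reading, and
`per_site=True` applies that division instead. The discrepancy is a known
tension in how percent-scale distances are combined with per-site-per-year
units; the package reproduces the conventional arithmetic by default and
documents rather than silently "fixes" it.

Classification against ORF and UTR reference ranges partitions the rate
axis into five categories (`below_orf` … `above_utr`) by the point
estimate; a value exactly on a boundary goes to the lower category. The
full [r_low, r_high] band is reported alongside: `band_above_orf` (even
the slowest bound beats the ORF ceiling) and `band_below_utr` (even the
fastest stays under the UTR ceiling) together express the "faster than
coding, slower than untranslated" pattern. Display rounding is two
significant figures; stored values keep full precision.

## Density tracks

Chromosomes are tiled with fixed windows (default 1 Mb); each hit is
clipped to every window it overlaps and the clipped bp accumulated. The
final partial window is normalized by its actual length so units stay
bp/Mb — dropping or under-normalizing it would fabricate low-density
chromosome ends, exactly where tandem repeats concentrate. Raw counting is
the default (densities can exceed 1e6 bp/Mb when annotations overlap);
merged mode unions intervals first and is capped at 1e6 by construction.
Matrix rows are natural-sorted (chr2 before chr10); bedGraph output uses
0-based half-open intervals.

## Identity clustering

Unclassified repeat models are grouped by greedy first-fit clustering:
sequences sorted longest-first (ties by name), each compared against
existing representatives in creation order and joining the first at or
above the identity threshold (default 50%). This mirrors the incremental
behaviour of the standard nucleotide clusterer, whose identity denominator
at low thresholds is the shorter sequence; identity here is matched bases
in an optimal global alignment (match +1, mismatch −1, gap −2, end gaps
penalized) divided by the shorter length. The dynamic program maximizes
(score, matches) lexicographically — both are additive along an alignment
path, so this is a well-defined objective and removes tie ambiguity in the
match count. Repeat consensi are strandless, so the reverse complement is
aligned too and the better identity kept (disable with
`both_strands=False`).

There is no k-mer prefilter: alignment is exact, and inputs are capped at
500 sequences of 5 kb to keep the quadratic DP honest. Clustering
genome-scale repeat libraries is explicitly out of scope; the value here
is a correct, testable reference of the procedure. Note that for short
random DNA the expected alignment identity under this scoring already
approaches 50%, so the default threshold is permissive — real separation
of families typically shows at stricter thresholds (see
`examples/05_cluster_unknowns.py`).

## The synthetic-data generator

The simulator plants repeat copies in a random-background genome and emits
FASTA, `.out`, GFF3 and an exact truth table. It emulates the structural
features the analysis stages key on:

- dispersed DNA-transposon families with broad divergence distributions;
- a young, low-divergence satellite family enriched near chromosome
  centers (centromere-like);
- microsatellite arrays enriched in the terminal fraction of each
  chromosome (telomere-like), with composition by motif length;
- unclassified A/T-rich families (58% A+T consensus composition).

Divergence is modeled observationally: each site of a copy is replaced by
one of the three other bases with probability D/100, so realized
divergence is a binomial fraction and matches what an annotation tool
would report against the consensus. Multiple hits, indels, transposition
mechanics and nested insertions are *not* modeled; copies are full-length
and never overlap. Consequently, passing recovery tests demonstrates the
pipeline arithmetic, not robustness to fragmented, nested or
indel-riddled real annotations.

Per-copy target divergences are drawn from a scaled Beta on [0, 70] with
mean exactly `divergence_mean` and spread `divergence_sd` (variance
clamped to the support). A Beta was chosen over a truncated normal
because truncation shifts the mean, which would silently break
mean-divergence recovery against the configured value; the Beta keeps the
first moment exact on a bounded support. `divergence_sd=0` plants every
copy at the mean.

Placement draws a chromosome proportional to length, then a start
position from weighted segments: for end-enriched families the terminal
5% of each chromosome end carries weight 10 versus 1 for the interior
(≈53% of copies land terminally at the defaults); center-enriched
families weight the central 10% the same way. Overlaps are rejected and
resampled, with a hard failure after 10,000 attempts per copy; total
planted bp must stay below 80% of the genome. All randomness flows from a
single seeded generator in a fixed draw order, so identical configuration
and seed give byte-identical outputs. The `.out` divergence column is the
realized value rounded to 0.1 (as annotation tables print it); the truth
table keeps full precision plus the drawn target.

The default configuration is a 5 Mb genome (four 1.25 Mb chromosomes)
whose family genome-shares follow a catfish-like repeatome: Tc1/mariner
transposons 8.8% of the genome at mean divergence 12 (sd 8), a young
center-enriched satellite 1.6% at mean 3.53 (sd 1), microsatellites 6.2%
split 46 / 18.6 / 13.6 / 12 / 9.8 percent of microsatellite bp across di-,
tetra-, tri-, mono- and pentanucleotide motifs, LINE/L2 1.9%, hAT/Ac 1.3%,
LTR/Gypsy 1.0%, and unclassified A/T-rich families 7.0% — about 28% of
the genome planted in total. Only the major categories are modeled, so
percent-of-repeatome values within the synthetic repeatome are
renormalized relative to a full 70-category table; percent-of-genome
values are the anchored quantities. This size runs the full pipeline in
about a second while leaving ≥ 10^5 sites per family of interest, enough
for mean-divergence recovery at small-fraction-of-a-percent precision.

## Statistical checks

Recovery tests separate the two noise sources the generator introduces.
The mutation process is binomial: the realized bp-weighted family
divergence is compared to the bp-weighted mean of the drawn targets
within 3·SE_binom, SE_binom = 100·sqrt(p(1−p)/N) over N planted sites.
Recovery of the configured mean additionally carries the per-copy draw
spread, so the comparison against `divergence_mean` uses
3·sqrt(SE_binom² + sd²/n_copies). The rate round-trip plants a family
whose mean K equals ρ·2T on the percent scale (ρ = 1e-7/yr, T = 16.6 Myr,
i.e. mean divergence jc_inverse(3.32) ≈ 3.25 with sd 0) and recovers ρ
through weighted-mean-K → rate arithmetic within 3 standard errors
propagated through the JC derivative, SE_K = SE_D/(1 − D/75).

## Known limitations

- The clusterer is a desk-scale reference, not a drop-in for clustering
  thousands of repeat models; its cluster boundaries can differ from
  heuristic tools even where both respect the identity threshold.
- Divergence landscapes assign each hit wholly to one bin; sub-element
  divergence structure is invisible at `.out` granularity.
- The rate module propagates only time uncertainty; uncertainty in K̄
  (finite copies, rounding of the divergence column) is not folded into
  the reported band.
- Kimura 2-parameter or CpG-adjusted distances are not implemented; only
  the one-parameter correction above.
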