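"""Readers and writers for the interchange formats the pipeline touches.

Three formats are handled: RepeatMasker ``.out`` annotation tables (read),
GFF3 repeat annotations (read/write, using a small self-describing attribute
dialect), and FASTA genomes (read, via Biopython). All on-disk coordinates
are 1-based inclusive; internally every interval is 0-based half-open, with
conversion happening only at the I/O boundary.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "RepeatHit",
    "GenomeIndex",
    "RepeatParseError",
    "parse_repeatmasker_out",
    "parse_gff_repeats",
    "write_gff",
    "read_fasta",
    "open_text",
]

#: observed divergence must stay below this bound for the Jukes-Cantor
#: transform to be defined (ln(1 - D/75) diverges at D = 75).
JC_SATURATION_BOUND = 75.0

# RepeatMasker class prefixes that denote tandem rather than dispersed repeats
_TANDEM_CLASS_PREFIXES = {"Simple_repeat", "Satellite", "Low_complexity"}


class RepeatParseError(ValueError):
    """Malformed record in an annotation file; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class RepeatHit:
    """One annotated repeat interval.

    ``qstart``/``qend`` are 0-based half-open genomic coordinates on ``query``.
    ``divergence`` is the percent of aligned sites that differ between this
    copy and the family consensus (the observed divergence D), constrained to
    ``[0, 75)`` — the domain of the Jukes-Cantor correction.
    """

    query: str
    qstart: int
    qend: int
    strand: str
    repeat_name: str
    repeat_class: str
    divergence: float
    score: int = 0
    pct_deleted: float = 0.0
    pct_inserted: float = 0.0
    rstart: int = 0
    rend: int = 0
    rleft: int = 0
    hit_id: int | None = None
    overlap_flagged: bool = False

    def __post_init__(self) -> None:
        if self.qstart < 0 or self.qend <= self.qstart:
            raise ValueError(
                f"invalid interval [{self.qstart}, {self.qend}) on {self.query!r}"
            )
        if not 0.0 <= self.divergence < JC_SATURATION_BOUND:
            raise ValueError(
                f"divergence {self.divergence} outside [0, {JC_SATURATION_BOUND})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self) -> int:
        """Number of genomic base pairs covered by the hit."""
        return self.qend - self.qstart


class GenomeIndex:
    """Ordered map of sequence name -> length, with optional sequence access.

    Serves as the denominator for percent-of-genome quantities and as the
    coordinate frame for density windows.
    """

    def __init__(
        self,
        lengths: Mapping[str, int],
        sequences: Mapping[str, str] | None = None,
    ):
        self._lengths: dict[str, int] = dict(lengths)
        if any(l <= 0 for l in self._lengths.values()):
            raise ValueError("all sequence lengths must be positive")
        self._sequences = dict(sequences) if sequences is not None else None
        if self._sequences is not None:
            for name, seq in self._sequences.items():
                if len(seq) != self._lengths.get(name):
                    raise ValueError(f"length mismatch for sequence {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_size(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def length(self, name: str) -> int:
        return self._lengths[name]

    def sequence(self, name: str) -> str:
        if self._sequences is None:
            raise KeyError("this index was built without sequence data")
        return self._sequences[name]

    @property
    def has_sequences(self) -> bool:
        return self._sequences is not None


def open_text(source: str | Path | IO) -> IO:
    """Open ``source`` for text reading, transparently decompressing gzip.

    File-like objects are returned unchanged.
    """
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _lines(source: str | Path | IO | Iterable[str]) -> Iterator[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        handle: Iterable[str] = open_text(source)
    else:
        handle = source
    for lineno, line in enumerate(handle, start=1):
        yield lineno, line.rstrip("\n")


def _paren_int(token: str, lineno: int, what: str) -> int:
    raw = token[1:-1] if token.startswith("(") and token.endswith(")") else token
    try:
        return int(raw)
    except ValueError:
        raise RepeatParseError(lineno, f"non-integer {what} field {token!r}") from None


def parse_repeatmasker_out(
    source: str | Path | IO | Iterable[str],
) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` table into :class:`RepeatHit` records.

    The standard dialect is expected: two header lines and a blank line,
    then whitespace-separated records with 1-based inclusive query
    coordinates and ``+``/``C`` strand. ``C`` (complement) maps to ``-`` and
    its repeat coordinates are read as ``(left) end begin``. Records lacking
    the trailing ID column get a running index; a trailing ``*``
    (overlap-shadowed by a higher-scoring hit) sets ``overlap_flagged``.
    """
    hits: list[RepeatHit] = []
    seen_data = False
    running = 0
    for lineno, line in _lines(source):
        stripped = line.strip()
        if not stripped:
            continue
        first = stripped.split(None, 1)[0]
        if not seen_data and not first.isdigit():
            # header block (column banners); only tolerated before data
            if lineno > 4:
                raise RepeatParseError(lineno, f"unparseable record {stripped!r}")
            continue
        seen_data = True
        tokens = stripped.split()
        flagged = False
        if tokens and tokens[-1] == "*":
            flagged = True
            tokens = tokens[:-1]
        if len(tokens) not in (14, 15):
            raise RepeatParseError(
                lineno, f"expected 14-15 fields, got {len(tokens)}"
            )
        try:
            divergence = float(tokens[1])
        except ValueError:
            raise RepeatParseError(
                lineno, f"non-numeric divergence {tokens[1]!r}"
            ) from None
        try:
            score = int(tokens[0])
            pct_del = float(tokens[2])
            pct_ins = float(tokens[3])
            qstart = int(tokens[5]) - 1  # 1-based inclusive -> 0-based half-open
            qend = int(tokens[6])
        except ValueError as exc:
            raise RepeatParseError(lineno, str(exc)) from None
        strand_token = tokens[8]
        if strand_token == "+":
            strand = "+"
            rstart = _paren_int(tokens[11], lineno, "repeat begin")
            rend = _paren_int(tokens[12], lineno, "repeat end")
            rleft = _paren_int(tokens[13], lineno, "repeat left")
        elif strand_token == "C":
            strand = "-"
            rleft = _paren_int(tokens[11], lineno, "repeat left")
            rend = _paren_int(tokens[12], lineno, "repeat end")
            rstart = _paren_int(tokens[13], lineno, "repeat begin")
        else:
            raise RepeatParseError(lineno, f"strand must be '+' or 'C', got {strand_token!r}")
        hit_id = int(tokens[14]) if len(tokens) == 15 else running
        try:
            hit = RepeatHit(
                query=tokens[4],
                qstart=qstart,
                qend=qend,
                strand=strand,
                repeat_name=tokens[9],
                repeat_class=tokens[10],
                divergence=divergence,
                score=score,
                pct_deleted=pct_del,
                pct_inserted=pct_ins,
                rstart=rstart,
                rend=rend,
                rleft=rleft,
                hit_id=hit_id,
                overlap_flagged=flagged,
            )
        except ValueError as exc:
            raise RepeatParseError(lineno, str(exc)) from None
        hits.append(hit)
        running += 1
    return hits


def _gff_type(repeat_class: str) -> str:
    return (
        "tandem_repeat"
        if repeat_class.split("/", 1)[0] in _TANDEM_CLASS_PREFIXES
        else "dispersed_repeat"
    )


def write_gff(hits: Iterable[RepeatHit]) -> str:
    """Serialize hits as GFF3 with the attribute dialect
    ``Target=<name>;Class=<class>;Divergence=<D>;ID=<hit_id>``.

    Coordinates are converted back to 1-based inclusive; the feature type is
    ``tandem_repeat`` for simple/satellite/low-complexity classes and
    ``dispersed_repeat`` otherwise.
    """
    out = ["##gff-version 3"]
    for hit in hits:
        attrs = (
            f"Target={hit.repeat_name};Class={hit.repeat_class};"
            f"Divergence={hit.divergence:g};ID={hit.hit_id}"
        )
        out.append(
            "\t".join(
                [
                    hit.query,
                    "repeatome-kit",
                    _gff_type(hit.repeat_class),
                    str(hit.qstart + 1),
                    str(hit.qend),
                    str(hit.score),
                    hit.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(out) + "\n"


def parse_gff_repeats(source: str | Path | IO | Iterable[str]) -> list[RepeatHit]:
    """Parse GFF3 repeat annotations written in the dialect of :func:`write_gff`."""
    hits: list[RepeatHit] = []
    running = 0
    for lineno, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip().split("\t")
        if len(cols) != 9:
            raise RepeatParseError(lineno, f"expected 9 tab-separated columns, got {len(cols)}")
        seqid, _source, _type, start, end, score, strand, _phase, attr_col = cols
        attrs: dict[str, str] = {}
        for chunk in attr_col.split(";"):
            chunk = chunk.strip()
            if chunk and "=" in chunk:
                key, value = chunk.split("=", 1)
                attrs[key] = value
        try:
            qstart = int(start) - 1
            qend = int(end)
        except ValueError:
            raise RepeatParseError(lineno, f"non-integer coordinates {start!r}/{end!r}") from None
        try:
            divergence = float(attrs.get("Divergence", "0"))
        except ValueError:
            raise RepeatParseError(
                lineno, f"non-numeric Divergence attribute {attrs.get('Divergence')!r}"
            ) from None
        hit_id = int(attrs["ID"]) if attrs.get("ID", "").lstrip("-").isdigit() else running
        try:
            hit = RepeatHit(
                query=seqid,
                qstart=qstart,
                qend=qend,
                strand=strand if strand in ("+", "-") else "+",
                repeat_name=attrs.get("Target", "unknown"),
                repeat_class=attrs.get("Class", "Unknown"),
                divergence=divergence,
                score=int(score) if score not in (".", "") else 0,
                hit_id=hit_id,
            )
        except ValueError as exc:
            raise RepeatParseError(lineno, str(exc)) from None
        hits.append(hit)
        running += 1
    return hits


def read_fasta(source: str | Path | IO) -> GenomeIndex:
    """Read a FASTA file (optionally gzipped) into a :class:`GenomeIndex`.

    Sequence names are taken up to the first whitespace. Duplicate names are
    an error.
    """
    handle = open_text(source)
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(handle, "fasta"):
        if record.id in lengths:
            raise ValueError(f"duplicate sequence name {record.id!r}")
        seq = str(record.seq)
        lengths[record.id] = len(seq)
        sequences[record.id] = seq
    return GenomeIndex(lengths, sequences)
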