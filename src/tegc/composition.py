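"""Base-composition arithmetic for soft-masked nucleotide sequences.

Everything downstream — genome GC (GC_G), GC of the repeat-masked fraction
(GC_REP), GC of the non-repetitive fraction (GC_NONREP), and per-library TE
GC (GC_TE) — reduces to tallies of upper- and lowercase A/C/G/T held in a
:class:`BaseCounts`.  Case is meaningful throughout: lowercase bases are
repeat-masked (soft-masking, as in Ensembl "sm" genome dumps), uppercase
bases are the non-repetitive fraction, and N of either case is an assembly
gap or hard-masked run and never enters a GC denominator.

Conventions:

* GC% = 100 * (G + C) / (A + C + G + T) over unambiguous bases only.
  N, IUPAC ambiguity codes (including S = G/C) and gap symbols are excluded
  from both numerator and denominator.  This makes the repeat/non-repeat
  weighted-mean identity exact.
* U is counted as T (some consensus libraries carry RNA-alphabet entries).
* GC% over an empty base set is undefined (``None``), not an error.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "BaseCounts",
    "CompositionSummary",
    "GenomePartition",
    "FastaFormatError",
    "read_fasta",
    "count_bases",
    "gc_percent",
    "partition_genome",
    "isochore_band",
    "DEFAULT_ISOCHORE_BOUNDARIES",
    "cvalue_to_mb",
    "MB_PER_PG",
    "sequence_stats_table",
]


class FastaFormatError(ValueError):
    """Raised when a putative FASTA file has no leading header line."""


@dataclass
class SequenceRecord:
    """One FASTA record with case preserved (lowercase = repeat-masked)."""

    identifier: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence identifier must be non-empty")


def _open_text(path: Union[str, Path]) -> TextIO:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_fasta(source: Union[str, Path, IO[str]]) -> Iterator[SequenceRecord]:
    """Stream :class:`SequenceRecord` objects from a FASTA file or handle.

    Plain or gzip-compressed files are accepted (by ``.gz`` suffix).  Line
    wrapping and trailing whitespace are normalized away; residue case is
    preserved.  An empty file yields an empty stream.  A file whose first
    non-blank line is not a ``>`` header raises :class:`FastaFormatError`.
    """
    if hasattr(source, "read"):
        yield from _read_fasta_handle(source)  # type: ignore[arg-type]
    else:
        with _open_text(source) as handle:
            yield from _read_fasta_handle(handle)


def _read_fasta_handle(handle: IO[str]) -> Iterator[SequenceRecord]:
    # SimpleFastaParser silently skips any preamble before the first ">",
    # which would hide malformed input; enforce the header requirement here.
    first = handle.readline()
    while first and not first.strip():
        first = handle.readline()
    if not first:
        return
    if not first.startswith(">"):
        raise FastaFormatError(
            f"not FASTA: first non-blank line does not start with '>': {first[:50]!r}"
        )
    title = first[1:].rstrip()
    pending = title
    for title, seq in _parser_with_first(handle, pending):
        ident = title.split(None, 1)[0] if title else ""
        if not ident:
            raise FastaFormatError("FASTA record with empty header line")
        yield SequenceRecord(identifier=ident, description=title, residues=seq)


def _parser_with_first(handle: IO[str], first_title: str):
    """Run SimpleFastaParser but re-attach the already-consumed header."""
    import io
    import itertools

    rest = itertools.chain([">" + first_title + "\n"], handle)

    class _Chain(io.TextIOBase):
        def __init__(self, it):
            self._it = it

        def readline(self):  # pragma: no cover - SimpleFastaParser iterates
            return next(self._it, "")

        def __iter__(self):
            return self._it

    return SimpleFastaParser(_Chain(rest))


@dataclass
class BaseCounts:
    """Exact masked/unmasked A/C/G/T tallies plus N and everything else.

    The sum of all ten fields equals the number of residues consumed; no
    symbol is ever dropped or rejected.
    """

    a_upper: int = 0
    c_upper: int = 0
    g_upper: int = 0
    t_upper: int = 0
    a_lower: int = 0
    c_lower: int = 0
    g_lower: int = 0
    t_lower: int = 0
    n_count: int = 0
    other_count: int = 0

    def total(self) -> int:
        return (
            self.a_upper + self.c_upper + self.g_upper + self.t_upper
            + self.a_lower + self.c_lower + self.g_lower + self.t_lower
            + self.n_count + self.other_count
        )

    def counted(self, fraction: str = "all") -> int:
        """Unambiguous A/C/G/T bases in the selected case fraction."""
        if fraction == "masked_only":
            return self.a_lower + self.c_lower + self.g_lower + self.t_lower
        if fraction == "unmasked_only":
            return self.a_upper + self.c_upper + self.g_upper + self.t_upper
        if fraction == "all":
            return self.counted("masked_only") + self.counted("unmasked_only")
        raise ValueError(f"unknown fraction {fraction!r}")

    def gc(self, fraction: str = "all") -> int:
        if fraction == "masked_only":
            return self.c_lower + self.g_lower
        if fraction == "unmasked_only":
            return self.c_upper + self.g_upper
        if fraction == "all":
            return self.gc("masked_only") + self.gc("unmasked_only")
        raise ValueError(f"unknown fraction {fraction!r}")

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.a_upper + other.a_upper,
            self.c_upper + other.c_upper,
            self.g_upper + other.g_upper,
            self.t_upper + other.t_upper,
            self.a_lower + other.a_lower,
            self.c_lower + other.c_lower,
            self.g_lower + other.g_lower,
            self.t_lower + other.t_lower,
            self.n_count + other.n_count,
            self.other_count + other.other_count,
        )

    def __iadd__(self, other: "BaseCounts") -> "BaseCounts":
        return self + other


def _tally_string(s: str) -> BaseCounts:
    # str.count is a C-level scan; 12 passes beat a Python per-char loop by
    # orders of magnitude on megabase inputs.
    counts = BaseCounts(
        a_upper=s.count("A"),
        c_upper=s.count("C"),
        g_upper=s.count("G"),
        t_upper=s.count("T") + s.count("U"),
        a_lower=s.count("a"),
        c_lower=s.count("c"),
        g_lower=s.count("g"),
        t_lower=s.count("t") + s.count("u"),
        n_count=s.count("N") + s.count("n"),
    )
    known = counts.total()
    counts.other_count = len(s) - known
    return counts


def count_bases(
    records: Union[str, SequenceRecord, Iterable[Union[str, SequenceRecord]]],
) -> BaseCounts:
    """Tally bases over a residue string, a record, or a stream of either.

    U/u is counted with T/t; N of either case goes to ``n_count``; every
    remaining symbol (IUPAC ambiguity codes, gaps) goes to ``other_count``.
    Unknown symbols are counted, never rejected.
    """
    if isinstance(records, str):
        return _tally_string(records)
    if isinstance(records, SequenceRecord):
        return _tally_string(records.residues)
    total = BaseCounts()
    for rec in records:
        total += _tally_string(rec if isinstance(rec, str) else rec.residues)
    return total


@dataclass
class CompositionSummary:
    """GC% over a selected base set; ``gc_percent`` is None when no
    unambiguous base was available (undefined, not zero)."""

    gc_percent: Optional[float]
    counted_bases: int
    total_length: int


def gc_percent(counts: BaseCounts, fraction: str = "all") -> CompositionSummary:
    """GC% of the selected case fraction of a :class:`BaseCounts`.

    ``fraction`` is one of ``all``, ``masked_only`` (lowercase bases,
    i.e. the repeat-masked part) or ``unmasked_only``.
    """
    denom = counts.counted(fraction)
    gc = None if denom == 0 else 100.0 * counts.gc(fraction) / denom
    return CompositionSummary(
        gc_percent=gc, counted_bases=denom, total_length=counts.total()
    )


@dataclass
class GenomePartition:
    """GC of a soft-masked assembly split into repeat / non-repeat fractions.

    ``gc_rep`` (GC_REP) is taken over lowercase bases, ``gc_nonrep``
    (GC_NONREP) over uppercase bases, ``gc_genome`` (GC_G) over both.  The
    base-weighted mean of the two defined fractions always reconstructs
    ``gc_genome`` exactly (up to floating rounding).
    """

    gc_genome: Optional[float]
    gc_rep: Optional[float]
    gc_nonrep: Optional[float]
    repeat_fraction: float
    counted_rep: int
    counted_nonrep: int

    @classmethod
    def from_counts(cls, counts: BaseCounts) -> "GenomePartition":
        rep = gc_percent(counts, "masked_only")
        nonrep = gc_percent(counts, "unmasked_only")
        overall = gc_percent(counts, "all")
        denom = rep.counted_bases + nonrep.counted_bases
        frac = rep.counted_bases / denom if denom else 0.0
        return cls(
            gc_genome=overall.gc_percent,
            gc_rep=rep.gc_percent,
            gc_nonrep=nonrep.gc_percent,
            repeat_fraction=frac,
            counted_rep=rep.counted_bases,
            counted_nonrep=nonrep.counted_bases,
        )


def partition_genome(
    records: Union[str, SequenceRecord, Iterable[Union[str, SequenceRecord]]],
) -> GenomePartition:
    """Partition a soft-masked assembly into repeat and non-repeat GC.

    Input with no lowercase base at all yields ``repeat_fraction`` 0 and an
    undefined ``gc_rep``; a warning is logged because this usually means the
    assembly was not soft-masked (hard-masked N-for-repeat dumps are not
    supported).
    """
    counts = count_bases(records)
    part = GenomePartition.from_counts(counts)
    if part.counted_rep == 0 and part.counted_nonrep > 0:
        logger.warning(
            "no soft-masked (lowercase) bases found: input may be unmasked "
            "or hard-masked; GC_REP is undefined"
        )
    return part


#: Lower boundaries of the isochore GC bands (percent).  The classical band
#: definitions leave gaps between bands (36->37, 40->41, 45->46, 52->53);
#: half-open intervals [lower, next_lower) make the classifier total.
DEFAULT_ISOCHORE_BOUNDARIES: Sequence[tuple[str, float]] = (
    ("sub-L1", 0.0),
    ("L1", 34.0),
    ("L2", 37.0),
    ("H1", 41.0),
    ("H2", 46.0),
    ("H3", 53.0),
)


def isochore_band(
    gc: float,
    boundaries: Sequence[tuple[str, float]] = DEFAULT_ISOCHORE_BOUNDARIES,
) -> str:
    """Classify a GC percentage into an isochore band label.

    Default bands: sub-L1 [0,34), L1 [34,37), L2 [37,41), H1 [41,46),
    H2 [46,53), H3 [53,100].  Boundaries are overridable; they must start at
    0 and increase strictly, which guarantees a total monotone classifier.
    """
    if not 0.0 <= gc <= 100.0:
        raise ValueError(f"GC% must lie in [0, 100], got {gc}")
    labels = [lab for lab, _ in boundaries]
    lowers = [low for _, low in boundaries]
    if lowers[0] != 0.0 or any(b <= a for a, b in zip(lowers, lowers[1:])):
        raise ValueError("isochore boundaries must start at 0 and be strictly increasing")
    return labels[bisect_right(lowers, gc) - 1]


#: Megabases of double-stranded DNA per picogram (0.978e9 bp/pg).
MB_PER_PG = 978.0


def cvalue_to_mb(c_value_pg: float, constant: float = MB_PER_PG) -> float:
    """Convert a cytological genome size (C-value, pg) to megabases."""
    if c_value_pg <= 0:
        raise ValueError(f"C-value must be positive, got {c_value_pg}")
    if constant <= 0:
        raise ValueError(f"conversion constant must be positive, got {constant}")
    return c_value_pg * constant


def _fmt(x: Optional[float], nd: int = 4) -> str:
    return "." if x is None else f"{x:.{nd}f}"


def sequence_stats_table(
    records: Iterable[SequenceRecord],
) -> Iterator[str]:
    """Yield TSV lines of per-sequence composition (header first).

    Columns: seq_id, length, counted_bases, gc_all, gc_rep, gc_nonrep,
    repeat_fraction.  Undefined values are written as ".".
    """
    yield "seq_id\tlength\tcounted_bases\tgc_all\tgc_rep\tgc_nonrep\trepeat_fraction"
    for rec in records:
        counts = count_bases(rec)
        part = GenomePartition.from_counts(counts)
        yield "\t".join(
            [
                rec.identifier,
                str(counts.total()),
                str(counts.counted("all")),
                _fmt(part.gc_genome),
                _fmt(part.gc_rep),
                _fmt(part.gc_nonrep),
                f"{part.repeat_fraction:.6f}",
            ]
        )
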