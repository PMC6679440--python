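"""Readers and writers for strand-specific allele-count tables and amplicon panels.

The count-file dialect is a plain TSV with one row per genomic position::

    chrom  pos  ref  depth_fwd  depth_rev  A_fwd  A_rev  C_fwd  C_rev  G_fwd  G_rev  T_fwd  T_rev

``pos`` is 1-based and inclusive (pileup/VCF convention); amplicon panels use
standard 0-based half-open BED coordinates. The four per-base columns on each
strand partition that strand's depth, i.e. the reference-base count equals the
strand depth minus the non-reference counts. Count files are expected to come
from an upstream extractor that has already applied base- and read-quality
filtering; this module only validates internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

BASES: tuple[str, ...] = ("A", "C", "G", "T")

COUNTS_COLUMNS: tuple[str, ...] = (
    "chrom",
    "pos",
    "ref",
    "depth_fwd",
    "depth_rev",
    "A_fwd",
    "A_rev",
    "C_fwd",
    "C_rev",
    "G_fwd",
    "G_rev",
    "T_fwd",
    "T_rev",
)


class CountsParseError(ValueError):
    """A count or BED file line could not be parsed."""


class CountsValidationError(ValueError):
    """Parsed values violate a count-table invariant."""


@dataclass(frozen=True, order=True)
class PositionKey:
    """A 1-based genomic position together with its reference base."""

    chrom: str
    pos: int
    ref: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CountsValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES:
            raise CountsValidationError(f"ref must be one of {BASES}, got {self.ref!r}")


@dataclass(frozen=True)
class StrandCounts:
    """Per-strand read depths and per-base read counts at one position.

    ``alt_fwd``/``alt_rev`` map every base (including the reference base) to
    its strand-specific read count; the four counts on a strand sum to that
    strand's depth.
    """

    depth_fwd: int
    depth_rev: int
    alt_fwd: Mapping[str, int]
    alt_rev: Mapping[str, int]

    def validate(self, ref: str) -> None:
        for strand, depth, counts in (
            ("forward", self.depth_fwd, self.alt_fwd),
            ("reverse", self.depth_rev, self.alt_rev),
        ):
            if depth < 0:
                raise CountsValidationError(f"negative {strand} depth {depth}")
            for base in BASES:
                if counts.get(base, 0) < 0:
                    raise CountsValidationError(
                        f"negative {strand} count for base {base}"
                    )
            total = sum(counts.get(b, 0) for b in BASES)
            if total > depth:
                raise CountsValidationError(
                    f"{strand} base counts sum to {total} > depth {depth}"
                )
            nonref = total - counts.get(ref, 0)
            if counts.get(ref, 0) != depth - nonref:
                raise CountsValidationError(
                    f"{strand} reference count {counts.get(ref, 0)} != "
                    f"depth {depth} - non-reference {nonref}"
                )

    def alt_count(self, alt: str, strand: str) -> int:
        counts = self.alt_fwd if strand == "+" else self.alt_rev
        return counts.get(alt, 0)

    def vaf(self, alt: str) -> float:
        """Strand-combined allele fraction of ``alt`` (0.0 at zero depth)."""
        depth = self.depth_fwd + self.depth_rev
        if depth == 0:
            return 0.0
        return (self.alt_fwd.get(alt, 0) + self.alt_rev.get(alt, 0)) / depth


@dataclass
class SampleCounts:
    """One sample's count table, keyed by position and sorted by (chrom, pos)."""

    sample_id: str
    records: dict[PositionKey, StrandCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = dict(
            sorted(self.records.items(), key=lambda kv: (kv[0].chrom, kv[0].pos))
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[PositionKey, StrandCounts]]:
        return iter(self.records.items())


@dataclass
class AmpliconPanel:
    """Amplicon intervals as (chrom, start, end, amplicon_id), 0-based half-open.

    Intervals may overlap; overlap zones are exactly where edge artifacts are
    flagged downstream.
    """

    intervals: list[tuple[str, int, int, str]]

    def covering(self, chrom: str, pos: int) -> list[tuple[str, int, int, str]]:
        """Intervals covering the 1-based position ``pos``."""
        p0 = pos - 1
        return [
            iv for iv in self.intervals if iv[0] == chrom and iv[1] <= p0 < iv[2]
        ]


def _parse_int(token: str, column: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise CountsParseError(
            f"line {lineno}: column {column!r} is not an integer: {token!r}"
        ) from None


def read_counts_file(path: str | Path, sample_id: str | None = None) -> SampleCounts:
    """Load one sample's count table, validating every row's invariants.

    Raises :class:`CountsParseError` for malformed lines (with line number) and
    :class:`CountsValidationError` when counts are internally inconsistent.
    """
    path = Path(path)
    records: dict[PositionKey, StrandCounts] = {}
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != COUNTS_COLUMNS:
                    raise CountsParseError(
                        f"line {lineno}: header {header} does not match the "
                        f"expected columns {list(COUNTS_COLUMNS)}"
                    )
                continue
            if len(fields) != len(COUNTS_COLUMNS):
                raise CountsParseError(
                    f"line {lineno}: expected {len(COUNTS_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            pos = _parse_int(pos_s, "pos", lineno)
            numbers = [
                _parse_int(tok, col, lineno)
                for tok, col in zip(fields[3:], COUNTS_COLUMNS[3:])
            ]
            key = PositionKey(chrom, pos, ref)
            sc = StrandCounts(
                depth_fwd=numbers[0],
                depth_rev=numbers[1],
                alt_fwd={b: numbers[2 + 2 * i] for i, b in enumerate(BASES)},
                alt_rev={b: numbers[3 + 2 * i] for i, b in enumerate(BASES)},
            )
            try:
                sc.validate(ref)
            except CountsValidationError as exc:
                raise CountsValidationError(
                    f"{path.name} line {lineno} ({chrom}:{pos}): {exc}"
                ) from None
            if key in records:
                raise CountsValidationError(
                    f"{path.name} line {lineno}: duplicate position {chrom}:{pos}"
                )
            records[key] = sc
        if header is None:
            raise CountsParseError(f"{path.name}: empty file, header row required")
    return SampleCounts(sample_id=sample_id or path.stem, records=records)


def write_counts_file(counts: SampleCounts, path: str | Path) -> None:
    """Write a count table in the TSV dialect; inverse of :func:`read_counts_file`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for key, sc in counts:
            row = [key.chrom, str(key.pos), key.ref, str(sc.depth_fwd), str(sc.depth_rev)]
            for base in BASES:
                row.append(str(sc.alt_fwd.get(base, 0)))
                row.append(str(sc.alt_rev.get(base, 0)))
            fh.write("\t".join(row) + "\n")


def read_panel_bed(path: str | Path) -> AmpliconPanel:
    """Load an amplicon panel from a 3+ column BED file."""
    path = Path(path)
    intervals: list[tuple[str, int, int, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CountsParseError(
                    f"{path.name} line {lineno}: BED needs >= 3 columns"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if start < 0 or start >= end:
                raise CountsValidationError(
                    f"{path.name} line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else f"amp{len(intervals) + 1}"
            intervals.append((chrom, start, end, name))
    return AmpliconPanel(intervals=intervals)


def panel_positions(panel: AmpliconPanel, ref_base: str = "A") -> list[PositionKey]:
    """Enumerate the distinct 1-based positions a panel covers.

    Without a reference sequence every position is given ``ref_base``; pass a
    FASTA-backed lookup to downstream code when real reference bases matter.
    """
    seen: dict[tuple[str, int], PositionKey] = {}
    for chrom, start, end, _ in panel.intervals:
        for pos0 in range(start, end):
            seen.setdefault((chrom, pos0 + 1), PositionKey(chrom, pos0 + 1, ref_base))
    return sorted(seen.values(), key=lambda k: (k.chrom, k.pos))


def reference_context(fasta: str | Path, key: PositionKey, window: int) -> str:
    """Uppercase reference bases in ``[pos - window, pos + window]``, clipped to the contig.

    Raises ``LookupError`` when the chromosome is missing or the position lies
    beyond the contig end.
    """
    from pyfaidx import Fasta

    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    if key.chrom not in fa:
        raise LookupError(f"chromosome {key.chrom!r} absent from FASTA")
    contig = fa[key.chrom]
    if key.pos > len(contig):
        raise LookupError(
            f"position {key.pos} beyond end of {key.chrom} (length {len(contig)})"
        )
    lo = max(0, key.pos - 1 - window)
    hi = min(len(contig), key.pos + window)
    return str(contig[lo:hi]).upper()
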