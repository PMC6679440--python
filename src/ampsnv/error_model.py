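"""Background sequencing-error model trained on a panel of normals.

For every genomic position, alternative allele and strand, the background
error rate is the pooled fraction of reads supporting that allele across the
usable normal samples, plus a constant pseudo-count C:

    s = Er / Erd + C

where Er sums the allele's supporting reads and Erd sums the strand depths
over the normals that survive two filters: (i) a normal whose strand-combined
allele fraction exceeds ``vaf_cap`` (default 5%) is dropped for that allele
only — it likely carries a germline variant rather than noise; (ii) a normal
with per-strand depth below ``min_strand_coverage`` (default 100 reads) on
either strand is dropped for all alleles at that position. When the dropped
fraction reaches ``max_unusable_fraction`` (default 2/3) the (position,
allele) is marked non-callable. Without normals a constant-rate model is
available as a fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .counts_io import BASES, PositionKey, SampleCounts

MODEL_FORMAT_VERSION = "1"

MIN_RECOMMENDED_NORMALS = 10


class ModelFormatError(ValueError):
    """An error-model file is truncated, malformed or of the wrong version."""


@dataclass(frozen=True)
class ErrorModelConfig:
    """Parameters of the error estimation.

    pseudo_count
        Additive regulariser C on each estimated rate; acts as an effective
        sensitivity floor for the downstream caller. Fraction, default 0.002.
    vaf_cap
        Allele fractions above this in a normal are treated as germline signal
        rather than noise and excluded. Fraction, default 0.05.
    min_strand_coverage
        Per-strand depth below which a normal is unusable at a position.
        Reads, default 100.
    max_unusable_fraction
        When at least this fraction of normals is unusable for a (position,
        allele), it becomes non-callable. Default 2/3, inclusive.
    constant_rate
        Fallback rate used when no normals are available. Default 0.01.
    """

    pseudo_count: float = 0.002
    vaf_cap: float = 0.05
    min_strand_coverage: int = 100
    max_unusable_fraction: float = 2.0 / 3.0
    constant_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.pseudo_count < 1:
            raise ValueError(f"pseudo_count must be in [0, 1), got {self.pseudo_count}")
        if not 0 < self.vaf_cap < 1:
            raise ValueError(f"vaf_cap must be in (0, 1), got {self.vaf_cap}")
        if self.min_strand_coverage < 0:
            raise ValueError("min_strand_coverage must be >= 0")
        if not 0 < self.max_unusable_fraction <= 1:
            raise ValueError("max_unusable_fraction must be in (0, 1]")
        if not 0 < self.constant_rate < 1:
            raise ValueError(f"constant_rate must be in (0, 1), got {self.constant_rate}")


@dataclass(frozen=True)
class ErrorEntry:
    """Per (position, alternative allele) background-error estimate.

    ``s_fwd``/``s_rev`` are NaN when the entry is non-callable.
    ``max_normal_vaf`` is the largest strand-combined allele fraction observed
    among the usable (noise) normals and feeds the high-noise warning flag.
    """

    s_fwd: float
    s_rev: float
    callable: bool
    max_normal_vaf: float
    n_used: int


@dataclass
class ErrorModel:
    """Position x allele background-error matrix plus its build configuration."""

    config: ErrorModelConfig
    entries: dict[tuple[PositionKey, str], ErrorEntry] = field(default_factory=dict)
    n_normals: int = 0

    def get(self, key: PositionKey, alt: str) -> ErrorEntry | None:
        return self.entries.get((key, alt))

    def positions(self) -> list[PositionKey]:
        seen = {key: None for key, _ in self.entries}
        return sorted(seen, key=lambda k: (k.chrom, k.pos))

    def __len__(self) -> int:
        return len(self.entries)


def estimate_errors(
    normals: list[SampleCounts], config: ErrorModelConfig | None = None
) -> ErrorModel:
    """Train the background-error model on a cohort of normal samples.

    Positions absent from a normal's count table count as unusable for that
    normal. Erd can only be zero when every usable sample has zero depth on a
    strand (possible only with ``min_strand_coverage=0``); such entries are
    marked non-callable since no rate is estimable.
    """
    if not normals:
        raise ValueError("estimate_errors requires at least one normal sample")
    config = config or ErrorModelConfig()
    n = len(normals)
    if n < MIN_RECOMMENDED_NORMALS:
        warnings.warn(
            f"only {n} normal samples supplied; fewer than "
            f"{MIN_RECOMMENDED_NORMALS} normals is likely to give low-quality "
            "error estimates",
            stacklevel=2,
        )

    all_keys: dict[PositionKey, None] = {}
    for sample in normals:
        for key in sample.records:
            all_keys.setdefault(key, None)

    entries: dict[tuple[PositionKey, str], ErrorEntry] = {}
    cutoff = config.max_unusable_fraction * n
    for key in all_keys:
        per_sample = [s.records.get(key) for s in normals]
        # coverage filter applies to all alleles at the position
        covered = [
            sc is not None
            and sc.depth_fwd >= config.min_strand_coverage
            and sc.depth_rev >= config.min_strand_coverage
            for sc in per_sample
        ]
        for alt in BASES:
            if alt == key.ref:
                continue
            usable = [
                sc
                for sc, cov in zip(per_sample, covered)
                if cov and sc.vaf(alt) <= config.vaf_cap
            ]
            n_excluded = n - len(usable)
            er_fwd = sum(sc.alt_fwd.get(alt, 0) for sc in usable)
            er_rev = sum(sc.alt_rev.get(alt, 0) for sc in usable)
            erd_fwd = sum(sc.depth_fwd for sc in usable)
            erd_rev = sum(sc.depth_rev for sc in usable)
            if n_excluded >= cutoff or erd_fwd == 0 or erd_rev == 0:
                entries[(key, alt)] = ErrorEntry(
                    s_fwd=math.nan,
                    s_rev=math.nan,
                    callable=False,
                    max_normal_vaf=0.0,
                    n_used=len(usable),
                )
                continue
            entries[(key, alt)] = ErrorEntry(
                s_fwd=er_fwd / erd_fwd + config.pseudo_count,
                s_rev=er_rev / erd_rev + config.pseudo_count,
                callable=True,
                max_normal_vaf=max(sc.vaf(alt) for sc in usable),
                n_used=len(usable),
            )
    return ErrorModel(config=config, entries=entries, n_normals=n)


def constant_error_model(
    positions: Iterable[PositionKey],
    rate: float | None = None,
    config: ErrorModelConfig | None = None,
) -> ErrorModel:
    """Uniform-rate fallback model for panels without normal samples."""
    config = config or ErrorModelConfig()
    rate = config.constant_rate if rate is None else rate
    if not 0 < rate < 1:
        raise ValueError(f"constant rate must be in (0, 1), got {rate}")
    config = replace(config, constant_rate=rate)
    entries = {
        (key, alt): ErrorEntry(
            s_fwd=rate, s_rev=rate, callable=True, max_normal_vaf=0.0, n_used=0
        )
        for key in positions
        for alt in BASES
        if alt != key.ref
    }
    return ErrorModel(config=config, entries=entries, n_normals=0)


_CONFIG_FIELDS = (
    "pseudo_count",
    "vaf_cap",
    "min_strand_coverage",
    "max_unusable_fraction",
    "constant_rate",
)

_TABLE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "s_fwd",
    "s_rev",
    "callable",
    "max_normal_vaf",
    "n_used",
)


def save_model(model: ErrorModel, path: str | Path) -> None:
    """Serialise a model to a versioned, '#'-headed TSV (round-trip exact)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#ampsnv_error_model\tversion={MODEL_FORMAT_VERSION}\n")
        cfg = "\t".join(
            f"{name}={getattr(model.config, name)!r}" for name in _CONFIG_FIELDS
        )
        fh.write(f"#config\t{cfg}\n")
        fh.write(f"#n_normals\t{model.n_normals}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for (key, alt), e in sorted(
            model.entries.items(), key=lambda kv: (kv[0][0].chrom, kv[0][0].pos, kv[0][1])
        ):
            fh.write(
                "\t".join(
                    (
                        key.chrom,
                        str(key.pos),
                        key.ref,
                        alt,
                        repr(e.s_fwd),
                        repr(e.s_rev),
                        "1" if e.callable else "0",
                        repr(e.max_normal_vaf),
                        str(e.n_used),
                    )
                )
                + "\n"
            )


def load_model(path: str | Path) -> ErrorModel:
    """Load a model written by :func:`save_model`; rejects wrong versions."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#ampsnv_error_model"):
        raise ModelFormatError(f"{path.name}: not an ampsnv error-model file")
    version = lines[0].split("version=", 1)[-1].strip()
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path.name}: model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    if len(lines) < 4:
        raise ModelFormatError(f"{path.name}: truncated model file")
    if not lines[1].startswith("#config\t") or not lines[2].startswith("#n_normals\t"):
        raise ModelFormatError(f"{path.name}: missing config/n_normals headers")
    cfg_tokens = lines[1].split("\t")[1:]
    cfg_kwargs: dict[str, float | int] = {}
    for tok in cfg_tokens:
        name, _, value = tok.partition("=")
        if name not in _CONFIG_FIELDS:
            raise ModelFormatError(f"{path.name}: unknown config field {name!r}")
        cfg_kwargs[name] = int(value) if name == "min_strand_coverage" else float(value)
    config = ErrorModelConfig(**cfg_kwargs)
    n_normals = int(lines[2].split("\t")[1])
    if lines[3].split("\t") != list(_TABLE_COLUMNS):
        raise ModelFormatError(f"{path.name}: unexpected table header")
    entries: dict[tuple[PositionKey, str], ErrorEntry] = {}
    for lineno, line in enumerate(lines[4:], start=5):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(_TABLE_COLUMNS):
            raise ModelFormatError(f"{path.name} line {lineno}: truncated row")
        key = PositionKey(fields[0], int(fields[1]), fields[2])
        entries[(key, fields[3])] = ErrorEntry(
            s_fwd=float(fields[4]),
            s_rev=float(fields[5]),
            callable=fields[6] == "1",
            max_normal_vaf=float(fields[7]),
            n_used=int(fields[8]),
        )
    return ErrorModel(config=config, entries=entries, n_normals=n_normals)
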