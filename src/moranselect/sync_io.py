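"""Reading and writing of sync-format count files and per-locus result tables.

The sync format (popoolation2 dialect) has one line per locus::

    chrom  pos  ref  A:T:C:G:N:del  A:T:C:G:N:del  ...

with one colon-separated count sextet per sequenced sample.  Sample columns
are ordered replicate-within-time-point by default (``time_major``): the
first block holds every replicate at the first time point, and so on.  The
alternative ``replicate_major`` layout (all time points of replicate 1
first) is supported via the ``layout`` argument.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "SyncFormatError",
    "SyncRecord",
    "LocusCounts",
    "LocusResult",
    "RESULT_COLUMNS",
    "LAYOUTS",
    "parse_sync_line",
    "format_sync_record",
    "read_sync",
    "write_sync",
    "to_locus_counts",
    "write_results",
    "read_results",
]

#: order of the counts inside a sextet
SEXTET_BASES = ("A", "T", "C", "G", "N", "del")
#: nucleotide precedence used to break ties when picking the focal allele
BASE_ORDER = ("A", "T", "C", "G")
LAYOUTS = ("time_major", "replicate_major")

_SEXTET_RE = re.compile(r"^\d+:\d+:\d+:\d+:\d+:\d+$")


class SyncFormatError(ValueError):
    """Raised on malformed sync input; carries line/column context."""


@dataclass(frozen=True)
class SyncRecord:
    """One sync line: a locus with per-sample A:T:C:G:N:del count sextets."""

    chrom: str
    pos: int
    ref: str
    samples: tuple  # tuple of 6-tuples of non-negative ints

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be a positive 1-based coordinate, got {self.pos}")
        if self.ref not in ("A", "T", "C", "G", "N"):
            raise ValueError(f"ref must be one of A,T,C,G,N, got {self.ref!r}")
        for i, s in enumerate(self.samples):
            if len(s) != 6:
                raise ValueError(f"sample {i + 1} has {len(s)} counts, expected 6")
            if any(c < 0 for c in s):
                raise ValueError(f"sample {i + 1} has negative counts: {s}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def parse_sync_line(line: str, line_number: Optional[int] = None) -> SyncRecord:
    """Parse one sync line into a :class:`SyncRecord`.

    Raises :class:`SyncFormatError` naming the offending line and column on
    malformed input (wrong field count, non-integer counts, bad sextet).
    """
    where = f" on line {line_number}" if line_number is not None else ""
    fields = line.split()
    if len(fields) < 4:
        raise SyncFormatError(
            f"expected at least 4 whitespace-separated columns{where}, got {len(fields)}"
        )
    chrom, pos_s, ref = fields[0], fields[1], fields[2]
    if not pos_s.isdigit():
        raise SyncFormatError(f"column 2{where}: position {pos_s!r} is not a positive integer")
    sextets = []
    for col, tok in enumerate(fields[3:], start=4):
        if not _SEXTET_RE.match(tok):
            raise SyncFormatError(
                f"column {col}{where}: {tok!r} is not a valid A:T:C:G:N:del count sextet"
            )
        sextets.append(tuple(int(x) for x in tok.split(":")))
    try:
        return SyncRecord(chrom=chrom, pos=int(pos_s), ref=ref, samples=tuple(sextets))
    except ValueError as exc:
        raise SyncFormatError(f"{exc}{where}") from exc


def format_sync_record(rec: SyncRecord) -> str:
    cols = [rec.chrom, str(rec.pos), rec.ref]
    cols.extend(":".join(str(c) for c in s) for s in rec.samples)
    return "\t".join(cols)


def read_sync(path) -> Iterator[SyncRecord]:
    """Yield :class:`SyncRecord` objects from a sync file, skipping blanks."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield parse_sync_line(line, line_number=i)


def write_sync(records: Iterable[SyncRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_sync_record(rec) + "\n")


@dataclass
class LocusCounts:
    """Focal-allele counts and coverages for one locus, replicates x times.

    ``counts[r, t]`` is the focal-allele read count of replicate ``r`` at
    time point ``t`` and ``coverage[r, t]`` the matching biallelic depth
    (focal + reference reads only).  ``generations`` are measured since the
    first sample, so ``generations[0] == 0``.
    """

    chrom: str
    pos: int
    counts: np.ndarray
    coverage: np.ndarray
    generations: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        g = np.asarray(self.generations, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != self.coverage.shape:
            raise ValueError("counts and coverage must be matching 2-D (R, T) arrays")
        if np.any(self.counts < 0) or np.any(self.coverage < 0):
            raise ValueError("counts and coverage must be non-negative")
        if np.any(self.counts > self.coverage):
            raise ValueError("focal count exceeds coverage at some sample")
        if g.ndim != 1 or g.size != self.counts.shape[1]:
            raise ValueError("generations must be 1-D with one entry per time point")
        if np.any(np.diff(g) <= 0):
            raise ValueError("generations must be strictly increasing")
        self.generations = g - g[0]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        """Observed frequencies c/C with NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.counts / self.coverage, np.nan)


def _sample_index(r: int, t: int, R: int, T: int, layout: str) -> int:
    if layout == "time_major":
        return t * R + r
    if layout == "replicate_major":
        return r * T + t
    raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")


def to_locus_counts(
    rec: SyncRecord,
    generations: Sequence[float],
    replicates: int,
    layout: str = "time_major",
    focal: str = "auto",
) -> LocusCounts:
    """Reduce a sync record to biallelic focal/reference counts.

    The focal allele defaults to the non-reference base with the largest
    count summed over all samples, ties broken in fixed A,T,C,G order
    (``focal="auto"``); an explicit base may be forced instead.  Coverage is
    focal + reference reads; other bases, N and del never enter it.
    """
    T = len(generations)
    R = replicates
    if rec.n_samples != R * T:
        raise ValueError(
            f"locus {rec.chrom}:{rec.pos} has {rec.n_samples} samples, "
            f"expected replicates x time points = {R} x {T} = {R * T}"
        )
    sam = np.asarray(rec.samples, dtype=np.int64)  # (R*T, 6)
    if focal == "auto":
        totals = sam[:, :4].sum(axis=0)
        order = [i for i, b in enumerate(BASE_ORDER) if b != rec.ref]
        focal_idx = max(order, key=lambda i: (totals[i], -i))
    else:
        if focal not in BASE_ORDER:
            raise ValueError(f"focal allele must be one of {BASE_ORDER}, got {focal!r}")
        focal_idx = BASE_ORDER.index(focal)
    ref_idx = BASE_ORDER.index(rec.ref) if rec.ref in BASE_ORDER else None

    counts = np.zeros((R, T), dtype=np.int64)
    cover = np.zeros((R, T), dtype=np.int64)
    for r in range(R):
        for t in range(T):
            s = sam[_sample_index(r, t, R, T, layout)]
            c = int(s[focal_idx])
            ref_c = int(s[ref_idx]) if ref_idx is not None else 0
            counts[r, t] = c
            cover[r, t] = c + ref_c
    return LocusCounts(
        chrom=rec.chrom, pos=rec.pos, counts=counts, coverage=cover, generations=generations
    )


@dataclass
class LocusResult:
    """Per-locus posterior summary row.

    Filtered loci keep their place in the output but carry no statistics
    (``None`` markers, written as ``NA``).  Degenerate gamma fits (non
    positive shape or rate) are flagged and report the offending fit but no
    posterior summaries.
    """

    chrom: str
    pos: int
    mean_sigma: Optional[float] = None
    log_bf: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    filtered: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.filtered and any(
            v is not None for v in (self.mean_sigma, self.log_bf, self.alpha, self.beta)
        ):
            raise ValueError("filtered loci must carry no statistics")


RESULT_COLUMNS = ("chrom", "pos", "mean_sigma", "log_BF", "alpha", "beta", "filtered", "degenerate")


def _fmt(v: Optional[float]) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return format(float(v), ".6g")


def write_results(results: Iterable[LocusResult], path, header_lines: Sequence[str] = ()) -> None:
    """Write a tab-separated result table, one row per locus.

    ``header_lines`` are emitted first as ``#``-prefixed comments (used by
    the CLI for seed / config provenance).
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            row = (
                res.chrom,
                str(res.pos),
                _fmt(res.mean_sigma),
                _fmt(res.log_bf),
                _fmt(res.alpha),
                _fmt(res.beta),
                str(int(res.filtered)),
                str(int(res.degenerate)),
            )
            fh.write("\t".join(row) + "\n")


def _parse_opt(tok: str) -> Optional[float]:
    return None if tok == "NA" else float(tok)


def read_results(path) -> list:
    """Read back a result table written by :func:`write_results`."""
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = tuple(line.rstrip("\n").split("\t"))
                if header != RESULT_COLUMNS:
                    raise SyncFormatError(f"unexpected result header {header}")
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                LocusResult(
                    chrom=f[0],
                    pos=int(f[1]),
                    mean_sigma=_parse_opt(f[2]),
                    log_bf=_parse_opt(f[3]),
                    alpha=_parse_opt(f[4]),
                    beta=_parse_opt(f[5]),
                    filtered=bool(int(f[6])),
                    degenerate=bool(int(f[7])),
                )
            )
    return out
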