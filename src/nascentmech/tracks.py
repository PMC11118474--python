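"""Genomic intervals, stranded point-coverage tracks, peaks and count matrices.

PRO-seq (and ChIP/ATAC) signal is handled as base-resolution counts of a
chosen read end (5' or 3') per strand.  The 3' end of a PRO-seq read marks
the RNA polymerase active site; the 5' end marks the transcription start
position.  Tracks are read from / written to plain 4-column bedGraph, one
file per strand; the common PRO-seq dialect that encodes minus-strand
counts as negative values is accepted and recorded.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "TrackPair",
    "Peak",
    "CountMatrix",
    "BedGraphError",
    "read_point_track",
    "write_point_track",
    "count_window",
    "size_factors",
    "differential_signal",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak with a summit position inside the interval."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError("summit must lie within the peak interval")


class BedGraphError(ValueError):
    """Raised for malformed or overlapping bedGraph records."""


@dataclass
class CoverageTrack:
    """Per-chromosome, per-strand base-resolution counts of one read end.

    ``values`` maps chromosome name to a dense int64 array; positions beyond
    the stored array are implicitly zero.
    """

    read_end: str  # {"five_prime", "three_prime"}
    strand: str  # {"+", "-"}
    values: dict[str, np.ndarray] = field(default_factory=dict)
    negative_dialect: bool = False  # minus-strand file used negative values

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base counts over [start, end), zero-padded outside storage."""
        out = np.zeros(end - start, dtype=np.int64)
        arr = self.values.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def add(self, chrom: str, pos: int, count: int = 1) -> None:
        arr = self.values.get(chrom)
        if arr is None or pos >= arr.size:
            new = np.zeros(max(pos + 1, 2 * (arr.size if arr is not None else 256)), dtype=np.int64)
            if arr is not None:
                new[: arr.size] = arr
            self.values[chrom] = new
            arr = new
        arr[pos] += count

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.values.values()))

    def trimmed(self) -> "CoverageTrack":
        """Copy with trailing zeros removed from every chromosome array."""
        vals = {}
        for chrom, arr in self.values.items():
            nz = np.nonzero(arr)[0]
            if nz.size:
                vals[chrom] = arr[: nz[-1] + 1].copy()
        return replace(self, values=vals)


@dataclass
class TrackPair:
    """Plus- and minus-strand tracks of the same read end."""

    plus: CoverageTrack
    minus: CoverageTrack

    @property
    def read_end(self) -> str:
        return self.plus.read_end

    def by_strand(self, strand: str) -> CoverageTrack:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"no track for strand {strand!r}")


def _parse_bedgraph(path: str, strand: str, read_end: str) -> CoverageTrack:
    track = CoverageTrack(read_end=read_end, strand=strand)
    chunks: dict[str, list[tuple[int, int, int]]] = {}
    negative = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: {exc}") from None
            if end <= start or start < 0:
                raise BedGraphError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if value < 0:
                negative = True
                value = -value
            count = int(round(value))
            if abs(value - count) > 1e-6:
                raise BedGraphError(f"{path}:{lineno}: non-integer count {fields[3]}")
            chunks.setdefault(fields[0], []).append((start, end, count))
    for chrom, runs in chunks.items():
        runs.sort()
        for (s1, e1, _), (s2, _, _) in zip(runs, runs[1:]):
            if s2 < e1:
                raise BedGraphError(f"{path}: overlapping intervals on {chrom} at {s2}")
        arr = np.zeros(max(e for _, e, _ in runs), dtype=np.int64)
        for s, e, c in runs:
            arr[s:e] = c
        track.values[chrom] = arr
    track.negative_dialect = negative
    return track


def read_point_track(path_plus: str, path_minus: str, read_end: str) -> TrackPair:
    """Read a pair of single-strand bedGraph files into coverage tracks.

    Minus-strand files may encode counts as negative values; absolute values
    are stored and the dialect recorded for round-trip writing.
    """
    if read_end not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown read_end {read_end!r}")
    return TrackPair(
        plus=_parse_bedgraph(path_plus, "+", read_end),
        minus=_parse_bedgraph(path_minus, "-", read_end),
    )


def _write_bedgraph(track: CoverageTrack, path: str, negate: bool) -> None:
    sign = -1 if negate else 1
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            # runs of identical non-zero values
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{sign * v}\n")


def write_point_track(pair: TrackPair, path_plus: str, path_minus: str) -> None:
    """Write canonical bedGraph (sorted, merged runs, zeros omitted)."""
    _write_bedgraph(pair.plus, path_plus, negate=False)
    _write_bedgraph(pair.minus, path_minus, negate=pair.minus.negative_dialect)


def count_window(tracks: TrackPair, interval: GenomicInterval, mode: str = "same") -> int:
    """Sum per-base counts over the interval under a strand-handling mode.

    mode: "same" counts the interval's own strand, "opposite" the other
    strand, "both" sums the two.  Windows extending beyond the stored
    chromosome emit a clipping warning (out-of-range bases count as zero).
    """
    if mode not in ("same", "opposite", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "both":
        total = 0
        for track in (tracks.plus, tracks.minus):
            total += int(track.get(interval.chrom, interval.start, interval.end).sum())
        return total
    strand = interval.strand
    if strand == ".":
        raise ValueError("stranded counting mode requires a stranded interval")
    if mode == "opposite":
        strand = "-" if strand == "+" else "+"
    track = tracks.by_strand(strand)
    arr = track.values.get(interval.chrom)
    stored = arr.size if arr is not None else 0
    if interval.end > stored:
        warnings.warn(
            f"window {interval.chrom}:{interval.start}-{interval.end} clipped to "
            f"stored length {stored}",
            stacklevel=2,
        )
    return int(track.get(interval.chrom, interval.start, interval.end).sum())


@dataclass
class CountMatrix:
    """Features x samples integer count table with condition labels."""

    features: list[GenomicInterval]
    samples: list[str]
    conditions: list[str]
    counts: np.ndarray  # shape (n_features, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("count matrix dimensions inconsistent with labels")
        if len(self.conditions) != len(self.samples):
            raise ValueError("one condition label per sample required")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def read_bed(path: str) -> list[GenomicInterval]:
    """BED6 (or BED3) intervals; strand defaults to '.'."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_peaks(path: str) -> list[Peak]:
    """Peaks from BED6+1 (summit in column 7) or BED with thickStart summit."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]),
                                 f[5] if len(f) > 5 else ".")
            summit = int(f[6]) if len(f) > 6 else iv.center
            score = float(f[4]) if len(f) > 4 else 0.0
            name = f[3] if len(f) > 3 else ""
            out.append(Peak(interval=iv, summit=summit, score=score, name=name))
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample (column).

    For each feature with all-positive counts, the ratio of each sample's
    count to the feature's geometric mean is formed; the factor is the
    median ratio over those features.  Features containing any zero are
    excluded from the median.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a features x samples matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; add a pseudo-count "
            "or use read-depth size factors"
        )
    sub = counts[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    return np.median(ratios, axis=0)


def differential_signal(
    matrix: CountMatrix,
    factors: np.ndarray,
    condition_trt: str,
    condition_ctrl: str,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
):
    """Per-feature log2 fold change and significance between two conditions.

    log2FC compares mean size-factor-normalized counts with a pseudo-count.
    The p-value comes from a conditional two-sided Poisson rate test
    (binomial test on the summed normalized counts given their total, with
    the null success probability set by the replicate numbers), followed by
    Benjamini-Hochberg adjustment across features.  This is a deliberate
    simplification relative to negative-binomial dispersion modelling.

    Returns a dict of arrays: log2fc, pvalue, padj, significant.
    """
    factors = np.asarray(factors, dtype=float)
    norm = matrix.counts / factors[None, :]
    cond = np.asarray(matrix.conditions)
    trt_cols = cond == condition_trt
    ctrl_cols = cond == condition_ctrl
    if not trt_cols.any() or not ctrl_cols.any():
        raise ValueError("each condition needs at least one replicate")
    mean_trt = norm[:, trt_cols].mean(axis=1)
    mean_ctrl = norm[:, ctrl_cols].mean(axis=1)
    log2fc = np.log2(mean_trt + pseudocount) - np.log2(mean_ctrl + pseudocount)
    both_zero = (mean_trt == 0) & (mean_ctrl == 0)
    log2fc[both_zero] = 0.0

    n_trt = int(trt_cols.sum())
    n_ctrl = int(ctrl_cols.sum())
    p_null = n_trt / (n_trt + n_ctrl)
    k_trt = np.rint(norm[:, trt_cols].sum(axis=1)).astype(int)
    k_ctrl = np.rint(norm[:, ctrl_cols].sum(axis=1)).astype(int)
    totals = k_trt + k_ctrl
    pvals = np.ones(len(totals))
    for i, (k, n) in enumerate(zip(k_trt, totals)):
        if n > 0:
            pvals[i] = stats.binomtest(int(k), int(n), p_null).pvalue
    padj = stats.false_discovery_control(pvals, method="bh")
    return {
        "log2fc": log2fc,
        "pvalue": pvals,
        "padj": padj,
        "significant": padj <= alpha,
    }
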