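"""Prominent-TSS calling, shift detection, matching, and divergent regions.

The 5' ends of PRO-seq reads pile up at sites of transcription initiation.
The most prominent TSS of a gene is the position of the maximum 5' count in
a window around the annotated start; comparing prominent TSSs between
control and treated conditions detects initiation-site shifts.  Because
shift rates are compared between gene classes, a pool of unchanged genes is
matched to the cases by TSS signal intensity.  A simple threshold caller
identifies divergently transcribed (bidirectional) regions from genome-wide
5' tracks; its BED output is interchangeable with external callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nascentmech.tracks import CoverageTrack, GenomicInterval, TrackPair

__all__ = [
    "TssCall",
    "TssShift",
    "BidirectionalRegion",
    "prominent_tss",
    "detect_shift",
    "match_controls",
    "shift_rate_comparison",
    "coupled_redistribution",
    "call_bidirectional",
]

MIN_COUNT = 5  # minimum 5' pileup for a TSS call
MIN_SHIFT = 10  # bases: minimum prominent-TSS movement that counts as a shift


@dataclass
class TssCall:
    gene: str
    position: int
    intensity: int
    window: GenomicInterval | None = None


@dataclass
class TssShift:
    gene: str
    ctrl: TssCall | None
    trt: TssCall | None
    delta: float  # trt - ctrl in gene orientation (+ = downstream); nan if unassessable
    shifted: bool
    assessable: bool
    distance_to_site_ctrl: float = float("nan")
    distance_to_site_trt: float = float("nan")


def prominent_tss(
    track5: CoverageTrack,
    window: GenomicInterval,
    gene: str = "",
    min_count: int = MIN_COUNT,
    smooth: int = 0,
) -> TssCall | None:
    """Position of the maximum 5' pileup in the window, or None if too weak.

    Ties are broken upstream-most in gene orientation.  ``smooth`` > 0
    aggregates counts over +/- that many bases before the argmax (off by
    default; raw pileups are used).
    """
    counts = track5.get(window.chrom, window.start, window.end).astype(float)
    if smooth > 0:
        kernel = np.ones(2 * smooth + 1)
        counts = np.convolve(counts, kernel, mode="same")
    peak = counts.max() if counts.size else 0
    if peak < min_count:
        return None
    at_max = np.nonzero(counts == peak)[0]
    idx = at_max[0] if window.strand != "-" else at_max[-1]
    pos = window.start + int(idx)
    raw = int(track5.get(window.chrom, pos, pos + 1)[0])
    return TssCall(gene=gene, position=pos, intensity=raw, window=window)


def detect_shift(
    ctrl_call: TssCall | None,
    trt_call: TssCall | None,
    strand: str,
    min_shift: int = MIN_SHIFT,
    gene: str = "",
    site_pos: int | None = None,
) -> TssShift:
    """Shift record between conditions; unassessable if either call is missing.

    When ``site_pos`` (a binding-site anchor position) is given, the
    absolute distances from each condition's prominent TSS to the site are
    recorded.
    """
    if ctrl_call is None or trt_call is None:
        return TssShift(gene, ctrl_call, trt_call, float("nan"), False, assessable=False)
    delta = trt_call.position - ctrl_call.position
    if strand == "-":
        delta = -delta
    shift = TssShift(
        gene=gene,
        ctrl=ctrl_call,
        trt=trt_call,
        delta=float(delta),
        shifted=abs(delta) >= min_shift,
        assessable=True,
    )
    if site_pos is not None:
        shift.distance_to_site_ctrl = float(abs(ctrl_call.position - site_pos))
        shift.distance_to_site_trt = float(abs(trt_call.position - site_pos))
    return shift


def match_controls(
    case_intensities: np.ndarray,
    pool_intensities: np.ndarray,
    caliper: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Greedy nearest-neighbour matching on log10 intensity, no replacement.

    Cases are processed in random order under the seed; a case whose nearest
    remaining pool member is farther than ``caliper`` log10 units stays
    unmatched.  Returns (pairs, unmatched_case_indices).
    """
    case = np.log10(np.asarray(case_intensities, dtype=float))
    pool = np.log10(np.asarray(pool_intensities, dtype=float))
    if pool.size == 0:
        raise ValueError("empty control pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(case.size)
    available = np.ones(pool.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for i in order:
        dist = np.abs(pool - case[i])
        dist[~available] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= caliper:
            pairs.append((int(i), j))
            available[j] = False
        else:
            unmatched.append(int(i))
    return pairs, unmatched


def shift_rate_comparison(
    case_shifts: list[TssShift], control_shifts: list[TssShift]
) -> dict:
    """Fraction of shifted genes in each group and their ratio."""
    def rate(shifts: list[TssShift]) -> tuple[float, int]:
        ok = [s for s in shifts if s.assessable]
        if not ok:
            return 0.0, 0
        return sum(s.shifted for s in ok) / len(ok), len(ok)

    rate_case, n_case = rate(case_shifts)
    rate_ctrl, n_ctrl = rate(control_shifts)
    if rate_ctrl > 0:
        ratio, defined = rate_case / rate_ctrl, True
    elif rate_case > 0 and n_ctrl > 0:
        ratio, defined = float("inf"), True
    else:
        ratio, defined = float("nan"), False
    return {
        "rate_case": rate_case,
        "rate_ctrl": rate_ctrl,
        "n_case": n_case,
        "n_ctrl": n_ctrl,
        "ratio": ratio,
        "ratio_defined": defined,
    }


def coupled_redistribution(
    track5_ctrl: CoverageTrack,
    track5_trt: CoverageTrack,
    chrom: str,
    ctrl_pos: int,
    trt_pos: int,
    halfwidth: int = 5,
    sf_ctrl: float = 1.0,
    sf_trt: float = 1.0,
) -> tuple[float, float]:
    """Normalized treated-minus-control 5' signal at each prominent TSS.

    A coupled redistribution (initiation moving from the control TSS to a
    new one) shows as a negative change at the control position and a
    positive change at the treated position.
    """
    def window_delta(pos: int) -> float:
        lo, hi = pos - halfwidth, pos + halfwidth + 1
        c = track5_ctrl.get(chrom, lo, hi).sum() / sf_ctrl
        t = track5_trt.get(chrom, lo, hi).sum() / sf_trt
        return float(t - c)

    return window_delta(ctrl_pos), window_delta(trt_pos)


@dataclass
class BidirectionalRegion:
    interval: GenomicInterval
    center: int
    plus_count: int
    minus_count: int
    plus_max_pos: int
    minus_max_pos: int


def call_bidirectional(
    tracks5: TrackPair,
    min_reads: int = 5,
    max_span: int = 300,
    window: int = 500,
    step: int = 100,
) -> list[BidirectionalRegion]:
    """Divergent-transcription regions from genome-wide 5' tracks.

    Windows of ``window`` bases slide by ``step``; a window qualifies when
    both strands have at least ``min_reads`` 5' counts, the maxima are in
    divergent orientation (minus-strand peak upstream of the plus-strand
    peak) and at most ``max_span`` bases apart.  Overlapping qualifying
    windows are merged; the region center is the midpoint of the opposing
    maxima.
    """
    regions: list[BidirectionalRegion] = []
    chroms = sorted(set(tracks5.plus.values) | set(tracks5.minus.values))
    for chrom in chroms:
        n = max(
            tracks5.plus.values.get(chrom, np.zeros(0)).size,
            tracks5.minus.values.get(chrom, np.zeros(0)).size,
        )
        if n == 0:
            continue
        plus = tracks5.plus.get(chrom, 0, n)
        minus = tracks5.minus.get(chrom, 0, n)
        qual: list[tuple[int, int]] = []
        for start in range(0, max(1, n - window + 1), step):
            end = min(start + window, n)
            p = plus[start:end]
            m = minus[start:end]
            if p.sum() < min_reads or m.sum() < min_reads:
                continue
            p_pos = start + int(np.argmax(p))
            m_pos = start + int(np.argmax(m))
            if m_pos < p_pos and (p_pos - m_pos) <= max_span:
                qual.append((start, end))
        # merge overlapping windows
        merged: list[list[int]] = []
        for s, e in qual:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            p = plus[s:e]
            m = minus[s:e]
            p_pos = s + int(np.argmax(p))
            m_pos = s + int(np.argmax(m))
            regions.append(
                BidirectionalRegion(
                    interval=GenomicInterval(chrom, s, e, "."),
                    center=(p_pos + m_pos) // 2,
                    plus_count=int(p.sum()),
                    minus_count=int(m.sum()),
                    plus_max_pos=p_pos,
                    minus_max_pos=m_pos,
                )
            )
    return regions
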