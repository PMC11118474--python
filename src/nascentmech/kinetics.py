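"""Pause/body quantification and compartment-model rate inference.

RNA polymerase II transcription is modelled as two compartments: polymerase
enters the promoter-proximal pause at initiation rate alpha, leaves it into
the gene body at pause-release rate beta (or is lost to premature
termination at rate gamma), and elongates at velocity v.  At steady state
the pause occupancy is P* = alpha / (beta + gamma) and the per-base body
occupancy is proportional to alpha / v with body flux beta * P*.

With gamma fixed to 0 and v assumed unchanged by treatment, fold changes in
the observed densities identify fold changes in the rates:

    dlog2_init    = log2(B1 / B0)
    dlog2_release = log2((B1 / P1) / (B0 / P0))

where P is the summed, size-factor-normalized 3' count in the pause window
and B the mean per-base normalized 3' count in the gene body.  A decrease
in apparent initiation is algebraically indistinguishable from an increase
in premature termination; every estimate carries this caveat flag.
dlog2_release is exactly the negated change in pausing index (P/B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nascentmech.tracks import GenomicInterval, TrackPair, count_window

__all__ = [
    "GeneWindows",
    "PauseBodyDensity",
    "RateChange",
    "make_gene_windows",
    "quantify_pause_body",
    "rate_changes",
    "fit_all_genes",
]

PAUSE_WIDTH = 100  # bases downstream of the TSS in the pause window
BODY_START = 500  # body window starts this far downstream of the TSS
BODY_CAP = 30_000  # body window truncated at this length


@dataclass(frozen=True)
class GeneWindows:
    """Pause and gene-body quantification windows for one gene."""

    gene: str
    chrom: str
    tss: int
    end: int  # gene end (exclusive, in gene orientation)
    strand: str
    pause: GenomicInterval
    body: GenomicInterval | None  # None when the gene is too short


def make_gene_windows(
    gene: str,
    chrom: str,
    tss: int,
    gene_end: int,
    strand: str,
    pause_width: int = PAUSE_WIDTH,
    body_start: int = BODY_START,
    body_cap: int = BODY_CAP,
) -> GeneWindows:
    """Build disjoint pause and body windows in gene orientation."""
    if strand == "+":
        pause = GenomicInterval(chrom, tss, tss + pause_width, "+")
        b_lo = tss + body_start
        b_hi = min(gene_end, b_lo + body_cap)
        body = GenomicInterval(chrom, b_lo, b_hi, "+") if b_hi > b_lo else None
    elif strand == "-":
        pause = GenomicInterval(chrom, tss - pause_width + 1, tss + 1, "-")
        b_hi = tss - body_start + 1
        b_lo = max(gene_end, b_hi - body_cap)
        body = GenomicInterval(chrom, b_lo, b_hi, "-") if b_hi > b_lo else None
    else:
        raise ValueError("gene strand must be + or -")
    return GeneWindows(gene, chrom, tss, gene_end, strand, pause, body)


@dataclass
class PauseBodyDensity:
    P: float  # normalized summed pause counts
    B: float  # normalized mean per-base body counts
    flagged: bool = False  # zero signal or missing body window


def quantify_pause_body(
    track3: TrackPair, windows: GeneWindows, size_factor: float = 1.0
) -> PauseBodyDensity:
    """Normalized pause sum and body per-base mean from same-strand 3' counts."""
    if windows.body is None:
        return PauseBodyDensity(0.0, 0.0, flagged=True)
    p = count_window(track3, windows.pause, mode="same") / size_factor
    b_total = count_window(track3, windows.body, mode="same") / size_factor
    b = b_total / windows.body.width
    return PauseBodyDensity(P=p, B=b, flagged=(p == 0 and b == 0))


@dataclass
class RateChange:
    gene: str
    dlog2_init: float
    dlog2_release: float
    caveat: bool = True  # init decrease confounded with termination increase
    excluded: bool = False
    exclusion_reason: str = ""


def rate_changes(
    P0: float, B0: float, P1: float, B1: float, gene: str = ""
) -> RateChange:
    """Per-gene rate fold changes from control (0) and treated (1) densities."""
    if min(P0, B0, P1, B1) <= 0:
        return RateChange(
            gene, np.nan, np.nan, excluded=True,
            exclusion_reason="zero pause or body density in one condition",
        )
    dinit = float(np.log2(B1 / B0))
    drelease = float(np.log2((B1 / P1) / (B0 / P0)))
    return RateChange(gene, dinit, drelease)


def fit_all_genes(
    tracks_ctrl: list[TrackPair],
    tracks_trt: list[TrackPair],
    windows_list: list[GeneWindows],
    factors_ctrl: list[float] | None = None,
    factors_trt: list[float] | None = None,
) -> pd.DataFrame:
    """Rate changes for every gene, pooling normalized replicates per condition.

    Each replicate is divided by its size factor and the normalized counts
    summed across replicates before densities are formed.  Returns a table
    with gene, P0, B0, P1, B1, dlog2_init, dlog2_release, caveat and
    exclusion columns.
    """
    factors_ctrl = factors_ctrl or [1.0] * len(tracks_ctrl)
    factors_trt = factors_trt or [1.0] * len(tracks_trt)

    def pooled(tracks: list[TrackPair], factors: list[float], windows: GeneWindows):
        P = B = 0.0
        flagged = False
        for track, sf in zip(tracks, factors):
            d = quantify_pause_body(track, windows, sf)
            P += d.P
            B += d.B
            flagged = flagged or d.flagged
        return P, B, flagged

    rows = []
    for w in windows_list:
        if w.body is None:
            rows.append(
                dict(gene=w.gene, P0=np.nan, B0=np.nan, P1=np.nan, B1=np.nan,
                     dlog2_init=np.nan, dlog2_release=np.nan, caveat=True,
                     excluded=True, exclusion_reason="empty body window")
            )
            continue
        P0, B0, _ = pooled(tracks_ctrl, factors_ctrl, w)
        P1, B1, _ = pooled(tracks_trt, factors_trt, w)
        rc = rate_changes(P0, B0, P1, B1, gene=w.gene)
        rows.append(
            dict(gene=w.gene, P0=P0, B0=B0, P1=P1, B1=B1,
                 dlog2_init=rc.dlog2_init, dlog2_release=rc.dlog2_release,
                 caveat=rc.caveat, excluded=rc.excluded,
                 exclusion_reason=rc.exclusion_reason)
        )
    return pd.DataFrame(rows)
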