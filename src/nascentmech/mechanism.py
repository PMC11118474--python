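"""Gene-class proximity analysis and the cis-repression mechanism classifier.

An activator that binds DNA and stimulates initiation can nonetheless
repress a gene in cis, depending on where its binding site sits relative to
the gene's initiation site:

* **TSS occlusion** — the site covers the prominent TSS itself, competing
  with polymerase for the initiator;
* **molecular roadblock** — the site sits within 500 bases downstream of
  the TSS, impeding early elongation (optionally accompanied by reduced
  genic bidirectional transcription at the site);
* **downstream-element occlusion** — an upstream-bound site covers the
  downstream promoter element (DPE, +27..+32 of the post-depletion TSS) or
  a YY1 motif in the +1..+300 zone, so depletion exposes the element and
  shifts initiation upstream;
* **activator competition** — the site overlaps a high-conformity motif of
  another initiation factor family (SP/KLF, ETS, NRF1, bZIP, YY1), which
  can take over the element once the repressing factor leaves.

Rules are evaluated in a documented precedence order; every satisfied label
is reported alongside the primary call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nascentmech.motifs import BindingSite, MotifModel, scan
from nascentmech.tracks import GenomicInterval
from nascentmech.tss import TssCall, TssShift

__all__ = [
    "GeneRecord",
    "OverlapRecord",
    "MechanismCall",
    "nearest_site_distance",
    "proximity_summary",
    "competition_scan",
    "dse_check",
    "classify_mechanism",
]

PROXIMITY = 500  # bases: "local" binding window around the TSS
DPE_WINDOW = (27, 32)  # downstream promoter element, relative to the TSS
YY1_ZONE = (1, 300)  # YY1 initiation-motif zone downstream of the TSS
YY1_P = 1e-4
Q_MIN = 0.99  # conformity quantile required for a competition call
MAX_SEARCH = 1_000_000
PARTNER_FAMILIES = ("SP/KLF", "ETS", "NRF1", "bZIP", "YY1")

MECHANISM_LABELS = (
    "tss_occlusion",
    "roadblock",
    "roadblock_bidirectional",
    "dse_occlusion",
    "competition_sp1",
    "competition_other",
    "unexplained",
    "no_local_site",
)


@dataclass
class GeneRecord:
    gene: str
    gene_class: str  # {"up", "down", "unchanged_matched"}
    tss: int
    strand: str
    chrom: str
    site: BindingSite | None = None
    expression: float = float("nan")

    def __post_init__(self) -> None:
        if self.gene_class not in ("up", "down", "unchanged_matched"):
            raise ValueError(f"unknown gene class {self.gene_class!r}")


@dataclass
class OverlapRecord:
    znf_site: GenomicInterval
    partner_name: str
    family: str
    partner_interval: GenomicInterval
    overlap_bases: int
    conformity_quantile: float
    score: float


@dataclass
class MechanismCall:
    gene: str
    labels: list[str]
    primary: str
    evidence: list = field(default_factory=list)


def nearest_site_distance(
    tss: int,
    strand: str,
    site_centers: np.ndarray,
    max_search: int = MAX_SEARCH,
) -> float | None:
    """Signed distance to the nearest site center; negative = upstream.

    ``site_centers`` are centers on the gene's chromosome, any order.
    Returns None when the nearest site is farther than ``max_search``.
    """
    centers = np.sort(np.asarray(site_centers))
    if centers.size == 0:
        return None
    idx = np.searchsorted(centers, tss)
    cands = centers[max(0, idx - 1) : idx + 1]
    nearest = int(cands[np.argmin(np.abs(cands - tss))])
    dist = nearest - tss
    if strand == "-":
        dist = -dist
    if abs(dist) > max_search:
        return None
    return float(dist)


def proximity_summary(
    classes: list[str], distances: list[float | None], d: float = PROXIMITY
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-class fraction of genes with a site within d bases, plus ECDF table."""
    if d <= 0:
        raise ValueError("d must be positive")
    df = pd.DataFrame({"gene_class": classes, "distance": [
        np.inf if x is None else abs(x) for x in distances
    ]})
    fractions = {
        cls: float((sub["distance"] <= d).mean())
        for cls, sub in df.groupby("gene_class")
    }
    ecdf = (
        df.sort_values("distance")
        .assign(rank=lambda t: t.groupby("gene_class").cumcount() + 1)
        .assign(ecdf=lambda t: t["rank"] / t.groupby("gene_class")["gene_class"].transform("size"))
    )
    return fractions, ecdf


_NULL_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def _null_best_scores(motif: MotifModel, length: int, n_random: int, seed: int) -> np.ndarray:
    """Sorted best-window scores of random background sequences.

    Each of ``n_random`` i.i.d. background sequences has the same length as
    the scanned region; its score is the best window score over both
    strands, matching the statistic recorded for a hit.
    """
    key = (id(motif), length, n_random, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        W = motif.width
        m = max(length - W + 1, 1)
        codes = rng.choice(4, size=(n_random, max(length, W)), p=motif.background)
        lo = motif.log_odds()[:, :4]
        lo_rc = lo[::-1, ::-1]
        fwd = np.zeros((n_random, m))
        rev = np.zeros((n_random, m))
        for w in range(W):
            col = codes[:, w : w + m]
            fwd += lo[w, col]
            rev += lo_rc[w, col]
        best = np.maximum(fwd.max(axis=1), rev.max(axis=1))
        _NULL_CACHE[key] = np.sort(best)
    return _NULL_CACHE[key]


def competition_scan(
    site: GenomicInterval,
    genome: dict[str, str],
    motif_library: list[tuple[str, MotifModel]],
    n_random: int = 1_000_000,
    seed: int = 0,
    flank: int = 10,
) -> list[OverlapRecord]:
    """Partner motifs overlapping the binding site, with conformity quantiles.

    The site plus ``flank`` bases on each side is scanned with every partner
    PWM (both strands, no p-value cutoff); the best-scoring hit that shares
    at least one base with the site is recorded.  Its conformity quantile is
    the rank of the hit score among the best-window scores of ``n_random``
    i.i.d. background sequences of the same length as the scanned region.
    """
    if not motif_library:
        raise ValueError("empty partner motif library")
    seq = genome[site.chrom]
    lo = max(0, site.start - flank)
    hi = min(len(seq), site.end + flank)
    window = seq[lo:hi]
    records: list[OverlapRecord] = []
    for family, motif in motif_library:
        hits = scan(motif, window, p_threshold=1.0, chrom=site.chrom, offset=lo)
        best = None
        for h in hits:
            if h.site.overlap(site) >= 1 and (best is None or h.score > best.score):
                best = h
        if best is None:
            continue
        null = _null_best_scores(motif, hi - lo, n_random, seed)
        quantile = float(np.searchsorted(null, best.score, side="right") / null.size)
        records.append(
            OverlapRecord(
                znf_site=site,
                partner_name=motif.name,
                family=family,
                partner_interval=best.site,
                overlap_bases=best.site.overlap(site),
                conformity_quantile=quantile,
                score=best.score,
            )
        )
    return records


def dse_check(
    trt_tss: int,
    strand: str,
    site: GenomicInterval,
    genome: dict[str, str],
    yy1_motif: MotifModel | None = None,
    dpe_window: tuple[int, int] = DPE_WINDOW,
    yy1_zone: tuple[int, int] = YY1_ZONE,
    yy1_p: float = YY1_P,
) -> dict[str, bool]:
    """Does the site occlude the DPE or a YY1 motif of the post-depletion TSS?

    Positions are gene-oriented: the DPE window is +27..+32 downstream of
    the treated prominent TSS; the YY1 zone is +1..+300.  ``dpe_occluded``
    is positional (the site covers any DPE base); ``yy1_occluded`` requires
    a YY1 hit at p <= ``yy1_p`` inside both the site and the zone.
    """
    if strand == "+":
        dpe_lo, dpe_hi = trt_tss + dpe_window[0], trt_tss + dpe_window[1] + 1
        zone_lo, zone_hi = trt_tss + yy1_zone[0], trt_tss + yy1_zone[1] + 1
    else:
        dpe_lo, dpe_hi = trt_tss - dpe_window[1], trt_tss - dpe_window[0] + 1
        zone_lo, zone_hi = trt_tss - yy1_zone[1], trt_tss - yy1_zone[0] + 1
    dpe_occluded = max(site.start, dpe_lo) < min(site.end, dpe_hi)

    yy1_occluded = False
    if yy1_motif is not None:
        seq = genome[site.chrom][site.start : site.end]
        for h in scan(yy1_motif, seq, yy1_p, chrom=site.chrom, offset=site.start):
            in_zone = max(h.site.start, zone_lo) < min(h.site.end, zone_hi)
            if in_zone:
                yy1_occluded = True
                break
    return {"dpe_occluded": dpe_occluded, "yy1_occluded": yy1_occluded}


def classify_mechanism(
    record: GeneRecord,
    ctrl_call: TssCall | None,
    shift: TssShift | None,
    bidir_change: tuple[float, bool] | None = None,
    overlaps: list[OverlapRecord] | None = None,
    sp1_increased: bool | None = None,
    dse_flags: dict[str, bool] | None = None,
    proximity: int = PROXIMITY,
    q_min: float = Q_MIN,
) -> MechanismCall:
    """Assign cis-repression mechanism labels to an up-regulated gene.

    The gate requires an up gene with an assigned site within ``proximity``
    bases of the control prominent TSS; otherwise the call is
    ``no_local_site``.  Rules run in precedence order (TSS occlusion >
    roadblock > DSE occlusion > competition), accumulating every satisfied
    label; the primary label is the first satisfied.  Missing evidence for
    a rule skips that rule and is noted in the evidence list.
    """
    evidence: list = []
    ctrl_tss = ctrl_call.position if ctrl_call is not None else record.tss
    site = record.site
    if record.gene_class != "up" or site is None:
        return MechanismCall(record.gene, ["no_local_site"], "no_local_site", evidence)
    dist = site.interval.center - ctrl_tss
    if record.strand == "-":
        dist = -dist
    if abs(dist) > proximity:
        evidence.append(("site_distance", dist))
        return MechanismCall(record.gene, ["no_local_site"], "no_local_site", evidence)

    labels: list[str] = []

    # 1. site covers the control prominent TSS
    if site.interval.contains(ctrl_tss):
        labels.append("tss_occlusion")
        evidence.append(("tss_in_site", ctrl_tss))

    # 2. site center downstream of the TSS
    if 0 < dist <= proximity:
        labels.append("roadblock")
        evidence.append(("site_downstream", dist))
        if bidir_change is not None:
            log2fc, significant = bidir_change
            if significant and log2fc < 0:
                labels.append("roadblock_bidirectional")
                evidence.append(("bidirectional_decrease", log2fc))
        else:
            evidence.append(("bidirectional_change", "not assessed"))

    # 3. site center upstream of the TSS
    if -proximity <= dist < 0:
        handled = False
        # (a) treated TSS shifted upstream of the site + occluded element
        if shift is not None and shift.assessable and dse_flags is not None:
            trt_pos = shift.trt.position
            upstream_of_site = (
                trt_pos < site.interval.start
                if record.strand == "+"
                else trt_pos >= site.interval.end
            )
            if upstream_of_site and (dse_flags.get("dpe_occluded") or dse_flags.get("yy1_occluded")):
                labels.append("dse_occlusion")
                evidence.append(("dse_flags", dict(dse_flags)))
                handled = True
        elif shift is None or dse_flags is None:
            evidence.append(("dse_rule", "not assessed"))
        # (b) high-conformity partner motif overlap
        if not handled and overlaps:
            best = max(overlaps, key=lambda o: o.conformity_quantile)
            if best.conformity_quantile >= q_min:
                sp = [
                    o for o in overlaps
                    if o.family == "SP/KLF" and o.conformity_quantile >= q_min
                ]
                if sp and sp1_increased:
                    labels.append("competition_sp1")
                    evidence.append(("sp1_overlap", sp[0]))
                else:
                    labels.append("competition_other")
                    evidence.append(("partner_overlap", best))
                handled = True
        if not handled and not labels:
            labels.append("unexplained")

    if not labels:
        labels.append("unexplained")

    precedence = [
        "tss_occlusion",
        "roadblock",
        "dse_occlusion",
        "competition_sp1",
        "competition_other",
        "unexplained",
    ]
    primary = next(p for p in precedence if p in labels)
    return MechanismCall(record.gene, labels, primary, evidence)
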