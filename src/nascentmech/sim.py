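"""Synthetic degron time-course generator with ground truth.

Emulates the statistical structure of a rapid-depletion nascent-
transcription experiment: a genome with binding sites drawn column-wise
from a degenerate composite PWM, stranded base-resolution PRO-seq 5'/3'
tracks for control and depleted conditions (pause peak + uniform gene-body
3' coverage, TSS-concentrated 5' coverage), ChIP-like peak intensities with
>95% signal depletion after treatment, and per-gene rate perturbations
organized by regulatory mechanism class:

* ``down`` genes carry an upstream promoter site and lose initiation upon
  depletion (planted negative dlog2 initiation);
* ``up`` genes gain transcription upon depletion through one of the planted
  cis-repression mechanisms (TSS occlusion, molecular roadblock with or
  without genic bidirectional transcription, downstream-element occlusion
  with an upstream TSS shift, or activator competition with an overlapping
  partner motif);
* ``unchanged`` genes have no local site and no planted effect.

Steady-state read counts are Poisson per compartment; an event-driven
(Gillespie-style) mode samples initiation events and exponential pause
dwells instead and serves as an oracle independent of the steady-state
algebra used by the rate estimator.  All randomness flows from the config
seed; identical configs produce identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nascentmech.motifs import MotifModel
from nascentmech.sequence import decode, encode, revcomp, write_fasta
from nascentmech.tracks import (
    CountMatrix,
    CoverageTrack,
    GenomicInterval,
    Peak,
    TrackPair,
    write_point_track,
)

__all__ = [
    "SimConfig",
    "SimData",
    "default_site_motif",
    "make_planted_motif",
    "builtin_partner_library",
    "simulate_genome",
    "simulate_proseq",
    "simulate_chip",
    "write_outputs",
]

MECHANISMS = (
    "tss_occlusion",
    "roadblock",
    "roadblock_bidirectional",
    "dse_occlusion",
    "competition_sp1",
    "competition_other",
)


def _consensus_pwm(consensus: str, p: float = 0.85, name: str = "pwm",
                   background=None) -> MotifModel:
    codes = encode(consensus)
    theta = np.full((codes.size, 4), (1 - p) / 3)
    theta[np.arange(codes.size), codes] = p
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    try:
        from nascentmech.motifs import locate_core

        co, exact = locate_core(MotifModel("tmp", theta, bg))
    except ValueError:
        co, exact = None, True
    return MotifModel(name, theta, bg, co, exact)


def builtin_partner_library() -> list[tuple[str, MotifModel]]:
    """Idealized consensus PWMs for the promoter-factor families.

    These are synthetic single-consensus idealizations of the SP/KLF, ETS,
    NRF1, bZIP and YY1 family motifs, not database matrices; they are meant
    for simulated genomes and for tests.
    """
    return [
        ("SP/KLF", _consensus_pwm("GGGGCGGGGC", name="SP1")),
        ("ETS", _consensus_pwm("ACCGGAAGTG", name="ETS")),
        ("NRF1", _consensus_pwm("GCGCATGCGC", name="NRF1")),
        ("bZIP", _consensus_pwm("TGACGTCA", name="CREB")),
        ("YY1", _consensus_pwm("CAAGATGGCG", name="YY1")),
    ]


def default_site_motif(name: str = "composite29") -> MotifModel:
    """Degenerate 29-column site model anchored on a central TGGGA core.

    The core pentamer is nearly invariant; flanking columns carry moderate
    information that tapers toward the edges, mimicking a composite motif
    whose base frequencies decay to the genomic background outside the
    29-mer.
    """
    return make_planted_motif(29, core_offset=12, seed=20240515, name=name)


def make_planted_motif(
    width: int,
    core_offset: int | None = None,
    seed: int = 7,
    name: str = "planted",
    core: str = "TGGGA",
) -> MotifModel:
    """Composite-style PWM of a given width with a strong central core.

    Flank columns have a random dominant base with probability declining
    from 0.65 next to the core to 0.40 at the edges (total-variation
    distance from uniform background 0.2-0.53, comfortably above the
    composite width-calling tolerance).
    """
    if core_offset is None:
        core_offset = (width - len(core)) // 2
    if not (0 <= core_offset <= width - len(core)):
        raise ValueError("core does not fit at core_offset")
    rng = np.random.default_rng(seed)
    theta = np.zeros((width, 4))
    core_codes = encode(core)
    half_span = max(core_offset, width - core_offset - len(core))
    for j in range(width):
        if core_offset <= j < core_offset + len(core):
            theta[j] = 0.02 / 3
            theta[j, core_codes[j - core_offset]] = 0.98
        else:
            dist = j - (core_offset + len(core) - 1) if j >= core_offset else core_offset - j
            p = 0.65 - 0.25 * min(1.0, dist / max(half_span, 1))
            dom = rng.integers(0, 4)
            theta[j] = (1 - p) / 3
            theta[j, dom] = p
    theta /= theta.sum(axis=1, keepdims=True)
    return MotifModel(name, theta, np.full(4, 0.25), core_offset)


@dataclass
class SimConfig:
    """Parameters of the simulated experiment; the seed is mandatory."""

    seed: int
    # cohort composition
    n_down: int = 60
    n_up_tss_occlusion: int = 8
    n_up_roadblock: int = 12
    n_up_roadblock_bidirectional: int = 6
    n_up_dse: int = 8
    n_up_competition_sp1: int = 8
    n_up_competition_other: int = 6
    n_unchanged: int = 60
    n_extra_sites: int = 20
    motifless_peak_fraction: float = 0.05
    # geometry
    gene_length: int = 4000
    gene_spacing: int = 9000
    chrom: str = "chrS"
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    site_motif: MotifModel | None = None
    # rates (expected read counts at depth 1)
    pause_reads: float = 400.0  # d * alpha / beta: expected pause-window 3' reads
    body_per_base: float = 2.0  # d * alpha / v: expected 3' reads per body base
    five_prime_reads: float = 120.0  # expected 5' reads per gene
    pause_window: tuple = (20, 60)
    tss_halfwidth: int = 10  # TSS weight vectors are 21-point distributions
    n_replicates: int = 2
    depth: float = 1.0
    # treatment effects
    down_init_range: tuple = (-2.0, -0.5)
    down_release_sd: float = 0.25
    up_init_range: tuple = (0.5, 1.5)
    tss_shift_prob_bound: float = 0.5  # down genes redistributing their TSS
    tss_shift_prob_background: float = 0.15
    tss_shift_range: tuple = (15, 60)
    roadblock_body_factor: float = 0.25  # control-only suppression past the site
    divergent_promoter_reads: float = 30.0
    genic_bidir_reads: float = 40.0
    genic_bidir_trt_factor: float = 0.3
    # ChIP
    chip_mean: float = 200.0
    chip_lognorm_sd: float = 0.5
    chip_residual: float = 0.03  # <5% of signal remains bound after depletion
    sp1_mean: float = 150.0
    sp1_gain_range: tuple = (0.7, 1.5)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.motifless_peak_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if min(self.pause_reads, self.body_per_base, self.five_prime_reads) <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SimData:
    """Genome, gene/site ground truth and (after simulation) tracks."""

    config: SimConfig
    genome: dict[str, str]
    genes: pd.DataFrame
    sites: pd.DataFrame
    peaks: list[Peak]
    tss_weights: dict[str, dict[str, np.ndarray]]  # gene -> condition -> 21 weights
    tracks: dict | None = None  # condition -> replicate -> {"three": TrackPair, "five": TrackPair}
    chip: dict | None = None


def _weight_vector(halfwidth: int, rng: np.random.Generator) -> np.ndarray:
    """21-point TSS weight vector: a dominant mode with geometric shoulders."""
    n = 2 * halfwidth + 1
    w = 0.4 ** np.abs(np.arange(n) - halfwidth).astype(float)
    w *= rng.uniform(0.8, 1.2, size=n)
    return w / w.sum()


def _oriented(tss: int, strand: str, offset: int) -> int:
    """Genomic position of a gene-oriented offset (downstream positive)."""
    return tss + offset if strand == "+" else tss - offset


def simulate_genome(config: SimConfig) -> SimData:
    """Background genome with planted sites, gene table and ground truth."""
    rng = np.random.default_rng(config.seed)
    motif = config.site_motif or default_site_motif()
    W = motif.width
    core_off = motif.core_offset or 0

    classes = (
        ["down"] * config.n_down
        + ["tss_occlusion"] * config.n_up_tss_occlusion
        + ["roadblock"] * config.n_up_roadblock
        + ["roadblock_bidirectional"] * config.n_up_roadblock_bidirectional
        + ["dse_occlusion"] * config.n_up_dse
        + ["competition_sp1"] * config.n_up_competition_sp1
        + ["competition_other"] * config.n_up_competition_other
        + ["unchanged"] * config.n_unchanged
    )
    rng.shuffle(classes)
    n_genes = len(classes)
    chrom_len = (n_genes + 1) * config.gene_spacing + config.n_extra_sites * 400 + 2000
    codes = rng.choice(4, size=chrom_len, p=np.asarray(config.background))
    partner = dict((f, m) for f, m in builtin_partner_library())

    gene_rows = []
    site_rows = []
    tss_weights: dict[str, dict[str, np.ndarray]] = {}
    occupied: list[tuple[int, int]] = []

    def plant(start: int, seq_codes: np.ndarray, strand: str) -> str:
        """Write a draw at ``start``; returns the motif-oriented sequence."""
        oriented = decode(seq_codes)
        if strand == "-":
            seq_codes = encode(revcomp(oriented))
        codes[start : start + seq_codes.size] = seq_codes
        return oriented

    def draw_site() -> np.ndarray:
        return np.array([rng.choice(4, p=motif.theta[j]) for j in range(W)], dtype=np.int8)

    for i, mech in enumerate(classes):
        gene = f"g{i:04d}"
        slot = (i + 1) * config.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = slot + 3000
            gene_end = tss + config.gene_length
        else:
            tss = slot + 3000 + config.gene_length
            gene_end = tss - config.gene_length
        gene_class = (
            "down" if mech == "down" else "unchanged" if mech == "unchanged" else "up"
        )

        # treatment effects
        if gene_class == "down":
            dinit = rng.uniform(*config.down_init_range)
            drelease = rng.normal(0.0, config.down_release_sd)
        elif gene_class == "up":
            dinit = rng.uniform(*config.up_init_range)
            drelease = 0.0
        else:
            dinit = drelease = 0.0

        # site geometry in gene-oriented offsets (downstream positive)
        site_lo_orient = None  # gene-oriented offset of the motif's 5'-most base
        trt_tss_offset = 0
        if mech == "down" or mech.startswith("competition"):
            site_lo_orient = -int(rng.integers(60, 300)) - W
        elif mech == "tss_occlusion":
            site_lo_orient = -int(rng.integers(5, W - 5))
        elif mech == "roadblock":
            site_lo_orient = int(rng.integers(80, 450)) - W // 2
        elif mech == "roadblock_bidirectional":
            # genic divergent initiation must be separable from the promoter
            site_lo_orient = int(rng.integers(200, 450)) - W // 2
        elif mech == "dse_occlusion":
            u = -int(rng.integers(40, 120))
            site_lo_orient = u
            trt_tss_offset = u - 28  # exposed TSS 28 bases upstream of the site

        site_record = None
        if site_lo_orient is not None:
            seq_codes = draw_site()
            if mech.startswith("competition"):
                pcons = "GGGGCGGGGC" if mech == "competition_sp1" else "ACCGGAAGTG"
                pcodes = encode(pcons)
                mid = (W - pcodes.size) // 2
                seq_codes[mid : mid + pcodes.size] = pcodes
            if mech == "dse_occlusion":
                ycodes = encode("CAAGATGGCG")
                seq_codes[10 : 10 + ycodes.size] = ycodes
            if strand == "+":
                start = tss + site_lo_orient
            else:
                start = tss - site_lo_orient - W
            written = plant(start, seq_codes, strand)
            site_record = dict(
                chrom=config.chrom, start=start, end=start + W, strand=strand,
                gene=gene, mechanism=mech, planted_seq=written,
                affinity=float(config.chip_mean * rng.lognormal(0.0, config.chip_lognorm_sd)),
            )
            site_rows.append(site_record)

        # TSS weight vectors per condition
        w_ctrl = _weight_vector(config.tss_halfwidth, rng)
        if mech == "dse_occlusion":
            shift = trt_tss_offset
        elif mech == "down" and rng.random() < config.tss_shift_prob_bound:
            shift = int(rng.integers(*config.tss_shift_range)) * (1 if rng.random() < 0.5 else -1)
        elif gene_class == "unchanged" and rng.random() < config.tss_shift_prob_background:
            shift = int(rng.integers(*config.tss_shift_range)) * (1 if rng.random() < 0.5 else -1)
        else:
            shift = 0
        w_trt = _weight_vector(config.tss_halfwidth, rng) if shift != 0 else w_ctrl
        tss_weights[gene] = {"control": w_ctrl, "treated": w_trt}

        gene_rows.append(dict(
            gene=gene, chrom=config.chrom, strand=strand, tss=tss, gene_end=gene_end,
            gene_class=gene_class, mechanism=mech,
            dlog2_init=dinit, dlog2_release=drelease,
            site_start=(site_record["start"] if site_record else -1),
            site_end=(site_record["end"] if site_record else -1),
            trt_tss=_oriented(tss, strand, (trt_tss_offset if mech == "dse_occlusion" else shift)),
            tss_shifted=bool(shift != 0),
        ))

    # intergenic sites in the tail region
    tail0 = (n_genes + 1) * config.gene_spacing
    for k in range(config.n_extra_sites):
        for _attempt in range(100):
            start = tail0 + k * 400 + int(rng.integers(50, 300))
            if all(not (start < e and start + W > s) for s, e in occupied):
                break
        else:
            raise RuntimeError("could not place intergenic site without collision")
        occupied.append((start, start + W))
        strand = "+" if rng.random() < 0.5 else "-"
        written = plant(start, draw_site(), strand)
        site_rows.append(dict(
            chrom=config.chrom, start=start, end=start + W, strand=strand,
            gene="", mechanism="intergenic", planted_seq=written,
            affinity=float(config.chip_mean * rng.lognormal(0.0, config.chip_lognorm_sd)),
        ))

    sites = pd.DataFrame(site_rows)
    genes = pd.DataFrame(gene_rows)
    genome = {config.chrom: decode(codes)}

    peaks = []
    for _, s in sites.iterrows():
        center = (s.start + s.end) // 2
        peaks.append(Peak(
            interval=GenomicInterval(s.chrom, max(0, center - 100), center + 100, "."),
            summit=int(center), score=float(s.affinity), name=f"peak_{len(peaks)}",
        ))
    n_motifless = int(round(len(peaks) * config.motifless_peak_fraction / (1 - config.motifless_peak_fraction)))
    for k in range(n_motifless):
        center = tail0 + config.n_extra_sites * 400 + 120 * (k + 1)
        peaks.append(Peak(
            interval=GenomicInterval(config.chrom, center - 100, center + 100, "."),
            summit=center, score=float(config.chip_mean), name=f"peak_{len(peaks)}",
        ))

    return SimData(config=config, genome=genome, genes=genes, sites=sites,
                   peaks=peaks, tss_weights=tss_weights)


def simulate_peak_set(
    n_peaks: int = 1000,
    planted_fraction: float = 0.6,
    motif: MotifModel | None = None,
    peak_length: int = 200,
    seed: int = 0,
    background=None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Peak-window sequences with motif instances planted in a fraction.

    Returns (sequences, core_positions, strands): ``core_positions[i]`` is
    the 0-based start of the planted core pentamer within peak i (forward
    coordinates; -1 when nothing was planted) and ``strands[i]`` the
    planted strand ("." when none).  Instances are drawn column-wise from
    the motif and placed uniformly away from the edges.
    """
    rng = np.random.default_rng(seed)
    motif = motif or default_site_motif()
    W = motif.width
    co = motif.core_offset or 0
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    n_planted = int(round(n_peaks * planted_fraction))
    seqs: list[str] = []
    core_pos = np.full(n_peaks, -1, dtype=np.int64)
    strands = np.full(n_peaks, ".", dtype=object)
    for i in range(n_peaks):
        codes = rng.choice(4, size=peak_length, p=bg).astype(np.int8)
        if i < n_planted:
            start = int(rng.integers(10, peak_length - W - 10))
            inst = np.array([rng.choice(4, p=motif.theta[j]) for j in range(W)], dtype=np.int8)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = encode(revcomp(decode(inst)))
            codes[start : start + W] = inst
            # central cores map to the same forward offset on either strand
            core_pos[i] = start + (co if strand == "+" else W - co - 5)
            strands[i] = strand
        seqs.append(decode(codes))
    order = rng.permutation(n_peaks)
    return (
        [seqs[i] for i in order],
        core_pos[order],
        strands[order],
    )


def _empty_pair(read_end: str, chrom: str, length: int) -> TrackPair:
    return TrackPair(
        plus=CoverageTrack(read_end, "+", {chrom: np.zeros(length, dtype=np.int64)}),
        minus=CoverageTrack(read_end, "-", {chrom: np.zeros(length, dtype=np.int64)}),
    )


def simulate_proseq(data: SimData, mode: str = "poisson", seed_offset: int = 1) -> SimData:
    """Fill in stranded 5'/3' tracks for both conditions and all replicates.

    ``mode="poisson"`` draws steady-state Poisson counts per compartment;
    ``mode="gillespie"`` draws initiation events and exponential pause
    dwells per gene and converts occupancy into reads, providing an
    independent oracle for rate-recovery tests.
    """
    if mode not in ("poisson", "gillespie"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = data.config
    rng = np.random.default_rng(cfg.seed + seed_offset)
    chrom = cfg.chrom
    length = len(data.genome[chrom])
    tracks: dict = {}
    p_lo, p_hi = cfg.pause_window
    n_pause = p_hi - p_lo + 1
    hw = cfg.tss_halfwidth

    for condition in ("control", "treated"):
        tracks[condition] = {}
        for rep in range(cfg.n_replicates):
            three = _empty_pair("three_prime", chrom, length)
            five = _empty_pair("five_prime", chrom, length)
            for _, g in data.genes.iterrows():
                sgn = 1 if g.strand == "+" else -1
                trt = condition == "treated"
                a_fac = 2.0 ** g.dlog2_init if trt else 1.0
                b_fac = 2.0 ** g.dlog2_release if trt else 1.0
                lam_pause = cfg.depth * cfg.pause_reads * a_fac / b_fac
                lam_body = cfg.depth * cfg.body_per_base * a_fac
                lam_five = cfg.depth * cfg.five_prime_reads * a_fac

                body_positions = np.arange(p_hi + 1, cfg.gene_length)
                if mode == "poisson":
                    n_p = rng.poisson(lam_pause)
                    body_counts = rng.poisson(lam_body, size=body_positions.size)
                else:
                    # event-driven: initiation events + exponential pause dwells
                    A = 1000
                    n_init = rng.poisson(A)
                    beta_c = b_fac
                    dwell = rng.exponential(1.0 / beta_c, size=n_init).sum()
                    n_p = rng.poisson(dwell * beta_c / A * lam_pause)
                    body_counts = rng.poisson(n_init / A * lam_body, size=body_positions.size)

                # roadblock: control-only suppression downstream of the site
                if g.mechanism in ("roadblock", "roadblock_bidirectional") and not trt:
                    site_off = abs((g.site_start + g.site_end) // 2 - g.tss)
                    past = body_positions > site_off
                    body_counts[past] = rng.binomial(body_counts[past], cfg.roadblock_body_factor)

                track3 = three.by_strand(g.strand)
                arr3 = track3.values[chrom]
                if n_p > 0:
                    offs = rng.integers(p_lo, p_hi + 1, size=n_p)
                    np.add.at(arr3, g.tss + sgn * offs, 1)
                pos3 = g.tss + sgn * body_positions
                arr3[pos3] += body_counts

                # 5' reads from the condition's TSS weight vector
                weights = data.tss_weights[g.gene][condition]
                anchor = g.trt_tss if trt else g.tss
                n5 = rng.poisson(lam_five)
                if n5 > 0:
                    draws = rng.multinomial(n5, weights)
                    offs5 = np.arange(-hw, hw + 1)
                    arr5 = five.by_strand(g.strand).values[chrom]
                    np.add.at(arr5, anchor + sgn * offs5, draws)

                # promoter divergent transcription (antisense upstream)
                anti = five.by_strand("-" if g.strand == "+" else "+")
                nanti = rng.poisson(cfg.depth * cfg.divergent_promoter_reads)
                if nanti > 0:
                    apos = g.tss - sgn * (110 + rng.integers(-5, 6, size=nanti))
                    np.add.at(anti.values[chrom], apos, 1)

                # genic bidirectional transcription at roadblock sites
                if g.mechanism == "roadblock_bidirectional":
                    center = (g.site_start + g.site_end) // 2
                    fac = cfg.genic_bidir_trt_factor if trt else 1.0
                    lam = cfg.depth * cfg.genic_bidir_reads * fac
                    for strand5, offset in (("-", -40), ("+", +40)):
                        nb = rng.poisson(lam)
                        if nb > 0:
                            bpos = center + offset + rng.integers(-3, 4, size=nb)
                            np.add.at(five.by_strand(strand5).values[chrom], bpos, 1)

            tracks[condition][rep] = {"three": three, "five": five}
    data.tracks = tracks
    return data


def simulate_chip(data: SimData, seed_offset: int = 2) -> SimData:
    """ChIP-like peak intensities per condition, plus SP1 partner peaks.

    Control counts are Poisson around each site's planted affinity;
    treatment counts keep only ``chip_residual`` of the mean, enforcing the
    near-complete chromatin depletion of the degraded factor.  SP1 peaks at
    SP-competition sites gain signal after treatment.
    """
    cfg = data.config
    rng = np.random.default_rng(cfg.seed + seed_offset)
    n_sites = len(data.sites)
    znf = {
        "control": rng.poisson(data.sites.affinity.to_numpy()[:, None],
                               size=(n_sites, cfg.n_replicates)),
        "treated": rng.poisson(cfg.chip_residual * data.sites.affinity.to_numpy()[:, None],
                               size=(n_sites, cfg.n_replicates)),
    }
    sp1_rows = []
    for idx, s in data.sites.iterrows():
        if s.mechanism == "competition_sp1":
            gain = 2.0 ** rng.uniform(*cfg.sp1_gain_range)
            ctrl = rng.poisson(cfg.sp1_mean, size=cfg.n_replicates)
            trt = rng.poisson(cfg.sp1_mean * gain, size=cfg.n_replicates)
            sp1_rows.append(dict(site_index=idx, gene=s.gene,
                                 ctrl=ctrl.tolist(), trt=trt.tolist(), gain=gain))
    data.chip = {"znf": znf, "sp1": pd.DataFrame(sp1_rows)}
    return data


def write_outputs(data: SimData, outdir: str) -> dict[str, str]:
    """Write FASTA, BEDs, bedGraphs and truth tables; returns path map."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    fa = os.path.join(outdir, "genome.fa")
    write_fasta(data.genome, fa)
    paths["genome"] = fa

    sites_bed = os.path.join(outdir, "sites.bed")
    with open(sites_bed, "w") as fh:
        for _, s in data.sites.iterrows():
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.mechanism or 'site'}\t0\t{s.strand}\n")
    paths["sites"] = sites_bed

    peaks_bed = os.path.join(outdir, "peaks.bed")
    with open(peaks_bed, "w") as fh:
        for p in data.peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:.1f}\t.\t{p.summit}\n"
            )
    paths["peaks"] = peaks_bed

    genes_tsv = os.path.join(outdir, "genes.tsv")
    data.genes.to_csv(genes_tsv, sep="\t", index=False)
    paths["genes"] = genes_tsv

    if data.tracks is not None:
        for condition, reps in data.tracks.items():
            for rep, ends in reps.items():
                for end_name, pair in ends.items():
                    base = os.path.join(outdir, f"{condition}_rep{rep}_{end_name}")
                    write_point_track(pair, base + "_plus.bedgraph", base + "_minus.bedgraph")
                    paths[f"{condition}_rep{rep}_{end_name}"] = base
    return paths
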