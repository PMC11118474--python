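"""End-to-end orchestration: sim -> motifs -> kinetics -> tss -> mechanism.

Every stage is a plain function over the library types so the pipeline can
be run whole (``run_pipeline``), resumed per stage, or reassembled in a
notebook.  Outputs are TSV/BED/bedGraph text files plus a JSON manifest
with SHA-256 checksums; identical configs and seeds give identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from nascentmech import kinetics as kin
from nascentmech import mechanism as mech
from nascentmech import tss as tssmod
from nascentmech.motifs import (
    BindingSite,
    CompositeMotif,
    HIT_P_THRESHOLD,
    IterativeResult,
    MotifHit,
    assign_binding_site,
    composite_motif,
    iterative_discovery,
    scan,
)
from nascentmech.sim import (
    SimConfig,
    SimData,
    builtin_partner_library,
    simulate_chip,
    simulate_genome,
    simulate_proseq,
    write_outputs,
)
from nascentmech.tracks import (
    CountMatrix,
    CoverageTrack,
    GenomicInterval,
    Peak,
    TrackPair,
    count_window,
    differential_signal,
)

__all__ = [
    "pool_pairs",
    "tss_table",
    "discover_and_assign",
    "bidirectional_changes",
    "mechanism_table",
    "run_pipeline",
]


def pool_pairs(pairs: list[TrackPair]) -> TrackPair:
    """Sum replicate tracks into one pair (counts are added per base)."""
    first = pairs[0]
    out = TrackPair(
        plus=CoverageTrack(first.read_end, "+", {}),
        minus=CoverageTrack(first.read_end, "-", {}),
    )
    for pair in pairs:
        for src, dst in ((pair.plus, out.plus), (pair.minus, out.minus)):
            for chrom, arr in src.values.items():
                if chrom in dst.values:
                    n = max(dst.values[chrom].size, arr.size)
                    merged = np.zeros(n, dtype=np.int64)
                    merged[: dst.values[chrom].size] = dst.values[chrom]
                    merged[: arr.size] += arr
                    dst.values[chrom] = merged
                else:
                    dst.values[chrom] = arr.copy()
    return out


def tss_table(
    data: SimData,
    window_halfwidth: int = 500,
    min_count: int = tssmod.MIN_COUNT,
    min_shift: int = tssmod.MIN_SHIFT,
) -> pd.DataFrame:
    """Prominent-TSS calls per condition and the shift record per gene."""
    five_ctrl = pool_pairs([data.tracks["control"][r]["five"] for r in data.tracks["control"]])
    five_trt = pool_pairs([data.tracks["treated"][r]["five"] for r in data.tracks["treated"]])
    rows = []
    for _, g in data.genes.iterrows():
        window = GenomicInterval(
            g.chrom, max(0, g.tss - window_halfwidth), g.tss + window_halfwidth + 1, g.strand
        )
        ctrl = tssmod.prominent_tss(five_ctrl.by_strand(g.strand), window, g.gene, min_count)
        trt = tssmod.prominent_tss(five_trt.by_strand(g.strand), window, g.gene, min_count)
        shift = tssmod.detect_shift(ctrl, trt, g.strand, min_shift, g.gene)
        rows.append(dict(
            gene=g.gene,
            ctrl_pos=(ctrl.position if ctrl else -1),
            ctrl_intensity=(ctrl.intensity if ctrl else 0),
            trt_pos=(trt.position if trt else -1),
            trt_intensity=(trt.intensity if trt else 0),
            delta=shift.delta,
            shifted=shift.shifted,
            assessable=shift.assessable,
        ))
    return pd.DataFrame(rows)


def discover_and_assign(
    peaks: list[Peak],
    genome: dict[str, str],
    W: int = 15,
    seed: int = 0,
    p_threshold: float = HIT_P_THRESHOLD,
    max_rounds: int = 6,
    **discover_kwargs,
) -> tuple[IterativeResult, CompositeMotif, list[BindingSite | None]]:
    """Iterative discovery on peak sequences, composite build, site assignment.

    Peaks keep genome coordinates throughout: discovery runs on the peak
    windows, the composite motif is averaged over the best genome-scanned
    hit of every peak, and each peak's binding site is the lowest-p-value
    hit repositioned at the composite width (None for motif-less peaks).
    """
    seqs = [genome[p.interval.chrom][p.interval.start : p.interval.end] for p in peaks]
    result = iterative_discovery(
        seqs, W, max_rounds=max_rounds, p_threshold=p_threshold, seed=seed, **discover_kwargs
    )
    best_hits: list[MotifHit | None] = []
    for p in peaks:
        cands: list[MotifHit] = []
        for m in result.motifs:
            cands.extend(
                scan(m, genome[p.interval.chrom][p.interval.start : p.interval.end],
                     p_threshold, chrom=p.interval.chrom, offset=p.interval.start)
            )
        if cands:
            cands.sort(key=lambda h: (h.pvalue, abs(h.site.center - p.summit), h.site.start))
            best_hits.append(cands[0])
        else:
            best_hits.append(None)
    usable = [h for h in best_hits if h is not None]
    if not usable:
        raise ValueError("no peak produced a motif hit; cannot build a composite")
    composite = composite_motif(usable, genome)
    scan_set = result.motifs + [composite.motif]
    sites = [
        assign_binding_site(p, scan_set, composite, genome, p_threshold)
        for p in peaks
    ]
    return result, composite, sites


def bidirectional_changes(
    data: SimData, regions: list[GenomicInterval], alpha: float = 0.05
) -> pd.DataFrame:
    """Differential divergent transcription (both-strand 5' counts) per region."""
    samples, conditions, columns = [], [], []
    for condition in ("control", "treated"):
        for rep in data.tracks[condition]:
            pair = data.tracks[condition][rep]["five"]
            col = [count_window(pair, r, mode="both") for r in regions]
            columns.append(col)
            samples.append(f"{condition}_rep{rep}")
            conditions.append(condition)
    counts = np.array(columns).T
    cm = CountMatrix(features=list(regions), samples=samples, conditions=conditions,
                     counts=counts)
    res = differential_signal(cm, np.ones(len(samples)), "treated", "control", alpha=alpha)
    return pd.DataFrame({
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "log2fc": res["log2fc"],
        "padj": res["padj"],
        "significant": res["significant"],
    })


def _truth_site(g) -> BindingSite | None:
    if g.site_start < 0:
        return None
    iv = GenomicInterval(g.chrom, int(g.site_start), int(g.site_end), g.strand)
    return BindingSite(interval=iv, pvalue=0.0, motif_name="planted")


def mechanism_table(
    data: SimData,
    tss_calls: pd.DataFrame,
    sites: list[BindingSite] | None = None,
    n_random: int = 10_000,
    seed: int = 0,
    q_min: float = mech.Q_MIN,
    proximity: int = mech.PROXIMITY,
) -> pd.DataFrame:
    """Mechanism labels for every gene from tracks, sites and ChIP evidence.

    ``sites`` defaults to the simulator's planted sites; pass assigned sites
    from ``discover_and_assign`` to run the classification on inferred
    binding positions instead.
    """
    library = builtin_partner_library()
    yy1 = dict(library)["YY1"]
    calls = tss_calls.set_index("gene")

    # nearest site per gene when an explicit assignment list is given
    site_by_gene: dict[str, BindingSite | None] = {}
    if sites is None:
        for _, g in data.genes.iterrows():
            site_by_gene[g.gene] = _truth_site(g)
    else:
        centers = np.array([s.interval.center for s in sites if s is not None])
        pool = [s for s in sites if s is not None]
        order = np.argsort(centers)
        centers = centers[order]
        pool = [pool[i] for i in order]
        for _, g in data.genes.iterrows():
            if centers.size == 0:
                site_by_gene[g.gene] = None
                continue
            idx = np.searchsorted(centers, g.tss)
            cands = [pool[j] for j in range(max(0, idx - 1), min(len(pool), idx + 1))]
            best = min(cands, key=lambda s: abs(s.interval.center - g.tss))
            site_by_gene[g.gene] = (
                best if abs(best.interval.center - g.tss) <= proximity else None
            )

    # genic bidirectional differential at downstream sites
    bidir_genes = data.genes[
        data.genes.mechanism.isin(["roadblock", "roadblock_bidirectional"])
    ]
    regions, region_genes = [], []
    for _, g in bidir_genes.iterrows():
        center = (int(g.site_start) + int(g.site_end)) // 2
        regions.append(GenomicInterval(g.chrom, center - 100, center + 100, "."))
        region_genes.append(g.gene)
    bidir = {}
    if regions:
        table = bidirectional_changes(data, regions)
        for gene, (_, row) in zip(region_genes, table.iterrows()):
            bidir[gene] = (float(row.log2fc), bool(row.significant))

    # SP1 differential per gene (simulated partner ChIP)
    sp1_up: dict[str, bool] = {}
    if data.chip is not None and len(data.chip["sp1"]):
        for _, row in data.chip["sp1"].iterrows():
            sp1_up[row.gene] = float(np.mean(row.trt)) > float(np.mean(row.ctrl))

    rows = []
    for _, g in data.genes.iterrows():
        c = calls.loc[g.gene]
        ctrl_call = (
            tssmod.TssCall(g.gene, int(c.ctrl_pos), int(c.ctrl_intensity), None)
            if c.ctrl_pos >= 0 else None
        )
        trt_call = (
            tssmod.TssCall(g.gene, int(c.trt_pos), int(c.trt_intensity), None)
            if c.trt_pos >= 0 else None
        )
        shift = tssmod.detect_shift(ctrl_call, trt_call, g.strand, gene=g.gene)
        site = site_by_gene[g.gene]
        record = mech.GeneRecord(
            gene=g.gene, gene_class=("up" if g.gene_class == "up" else
                                     "down" if g.gene_class == "down" else "unchanged_matched"),
            tss=int(g.tss), strand=g.strand, chrom=g.chrom, site=site,
        )
        overlaps = None
        dse_flags = None
        if site is not None and record.gene_class == "up":
            overlaps = mech.competition_scan(
                site.interval, data.genome, library, n_random=n_random, seed=seed
            )
            if shift.assessable:
                dse_flags = mech.dse_check(
                    trt_call.position, g.strand, site.interval, data.genome, yy1
                )
        call = mech.classify_mechanism(
            record, ctrl_call, shift,
            bidir_change=bidir.get(g.gene),
            overlaps=overlaps,
            sp1_increased=sp1_up.get(g.gene),
            dse_flags=dse_flags,
            proximity=proximity,
            q_min=q_min,
        )
        rows.append(dict(
            gene=g.gene, gene_class=g.gene_class, true_mechanism=g.mechanism,
            labels=",".join(call.labels), primary=call.primary,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config-driven end-to-end run
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "pipeline_out",
    "sim": {},  # SimConfig overrides
    "motifs": {"width": 15, "p_threshold": HIT_P_THRESHOLD, "enabled": True},
    "tss": {"min_count": tssmod.MIN_COUNT, "min_shift": tssmod.MIN_SHIFT},
    "mechanism": {"n_random": 10_000, "q_min": mech.Q_MIN, "proximity": mech.PROXIMITY},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def run_pipeline(config: dict, outdir: str | None = None) -> dict:
    """Run sim -> motifs -> kinetics -> tss -> mechanism; return the manifest."""
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = outdir or cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])

    sim_cfg = SimConfig(seed=seed, **cfg["sim"])
    data = simulate_genome(sim_cfg)
    data = simulate_proseq(data)
    data = simulate_chip(data)
    paths = write_outputs(data, outdir)

    files: dict[str, str] = {k: v for k, v in paths.items() if os.path.isfile(v)}

    # kinetics
    windows = [
        kin.make_gene_windows(g.gene, g.chrom, g.tss, g.gene_end, g.strand)
        for _, g in data.genes.iterrows()
    ]
    ctrl3 = [data.tracks["control"][r]["three"] for r in data.tracks["control"]]
    trt3 = [data.tracks["treated"][r]["three"] for r in data.tracks["treated"]]
    rates = kin.fit_all_genes(ctrl3, trt3, windows)
    rates_path = os.path.join(outdir, "rate_changes.tsv")
    rates.to_csv(rates_path, sep="\t", index=False)
    files["rate_changes"] = rates_path

    # tss
    tss_calls = tss_table(data, min_count=cfg["tss"]["min_count"],
                          min_shift=cfg["tss"]["min_shift"])
    tss_path = os.path.join(outdir, "tss_calls.tsv")
    tss_calls.to_csv(tss_path, sep="\t", index=False)
    files["tss_calls"] = tss_path

    five_ctrl = pool_pairs([data.tracks["control"][r]["five"] for r in data.tracks["control"]])
    bidir_regions = tssmod.call_bidirectional(five_ctrl)
    bidir_path = os.path.join(outdir, "bidirectional_regions.bed")
    with open(bidir_path, "w") as fh:
        for r in bidir_regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"bidir\t{r.plus_count + r.minus_count}\t.\t{r.center}\n"
            )
    files["bidirectional_regions"] = bidir_path

    # motifs (optional stage)
    sites = None
    if cfg["motifs"].get("enabled", True):
        result, composite, assigned = discover_and_assign(
            data.peaks, data.genome, W=int(cfg["motifs"]["width"]), seed=seed,
            p_threshold=float(cfg["motifs"]["p_threshold"]),
        )
        sites = assigned
        sites_path = os.path.join(outdir, "assigned_sites.bed")
        with open(sites_path, "w") as fh:
            for peak, s in zip(data.peaks, assigned):
                if s is None:
                    continue
                iv = s.interval
                score = int(round(min(999.0, -10 * np.log10(max(s.pvalue, 1e-99)))))
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.motif_name}\t{score}\t{iv.strand}\n")
        files["assigned_sites"] = sites_path
        from nascentmech.motifs import write_meme

        meme_path = os.path.join(outdir, "motifs.meme")
        write_meme(result.motifs + [composite.motif], meme_path)
        files["motifs"] = meme_path

    # mechanism (on planted sites; assigned sites are written alongside)
    mech_tab = mechanism_table(
        data, tss_calls, sites=None,
        n_random=int(cfg["mechanism"]["n_random"]), seed=seed,
        q_min=float(cfg["mechanism"]["q_min"]),
        proximity=int(cfg["mechanism"]["proximity"]),
    )
    mech_path = os.path.join(outdir, "mechanisms.tsv")
    mech_tab.to_csv(mech_path, sep="\t", index=False)
    files["mechanisms"] = mech_path

    summary = (
        mech_tab[mech_tab.gene_class == "up"].groupby("primary").size().to_dict()
    )
    manifest = {
        "seed": seed,
        "files": {k: {"path": os.path.relpath(v, outdir), "sha256": _sha256(v)}
                  for k, v in sorted(files.items())},
        "mechanism_summary": summary,
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
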