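"""Proximity analysis and the cis-repression mechanism classifier."""

import numpy as np
import pytest

from nascentmech.mechanism import (
    GeneRecord,
    classify_mechanism,
    competition_scan,
    dse_check,
    nearest_site_distance,
    proximity_summary,
)
from nascentmech.motifs import BindingSite
from nascentmech.sequence import random_sequence, revcomp
from nascentmech.sim import builtin_partner_library
from nascentmech.tracks import GenomicInterval
from nascentmech.tss import TssCall, detect_shift

LIBRARY = builtin_partner_library()
YY1 = dict(LIBRARY)["YY1"]


class TestNearestSite:
    def test_site_on_tss_gives_zero(self):
        assert nearest_site_distance(1000, "+", np.array([1000])) == 0

    def test_upstream_site_is_negative(self):
        assert nearest_site_distance(1000, "+", np.array([700])) == -300
        assert nearest_site_distance(1000, "-", np.array([1300])) == -300

    def test_beyond_max_search_is_none(self):
        assert nearest_site_distance(0, "+", np.array([2_000_000])) is None

    def test_matches_linear_scan_oracle(self, rng):
        centers = np.sort(rng.integers(0, 10_000_000, 500))
        for _ in range(1000):
            tss = int(rng.integers(0, 10_000_000))
            strand = "+" if rng.random() < 0.5 else "-"
            got = nearest_site_distance(tss, strand, centers)
            best = min(centers, key=lambda c: abs(c - tss))
            expect = (best - tss) * (1 if strand == "+" else -1)
            if abs(expect) > 1_000_000:
                assert got is None
            else:
                assert got == expect


class TestProximitySummary:
    def test_all_zero_distances(self):
        frac, _ = proximity_summary(["up", "down"], [0.0, 0.0], d=500)
        assert frac == {"up": 1.0, "down": 1.0}

    def test_all_beyond_d(self):
        frac, _ = proximity_summary(["up", "up"], [900.0, -1200.0], d=500)
        assert frac["up"] == 0.0

    def test_planted_truth_separates_classes(self, sim_data):
        genes = sim_data.genes
        centers = np.sort(
            ((sim_data.sites.start + sim_data.sites.end) // 2).to_numpy()
        )
        classes, dists = [], []
        for _, g in genes.iterrows():
            if g.gene_class not in ("down", "unchanged"):
                continue
            classes.append("down" if g.gene_class == "down" else "unchanged_matched")
            dists.append(nearest_site_distance(g.tss, g.strand, centers))
        frac, _ = proximity_summary(classes, dists, d=500)
        assert frac["down"] >= 0.95
        assert frac["unchanged_matched"] <= 0.3


class TestCompetitionScan:
    def test_planted_sp1_consensus_scores_top_quantile(self, rng):
        seq = random_sequence(2000, rng)
        site = GenomicInterval("chr1", 900, 929, "+")
        seq = seq[:909] + "GGGGCGGGGC" + seq[919:]
        records = competition_scan(site, {"chr1": seq}, LIBRARY, n_random=10_000, seed=0)
        sp = [r for r in records if r.family == "SP/KLF"]
        assert sp and sp[0].conformity_quantile >= 0.999
        assert sp[0].overlap_bases == 10

    def test_overlap_base_arithmetic(self):
        a = GenomicInterval("chr1", 100, 129)
        b = GenomicInterval("chr1", 125, 135)
        assert a.overlap(b) == 4

    def test_empty_library_rejected(self, rng):
        site = GenomicInterval("chr1", 10, 39)
        with pytest.raises(ValueError, match="library"):
            competition_scan(site, {"chr1": random_sequence(100, rng)}, [])

    def test_random_sites_rarely_reach_top_quantile(self):
        n_high = 0
        for seed in range(10):
            r = np.random.default_rng(3000 + seed)
            seq = random_sequence(400, r)
            site = GenomicInterval("chr1", 180, 209, "+")
            recs = competition_scan(site, {"chr1": seq}, LIBRARY, n_random=10_000, seed=seed)
            n_high += sum(rec.conformity_quantile >= 0.999 for rec in recs)
        assert n_high <= 2


class TestDseCheck:
    def test_site_covering_dpe_window(self, rng):
        seq = random_sequence(2000, rng)
        tss = 1000
        site = GenomicInterval("chr1", tss + 28, tss + 33, "+")
        flags = dse_check(tss, "+", site, {"chr1": seq}, None)
        assert flags["dpe_occluded"]

    def test_yy1_consensus_inside_site_and_zone(self, rng):
        seq = random_sequence(2000, rng)
        tss = 1000
        site = GenomicInterval("chr1", tss + 30, tss + 59, "+")
        seq = seq[:tss + 40] + "CAAGATGGCG" + seq[tss + 50:]
        flags = dse_check(tss, "+", site, {"chr1": seq}, YY1)
        assert flags["yy1_occluded"]

    def test_minus_strand_orientation(self, rng):
        seq = random_sequence(2000, rng)
        tss = 1000
        # downstream of a minus-strand TSS means smaller coordinates
        site = GenomicInterval("chr1", tss - 33, tss - 27, "-")
        assert dse_check(tss, "-", site, {"chr1": seq}, None)["dpe_occluded"]

    def test_upstream_site_is_negative_for_both(self, rng):
        seq = random_sequence(2000, rng)
        tss = 1000
        site = GenomicInterval("chr1", tss - 200, tss - 171, "+")
        flags = dse_check(tss, "+", site, {"chr1": seq}, YY1)
        assert not flags["dpe_occluded"] and not flags["yy1_occluded"]


def _record(tss=10_000, strand="+", site_span=None, gene_class="up"):
    site = None
    if site_span is not None:
        site = BindingSite(
            interval=GenomicInterval("chr1", site_span[0], site_span[1], strand),
            pvalue=1e-6, motif_name="m",
        )
    return GeneRecord("g", gene_class, tss, strand, "chr1", site)


def _shift(ctrl, trt, strand="+"):
    return detect_shift(TssCall("g", ctrl, 20), TssCall("g", trt, 20), strand)


class TestClassifier:
    def test_site_spanning_tss_is_occlusion(self):
        rec = _record(site_span=(9990, 10_019))
        call = classify_mechanism(rec, TssCall("g", 10_000, 30), _shift(10_000, 10_000))
        assert call.primary == "tss_occlusion"
        assert "tss_occlusion" in call.labels

    def test_downstream_site_with_bidir_loss_is_roadblock(self):
        rec = _record(site_span=(10_186, 10_215))
        call = classify_mechanism(
            rec, TssCall("g", 10_000, 30), _shift(10_000, 10_000),
            bidir_change=(-1.5, True),
        )
        assert call.primary == "roadblock"
        assert set(call.labels) >= {"roadblock", "roadblock_bidirectional"}

    def test_upstream_site_with_shift_and_dpe_is_dse_occlusion(self):
        site = (9_900, 9_929)
        rec = _record(site_span=site)
        # treated TSS 28 bases upstream of the site start; DPE falls in the site
        call = classify_mechanism(
            rec, TssCall("g", 10_000, 30), _shift(10_000, site[0] - 28),
            dse_flags={"dpe_occluded": True, "yy1_occluded": False},
        )
        assert call.primary == "dse_occlusion"

    def test_upstream_overlap_with_sp1_gain_is_competition(self):
        from nascentmech.mechanism import OverlapRecord
        site_iv = GenomicInterval("chr1", 9_900, 9_929, "+")
        rec = _record(site_span=(9_900, 9_929))
        ov = OverlapRecord(site_iv, "SP1", "SP/KLF",
                           GenomicInterval("chr1", 9_905, 9_915), 10, 0.9999, 19.0)
        call = classify_mechanism(
            rec, TssCall("g", 10_000, 30), _shift(10_000, 10_000),
            overlaps=[ov], sp1_increased=True,
        )
        assert call.primary == "competition_sp1"
        call2 = classify_mechanism(
            rec, TssCall("g", 10_000, 30), _shift(10_000, 10_000),
            overlaps=[ov], sp1_increased=False,
        )
        assert call2.primary == "competition_other"

    def test_upstream_site_without_evidence_is_unexplained(self):
        rec = _record(site_span=(9_900, 9_929))
        call = classify_mechanism(rec, TssCall("g", 10_000, 30), _shift(10_000, 10_000),
                                  overlaps=[])
        assert call.primary == "unexplained"

    def test_up_gene_without_local_site_is_gated(self):
        call = classify_mechanism(_record(site_span=None), TssCall("g", 10_000, 30), None)
        assert call.labels == ["no_local_site"]
        far = _record(site_span=(20_000, 20_029))
        call2 = classify_mechanism(far, TssCall("g", 10_000, 30), None)
        assert call2.labels == ["no_local_site"]

    def test_deterministic_given_identical_evidence(self):
        rec = _record(site_span=(10_186, 10_215))
        args = (rec, TssCall("g", 10_000, 30), _shift(10_000, 10_000))
        a = classify_mechanism(*args, bidir_change=(-1.5, True))
        b = classify_mechanism(*args, bidir_change=(-1.5, True))
        assert (a.labels, a.primary) == (b.labels, b.primary)


class TestCohortRecall:
    def test_simulated_cohort_recall(self, sim_data):
        from nascentmech.pipeline import mechanism_table, tss_table

        calls = tss_table(sim_data)
        tab = mechanism_table(sim_data, calls, seed=5)
        up = tab[tab.gene_class == "up"]
        for mech_name, floor in [
            ("tss_occlusion", 1.0), ("roadblock", 1.0),
            ("dse_occlusion", 0.9), ("competition_sp1", 0.9),
            ("competition_other", 0.9),
        ]:
            sub = up[up.true_mechanism == mech_name]
            assert len(sub) > 0
            recall = sub.labels.str.contains(mech_name).mean()
            assert recall >= floor, mech_name
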