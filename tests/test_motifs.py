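"""Motifs: scoring, exact p-values, scanning, discovery, composite, assignment."""

from itertools import product

import numpy as np
import pytest

from nascentmech.motifs import (
    MotifHit,
    MotifModel,
    assign_binding_site,
    composite_motif,
    discover_motif,
    iterative_discovery,
    locate_core,
    read_meme,
    scan,
    score_pvalue,
    score_site,
    write_meme,
)
from nascentmech.sequence import encode, random_sequence, revcomp
from nascentmech.sim import make_planted_motif
from nascentmech.tracks import GenomicInterval, Peak

UNIFORM = np.full(4, 0.25)


def consensus_pwm(consensus, p=0.97):
    codes = encode(consensus)
    theta = np.full((codes.size, 4), (1 - p) / 3)
    theta[np.arange(codes.size), codes] = p
    theta /= theta.sum(axis=1, keepdims=True)
    return MotifModel("cons", theta, UNIFORM.copy())


class TestScoring:
    def test_background_motif_scores_zero(self, rng):
        theta = np.tile(UNIFORM, (8, 1))
        m = MotifModel("bg", theta, UNIFORM.copy())
        for _ in range(10):
            assert score_site(m, random_sequence(8, rng)) == pytest.approx(0.0)

    def test_single_column_certain_base_is_two_bits(self):
        theta = np.array([[1.0, 0.0, 0.0, 0.0]])
        m = MotifModel("a", theta, UNIFORM.copy())
        # probability floor keeps log odds finite; the A column is ~2 bits
        assert score_site(m, "A") == pytest.approx(2.0, abs=1e-3)

    def test_matches_per_position_hand_sum(self, rng):
        theta = rng.dirichlet(np.ones(4), size=6)
        m = MotifModel("r", theta, UNIFORM.copy())
        lo = m.log_odds()
        for _ in range(100):
            w = random_sequence(6, rng)
            hand = sum(lo[j, encode(w)[j]] for j in range(6))
            assert score_site(m, w) == pytest.approx(hand)

    def test_length_mismatch_rejected(self, rng):
        m = consensus_pwm("ACGTA")
        with pytest.raises(ValueError, match="width"):
            score_site(m, "ACGTAC")


class TestExactPvalues:
    def test_score_below_minimum_gives_one(self):
        m = consensus_pwm("ACGTT")
        assert score_pvalue(m, -1e6) == 1.0

    @pytest.mark.parametrize("W", [4, 5, 6])
    def test_dp_tail_equals_enumeration(self, W, rng):
        theta = rng.dirichlet(np.ones(4) * 0.7, size=W)
        m = MotifModel("r", theta, UNIFORM.copy())
        L = m.int_log_odds()[:, :4]
        words = np.array(list(product(range(4), repeat=W)))
        scores = L[np.arange(W)[None, :], words].sum(axis=1)
        for q in (0.05, 0.25, 0.5, 0.75, 0.95, 0.999):
            s = int(np.quantile(scores, q))
            brute = float((scores >= s).mean())
            dp = m.tail_probability(s)
            assert dp == pytest.approx(brute, rel=1e-3)

    def test_unique_best_word_probability(self):
        m = consensus_pwm("ACGTT")
        best = score_site(m, "ACGTT")
        assert score_pvalue(m, best) == pytest.approx(4.0 ** -5, rel=1e-9)

    def test_tail_monotone_non_increasing(self, rng):
        theta = rng.dirichlet(np.ones(4), size=7)
        m = MotifModel("r", theta, UNIFORM.copy())
        ps = [score_pvalue(m, s) for s in np.linspace(-10, 12, 60)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng):
        m = consensus_pwm("TTGACTACAATGGG")
        seq = random_sequence(300, rng)
        seq = seq[:40] + "TTGACTACAATGGG" + seq[54:]
        hits = scan(m, seq, 1e-5)
        assert [(h.site.start, h.site.end, h.strand) for h in hits] == [(40, 54, "+")]

    def test_reverse_complement_reported_on_minus(self, rng):
        m = consensus_pwm("TTGACTACAATGGG")
        seq = random_sequence(300, rng)
        seq = seq[:40] + revcomp("TTGACTACAATGGG") + seq[54:]
        hits = scan(m, seq, 1e-5)
        assert [(h.site.start, h.strand) for h in hits] == [(40, "-")]

    def test_hit_count_matches_binomial_expectation(self, rng):
        theta = rng.dirichlet(np.ones(4) * 2, size=8)
        m = MotifModel("r", theta, UNIFORM.copy())
        L = 10_000
        p = 1e-4
        seq = random_sequence(L, rng)
        hits = scan(m, seq, p)
        lam = 2 * (L - 8 + 1) * p
        assert abs(len(hits) - lam) <= 3 * np.sqrt(lam) + 1

    def test_hits_invariant_under_sequence_revcomp(self, rng):
        m = make_planted_motif(11, seed=3)
        seq = random_sequence(150, rng)
        pos = 60
        seq = seq[:pos] + m.consensus + seq[pos + 11:]
        fwd = scan(m, seq, 1e-3)
        rev = scan(m, revcomp(seq), 1e-3)
        L = len(seq)
        mapped = sorted((L - h.site.end, L - h.site.start, "-" if h.strand == "+" else "+")
                        for h in rev)
        assert mapped == sorted((h.site.start, h.site.end, h.strand) for h in fwd)

    def test_short_sequence_gives_empty_list(self):
        assert scan(consensus_pwm("ACGTACGT"), "ACG", 0.5) == []


class TestDiscovery:
    def test_recovers_planted_consensus(self, rng):
        planted = "ACTACAATGGG"
        seqs = []
        for i in range(120):
            s = random_sequence(80, np.random.default_rng(500 + i))
            pos = (i * 7) % (80 - 11)
            seqs.append(s[:pos] + planted + s[pos + 11:])
        res = discover_motif(seqs, 11, seed=2, n_shuffles=10)
        got = res.motif.consensus
        assert got in (planted, revcomp(planted))
        assert res.occurrence_fraction >= 0.95
        assert res.significant

    def test_log_likelihood_non_decreasing(self, rng):
        seqs = [random_sequence(60, rng) for _ in range(30)]
        for i in range(15):
            seqs[i] = seqs[i][:20] + "GGATTCCG" + seqs[i][28:]
        res = discover_motif(seqs, 8, seed=0, n_shuffles=2)
        path = res.log_likelihood_path
        assert np.all(np.diff(path) >= -1e-6)

    def test_identical_sequences_converge_to_substring(self):
        seqs = ["ACGTTGCAGGTCAGTACGTTAAGCCT"] * 25
        res = discover_motif(seqs, 8, seed=0, n_shuffles=2)
        cons = res.motif.consensus
        assert cons in seqs[0] or revcomp(cons) in seqs[0]

    def test_too_few_sequences_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            discover_motif([random_sequence(50, rng) for _ in range(5)], 8)


class TestIterativeDiscovery:
    def test_two_families_recovered_in_prevalence_order(self):
        famA = "TTGACTACAATGG"
        famB = "CCGGATATCGCAC"
        seqs = []
        for i in range(160):
            s = random_sequence(120, np.random.default_rng(900 + i))
            pos = (11 * i) % (120 - 13)
            if i < 96:  # 60%
                s = s[:pos] + famA + s[pos + 13:]
            elif i < 136:  # 25%
                s = s[:pos] + famB + s[pos + 13:]
            seqs.append(s)
        order = np.random.default_rng(1).permutation(len(seqs))
        seqs = [seqs[i] for i in order]
        res = iterative_discovery(seqs, 13, seed=0, n_shuffles=10)
        assert len(res.motifs) == 2
        c0, c1 = res.motifs[0].consensus, res.motifs[1].consensus
        assert c0 in (famA, revcomp(famA))
        assert c1 in (famB, revcomp(famB))
        assert res.assigned.mean() >= (96 + 40) / 160 - 0.03


class TestComposite:
    @staticmethod
    def _hits_from_planted(motif, n_sites, seed, genome_len=None):
        """Plant motif instances in one long background sequence."""
        rng = np.random.default_rng(seed)
        W = motif.width
        spacing = W + 120
        L = genome_len or n_sites * spacing + 200
        codes = rng.choice(4, size=L).astype(np.int8)
        hits = []
        from nascentmech.sequence import decode
        for k in range(n_sites):
            start = 100 + k * spacing
            inst = np.array([rng.choice(4, p=motif.theta[j]) for j in range(W)], dtype=np.int8)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = encode(revcomp(decode(inst)))
            codes[start:start + W] = inst
            hits.append(MotifHit(
                site=GenomicInterval("chrC", start, start + W, strand),
                strand=strand, score=0.0, pvalue=1e-6, motif=motif,
            ))
        return {"chrC": decode(codes)}, hits

    def test_background_flanks_give_core_width(self, rng):
        core_only = make_planted_motif(5, core_offset=0, seed=1)
        genome, hits = self._hits_from_planted(core_only, 2500, seed=11)
        comp = composite_motif(hits, genome)
        assert comp.estimated_width == 5

    @pytest.mark.parametrize("width", [11, 21])
    def test_planted_width_recovered(self, width):
        motif = make_planted_motif(width, seed=width)
        genome, hits = self._hits_from_planted(motif, 1500, seed=width + 1)
        comp = composite_motif(hits, genome)
        assert abs(comp.estimated_width - width) <= 2

    def test_width_never_increases_with_tolerance(self):
        motif = make_planted_motif(21, seed=4)
        genome, hits = self._hits_from_planted(motif, 800, seed=5)
        w1 = composite_motif(hits, genome, tolerance=0.05).estimated_width
        w2 = composite_motif(hits, genome, tolerance=0.10).estimated_width
        assert w2 <= w1

    def test_few_hits_flagged_low_confidence(self):
        motif = make_planted_motif(11, seed=6)
        genome, hits = self._hits_from_planted(motif, 20, seed=7)
        assert composite_motif(hits, genome).low_confidence


class TestAssignment:
    def _setup(self, rng):
        motif = make_planted_motif(15, core_offset=5, seed=9)
        comp_motif = make_planted_motif(29, core_offset=12, seed=9)
        from nascentmech.motifs import CompositeMotif
        comp = CompositeMotif(
            freq=np.tile(UNIFORM, (105, 1)), estimated_width=29,
            motif=comp_motif, n_hits=100, flank=50, low_confidence=False,
        )
        return motif, comp

    def test_lowest_pvalue_hit_wins(self, rng):
        motif, comp = self._setup(rng)
        strong = consensus_pwm("TTGACTACAATGGG")
        seq = random_sequence(400, rng)
        seq = seq[:100] + "TTGACTACAATGGG" + seq[114:]
        genome = {"chrA": seq}
        peak = Peak(GenomicInterval("chrA", 0, 400, "."), summit=200)
        site = assign_binding_site(peak, [strong], comp, genome)
        assert site is not None
        cstart = (site.interval.start + comp.motif.core_offset
                  if site.interval.strand == "+"
                  else site.interval.end - comp.motif.core_offset - 5)
        co, _ = locate_core(strong)
        assert cstart == 100 + co

    def test_no_hit_returns_none(self, rng):
        motif, comp = self._setup(rng)
        genome = {"chrA": random_sequence(300, rng)}
        peak = Peak(GenomicInterval("chrA", 0, 300, "."), summit=150)
        assert assign_binding_site(peak, [consensus_pwm("TTGACTACAATGGG")], comp, genome) is None

    def test_tie_broken_toward_summit(self, rng):
        motif, comp = self._setup(rng)
        cons = "TTGACTACAATGGG"
        seq = random_sequence(600, rng)
        seq = seq[:50] + cons + seq[64:400] + cons + seq[414:]
        genome = {"chrA": seq}
        peak = Peak(GenomicInterval("chrA", 0, 600, "."), summit=390)
        site = assign_binding_site(peak, [consensus_pwm(cons)], comp, genome)
        # both hits have identical p-values; the one near the summit (400) wins
        assert abs(site.hit.site.start - 400) < abs(site.hit.site.start - 50)


class TestMemeIO:
    def test_round_trip(self, tmp_path, rng):
        motifs = [make_planted_motif(11, seed=1, name="m1"),
                  make_planted_motif(8, core_offset=1, seed=2, name="m2")]
        path = str(tmp_path / "motifs.meme")
        write_meme(motifs, path)
        back = read_meme(path)
        assert [m.name for m in back] == ["m1", "m2"]
        for a, b in zip(motifs, back):
            np.testing.assert_allclose(a.theta, b.theta, atol=5e-6)
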