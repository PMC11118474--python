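"""Position-weight-matrix models: scoring, exact p-values, de novo discovery.

The motif machinery supports the discover/scan/remove workflow used to
characterize degenerate transcription-factor binding sites:

* log2-odds scoring of sequence windows against a genomic background;
* exact hit p-values by dynamic-programming convolution of the per-column
  score distributions on a discretized grid;
* ZOOPS (zero-or-one occurrence per sequence) EM discovery seeded from
  enriched words, with an empirical shuffled-sequence null for motif
  significance;
* iterative discovery where peaks explained by previously found motifs are
  removed from the discovery set until no significant motif remains;
* construction of a wide composite motif by anchoring all hit sequences on
  a core pentamer (TGGGA by default) and averaging base frequencies until
  they decay to the genomic background; and
* per-peak binding-site assignment using the lowest-p-value hit.

Scores are discretized to 1/1000 bit by default; the same discretization is
used for scanning and for the null distribution, so reported p-values are
exact for the discretized score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from nascentmech.sequence import ALPHABET, decode, encode, revcomp
from nascentmech.tracks import GenomicInterval, Peak

__all__ = [
    "MotifModel",
    "MotifHit",
    "CompositeMotif",
    "BindingSite",
    "DiscoveryResult",
    "IterativeResult",
    "score_site",
    "score_pvalue",
    "scan",
    "discover_motif",
    "iterative_discovery",
    "composite_motif",
    "assign_binding_site",
    "read_meme",
    "write_meme",
    "locate_core",
]

DEFAULT_SCALE = 1000  # score grid: 1/1000 bit
DEFAULT_CORE = "TGGGA"
HIT_P_THRESHOLD = 5e-4  # p <= 0.0005 defines a motif hit
_THETA_FLOOR = 1e-4  # probability floor when forming log-odds


@dataclass
class MotifModel:
    """PWM with background frequencies and an optional core-anchor offset."""

    name: str
    theta: np.ndarray  # (W, 4) column probabilities, ACGT order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    core_offset: int | None = None  # column where the core pentamer begins
    core_exact: bool = True  # consensus at core_offset equals the anchor pentamer

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 4:
            raise ValueError("theta must be a (W, 4) matrix")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if self.core_offset is not None and not (0 <= self.core_offset <= self.width - 5):
            raise ValueError("core_offset outside motif")
        self._cache: dict[int, tuple[np.ndarray, int, np.ndarray]] = {}

    @property
    def width(self) -> int:
        return self.theta.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.theta.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-column log2 odds, shape (W, 5); the N column scores 0."""
        lo = np.zeros((self.width, 5))
        lo[:, :4] = np.log2(np.clip(self.theta, _THETA_FLOOR, None) / self.background)
        return lo

    def int_log_odds(self, scale: int = DEFAULT_SCALE) -> np.ndarray:
        """log_odds rounded to an integer grid of 1/scale bits."""
        return np.rint(self.log_odds() * scale).astype(np.int64)

    def reverse_complement(self) -> "MotifModel":
        theta_rc = self.theta[::-1, ::-1].copy()
        co = None
        if self.core_offset is not None:
            co = self.width - self.core_offset - 5
        return MotifModel(self.name + "_rc", theta_rc, self.background, co, self.core_exact)

    def information_content(self) -> float:
        """Total relative entropy to the background, in bits."""
        t = np.clip(self.theta, 1e-12, None)
        return float((t * np.log2(t / self.background)).sum())

    # -- exact score distribution ------------------------------------------
    def _distribution(self, scale: int = DEFAULT_SCALE):
        """(tail, offset, scores): tail[i] = P(S >= offset + i) under background."""
        if scale in self._cache:
            return self._cache[scale]
        L = self.int_log_odds(scale)[:, :4]
        mins = L.min(axis=1)
        offset = int(mins.sum())
        size = int((L.max(axis=1) - mins).sum()) + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        cur = 1
        for j in range(self.width):
            shifts = L[j] - mins[j]
            width = int(shifts.max())
            new = np.zeros(cur + width)
            for b in range(4):
                s = int(shifts[b])
                new[s : s + cur] += dist[:cur] * self.background[b]
            dist = new
            cur = cur + width
        tail = np.cumsum(dist[::-1])[::-1]
        self._cache[scale] = (tail, offset, dist)
        return self._cache[scale]

    def tail_probability(self, int_score: int, scale: int = DEFAULT_SCALE) -> float:
        tail, offset, _ = self._distribution(scale)
        idx = int_score - offset
        if idx <= 0:
            return 1.0
        if idx >= tail.size:
            return float(tail[-1])
        return float(tail[idx])

    def score_threshold(self, p_threshold: float, scale: int = DEFAULT_SCALE) -> int | None:
        """Smallest integer score whose tail probability is <= p_threshold."""
        tail, offset, _ = self._distribution(scale)
        idx = np.searchsorted(-tail, -p_threshold, side="left")
        if idx >= tail.size:
            return None
        return int(offset + idx)


@dataclass
class MotifHit:
    """A scored window on either strand, in forward coordinates."""

    site: GenomicInterval
    strand: str
    score: float
    pvalue: float
    motif: MotifModel | None = None


@dataclass
class CompositeMotif:
    """Average base frequencies around the aligned core and the trimmed PWM."""

    freq: np.ndarray  # (2*flank + core, 4)
    estimated_width: int
    motif: MotifModel
    n_hits: int
    flank: int
    low_confidence: bool


@dataclass
class BindingSite:
    interval: GenomicInterval
    pvalue: float
    motif_name: str
    hit: MotifHit | None = None


def score_site(motif: MotifModel, window: str) -> float:
    """Sum of per-column log2 odds over a window of the motif's width."""
    codes = encode(window)
    if codes.size != motif.width:
        raise ValueError(f"window length {codes.size} != motif width {motif.width}")
    lo = motif.log_odds()
    return float(lo[np.arange(motif.width), codes].sum())


def score_pvalue(motif: MotifModel, score: float, scale: int = DEFAULT_SCALE) -> float:
    """Exact P(S >= score) for a background window, on the discretized grid."""
    return motif.tail_probability(int(round(score * scale)), scale)


def _window_scores(L: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Integer scores of every window; L is (W, 5) integer log-odds."""
    W = L.shape[0]
    n = codes.size - W + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    for j in range(W):
        scores += L[j, codes[j : j + n]]
    return scores


def scan(
    motif: MotifModel,
    sequence: str,
    p_threshold: float = HIT_P_THRESHOLD,
    chrom: str = "seq",
    offset: int = 0,
    scale: int = DEFAULT_SCALE,
) -> list[MotifHit]:
    """All windows with hit p-value <= threshold, on both strands.

    Reverse-strand windows are scored as the reverse complement of the
    forward window under the same motif and null distribution; hits are
    reported in forward coordinates with strand "-".
    """
    codes = encode(sequence)
    W = motif.width
    if codes.size < W:
        return []
    t = motif.score_threshold(p_threshold, scale)
    if t is None:
        return []
    L = motif.int_log_odds(scale)
    # rc matrix: scoring forward window w under Lrc == scoring revcomp(w) under L
    Lrc = np.zeros_like(L)
    Lrc[:, :4] = L[::-1, :4][:, ::-1]
    hits: list[MotifHit] = []
    for strand, mat in (("+", L), ("-", Lrc)):
        scores = _window_scores(mat, codes)
        for pos in np.nonzero(scores >= t)[0]:
            s = int(scores[pos])
            hits.append(
                MotifHit(
                    site=GenomicInterval(chrom, offset + int(pos), offset + int(pos) + W, strand),
                    strand=strand,
                    score=s / scale,
                    pvalue=motif.tail_probability(s, scale),
                    motif=motif,
                )
            )
    hits.sort(key=lambda h: (h.site.start, h.strand))
    return hits


def _core_score(theta: np.ndarray, core: str = DEFAULT_CORE) -> tuple[int, float, bool]:
    """(offset, log-prob score, exact) of the best core placement in theta."""
    codes = encode(core)
    k = codes.size
    W = theta.shape[0]
    if W < k:
        raise ValueError("motif narrower than the core")
    logp = np.log(np.clip(theta, 1e-12, None))
    scores = [float(logp[np.arange(j, j + k), codes].sum()) for j in range(W - k + 1)]
    off = int(np.argmax(scores))
    consensus = "".join(ALPHABET[b] for b in theta[off : off + k].argmax(axis=1))
    return off, scores[off], consensus == core


def _canonical_orientation(
    theta: np.ndarray, background: np.ndarray, name: str, core: str = DEFAULT_CORE
) -> MotifModel:
    """Orient a discovered PWM so the core pentamer reads on the + strand.

    Motifs are discovered up to reverse complement; anchoring the composite
    requires a consistent orientation, chosen by the better-scoring (and
    preferentially exact) core placement of the two.
    """
    if theta.shape[0] < len(core):
        return MotifModel(name, theta, background, None, True)
    off_f, score_f, exact_f = _core_score(theta, core)
    theta_rc = theta[::-1, ::-1].copy()
    off_r, score_r, exact_r = _core_score(theta_rc, core)
    take_rc = (exact_r and not exact_f) or (exact_r == exact_f and score_r > score_f)
    if take_rc:
        return MotifModel(name, theta_rc, background, off_r, exact_r)
    return MotifModel(name, theta, background, off_f, exact_f)


def locate_core(motif: MotifModel, core: str = DEFAULT_CORE) -> tuple[int, bool]:
    """Best-scoring position of the core pentamer within the motif.

    Returns (offset, exact) where exact means the motif consensus at that
    offset equals the core.
    """
    codes = encode(core)
    k = codes.size
    if motif.width < k:
        raise ValueError("motif narrower than the core")
    logp = np.log(np.clip(motif.theta, 1e-12, None))
    scores = [logp[np.arange(j, j + k), codes].sum() for j in range(motif.width - k + 1)]
    off = int(np.argmax(scores))
    exact = motif.consensus[off : off + k] == core
    return off, exact


# ---------------------------------------------------------------------------
# ZOOPS EM discovery
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    motif: MotifModel
    log_likelihood: float
    gamma: float  # per-sequence occurrence probability
    occurrence_fraction: float  # sequences with posterior site probability > 0.5
    significant: bool
    statistic: float  # information content x expected occurrences
    null_statistics: np.ndarray
    log_likelihood_path: np.ndarray


def _pad_sequences(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lmax = max(s.size for s in seqs)
    mat = np.full((len(seqs), lmax), 4, dtype=np.int8)  # pad with N
    lengths = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        mat[i, : s.size] = s
        lengths[i] = s.size
    return mat, lengths


def _revcomp_codes(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement encoded rows; N (4) maps to N."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    return comp[mat[:, ::-1]]


def _seed_words(mat: np.ndarray, lengths: np.ndarray, W: int, n_starts: int) -> list[np.ndarray]:
    """Most frequent N-free W-mers across all sequences, both strands."""
    n, lmax = mat.shape
    m = lmax - W + 1
    if m <= 0:
        raise ValueError("sequences shorter than the motif width")
    both = np.vstack([mat, _revcomp_codes(mat)])
    both_lengths = np.concatenate([lengths, lengths])
    windows = np.lib.stride_tricks.sliding_window_view(both, W, axis=1)  # (2n, m, W)
    # on the rc rows, valid windows sit at the end of the padded row
    fwd_valid = np.arange(m)[None, :] <= (lengths - W)[:, None]
    rc_valid = np.arange(m)[None, :] >= (lmax - lengths)[:, None]
    valid = np.vstack([fwd_valid, rc_valid]) & (windows < 4).all(axis=2)
    flat = np.ascontiguousarray(windows[valid]).astype(np.uint8)
    if flat.shape[0] == 0:
        raise ValueError("no N-free window available for seeding")
    packed = flat.view([("", np.uint8)] * W).ravel()
    uniq, counts = np.unique(packed, return_counts=True)
    order = np.argsort(counts)[::-1]
    words = uniq[order[:n_starts]].view(np.uint8).reshape(-1, W)
    return [w.astype(np.int8) for w in words]


def _zoops_em(
    mat: np.ndarray,
    lengths: np.ndarray,
    seed_word: np.ndarray,
    max_iter: int,
    tol: float,
    pseudocount: float = 0.25,
):
    """Run strand-aware ZOOPS EM from one seed.

    A sequence contains either no occurrence or one occurrence at one of
    its 2*m (position, strand) slots.  Returns (theta, pi, gamma, Q,
    loglik path).
    """
    n, lmax = mat.shape
    W = seed_word.size
    m = lmax - W + 1
    m_i = np.maximum(lengths - W + 1, 0)
    valid = np.arange(m)[None, :] < m_i[:, None]

    base_counts = np.zeros(4)
    for b in range(4):
        base_counts[b] = (mat == b).sum()
    pi = (base_counts + 1.0) / (base_counts.sum() + 4.0)

    theta = np.full((W, 4), 0.1)
    theta[np.arange(W), seed_word] = 0.7
    gamma = 0.5

    counts_ib = np.zeros((n, 4))
    for b in range(4):
        counts_ib[:, b] = (mat == b).sum(axis=1)

    path = []
    prev = -np.inf
    Q = np.zeros(n)
    for _ in range(max_iter):
        M = np.log(np.clip(theta, 1e-12, None) / pi)  # (W,4)
        Mf = np.zeros((W, 5))
        Mf[:, :4] = M
        # scoring a forward window against the rc motif == scoring its
        # revcomp against the motif
        Mr = np.zeros((W, 5))
        Mr[:, :4] = M[::-1, ::-1]
        loglr_f = np.zeros((n, m))
        loglr_r = np.zeros((n, m))
        for w in range(W):
            col = mat[:, w : w + m]
            loglr_f += Mf[w, col]
            loglr_r += Mr[w, col]
        loglr_f[~valid] = -np.inf
        loglr_r[~valid] = -np.inf
        with np.errstate(divide="ignore"):
            prior = np.where(
                m_i > 0, np.log(gamma) - np.log(2 * np.maximum(m_i, 1)), -np.inf
            )
        stacked = np.concatenate([loglr_f, loglr_r], axis=1) + prior[:, None]
        A = logsumexp(stacked, axis=1)
        denom = np.logaddexp(np.log1p(-gamma), A)
        z = np.exp(stacked - denom[:, None])
        z_f, z_r = z[:, :m], z[:, m:]
        Q = np.exp(A - denom)

        bg = counts_ib @ np.log(pi)
        loglik = float((denom + bg).sum())
        # MAP objective: the Dirichlet pseudo-counts on theta and pi act as
        # priors, and EM is monotone in the penalized likelihood
        objective = loglik + pseudocount * float(np.log(np.clip(theta, 1e-12, None)).sum()) \
            + float(np.log(pi).sum())
        path.append(objective)
        if objective - prev < tol and np.isfinite(prev):
            break
        prev = objective

        # M-step: rc-slot counts fold back as complement at mirrored columns
        C = np.zeros((W, 4))
        Cr = np.zeros((W, 4))
        for w in range(W):
            codes = mat[:, w : w + m].ravel()
            C[w] += np.bincount(codes, weights=z_f.ravel(), minlength=5)[:4]
            Cr[w] += np.bincount(codes, weights=z_r.ravel(), minlength=5)[:4]
        C += Cr[::-1, ::-1]
        occ = z.sum()
        theta = (C + pseudocount) / (occ + 4 * pseudocount)
        theta /= theta.sum(axis=1, keepdims=True)
        motif_base = C.sum(axis=0)
        bg_counts = np.maximum(base_counts - motif_base, 0.0)
        pi = (bg_counts + 1.0) / (bg_counts.sum() + 4.0)
        gamma = float(np.clip(Q.mean(), 1.0 / (2 * n), 1 - 1e-6))

    return theta, pi, gamma, Q, np.asarray(path)


def _discover_once(mat, lengths, W, n_starts, max_iter, tol):
    seeds = _seed_words(mat, lengths, W, n_starts)
    best = None
    for word in seeds:
        theta, pi, gamma, Q, path = _zoops_em(mat, lengths, word, max_iter, tol)
        if best is None or path[-1] > best[4][-1]:
            best = (theta, pi, gamma, Q, path)
    return best


def _stat(theta, pi, gamma, n_seq) -> float:
    t = np.clip(theta, 1e-12, None)
    ic = float((t * np.log2(t / pi)).sum())
    return ic * gamma * n_seq


def discover_motif(
    sequences: list[str],
    W: int,
    n_starts: int = 3,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    n_shuffles: int = 20,
    min_sequences: int = 20,
    name: str = "denovo",
) -> DiscoveryResult:
    """ZOOPS EM de novo discovery of one width-W motif.

    Seeds are the ``n_starts`` most frequent W-mers; the best start by final
    log-likelihood wins.  Significance compares the discovered motif's
    relative entropy x expected occurrence count against the same statistic
    on ``n_shuffles`` base-shuffled copies of the input (which preserve
    composition but destroy motifs); the motif is accepted when it beats
    every shuffle, an exact 1/(n_shuffles+1) level test by exchangeability.
    """
    if len(sequences) < min_sequences:
        raise ValueError(f"need at least {min_sequences} sequences, got {len(sequences)}")
    if not (5 <= W <= 40):
        raise ValueError("motif width must be in [5, 40]")
    rng = np.random.default_rng(seed)
    encoded = [encode(s) for s in sequences]
    mat, lengths = _pad_sequences(encoded)

    theta, pi, gamma, Q, path = _discover_once(mat, lengths, W, n_starts, max_iter, tol)
    statistic = _stat(theta, pi, gamma, len(sequences))

    null_stats = np.zeros(n_shuffles)
    for k in range(n_shuffles):
        shuf = mat.copy()
        for i in range(shuf.shape[0]):
            li = lengths[i]
            perm = rng.permutation(li)
            shuf[i, :li] = mat[i, :li][perm]
        t0, p0, g0, _, _ = _discover_once(shuf, lengths, W, n_starts, max_iter, tol)
        null_stats[k] = _stat(t0, p0, g0, len(sequences))

    # exceeding every null statistic gives an exact (n_shuffles+1)^-1
    # false-acceptance probability by exchangeability (~5% at 20 shuffles)
    significant = bool(statistic > null_stats.max())
    motif = _canonical_orientation(theta, pi / pi.sum(), name)
    return DiscoveryResult(
        motif=motif,
        log_likelihood=float(path[-1]),
        gamma=gamma,
        occurrence_fraction=float((Q > 0.5).mean()),
        significant=significant,
        statistic=statistic,
        null_statistics=null_stats,
        log_likelihood_path=path,
    )


@dataclass
class IterativeResult:
    motifs: list[MotifModel]
    assigned: np.ndarray  # bool per peak: any motif hit at the threshold
    hits: list[list[MotifHit]]  # per peak, hits from all discovered motifs
    rounds: list[DiscoveryResult]


def iterative_discovery(
    peak_sequences: list[str],
    W: int,
    max_rounds: int = 6,
    p_threshold: float = HIT_P_THRESHOLD,
    seed: int = 0,
    min_sequences: int = 20,
    **discover_kwargs,
) -> IterativeResult:
    """Discover motifs, remove explained peaks, repeat until nothing is left.

    Each round runs ZOOPS discovery on the peaks not yet explained, then
    scans *all* peaks with the new motif at the hit threshold; peaks with at
    least one hit to any discovered motif leave the discovery set.  The loop
    stops when a round's motif fails the shuffled-null significance test,
    when too few peaks remain, or after ``max_rounds``.
    """
    n = len(peak_sequences)
    assigned = np.zeros(n, dtype=bool)
    hits: list[list[MotifHit]] = [[] for _ in range(n)]
    motifs: list[MotifModel] = []
    rounds: list[DiscoveryResult] = []
    remaining = list(range(n))
    for rnd in range(max_rounds):
        if len(remaining) < min_sequences:
            break
        res = discover_motif(
            [peak_sequences[i] for i in remaining],
            W,
            seed=seed + rnd,
            min_sequences=min_sequences,
            name=f"motif_{rnd + 1}",
            **discover_kwargs,
        )
        rounds.append(res)
        if not res.significant:
            break
        motifs.append(res.motif)
        for i in range(n):
            found = scan(res.motif, peak_sequences[i], p_threshold)
            if found:
                hits[i].extend(found)
                assigned[i] = True
        remaining = [i for i in range(n) if not assigned[i]]
    return IterativeResult(motifs=motifs, assigned=assigned, hits=hits, rounds=rounds)


# ---------------------------------------------------------------------------
# Composite motif and binding-site assignment
# ---------------------------------------------------------------------------


def _core_forward_start(hit: MotifHit, core_offset: int, core_len: int = 5) -> int:
    if hit.strand == "+":
        return hit.site.start + core_offset
    return hit.site.end - core_offset - core_len


def composite_motif(
    hits: list[MotifHit],
    genome: dict[str, str],
    flank: int = 50,
    tolerance: float = 0.05,
    gap_max: int = 2,
    core: str = DEFAULT_CORE,
    min_hits: int = 50,
    name: str = "composite",
) -> CompositeMotif:
    """Average base frequencies around the core anchor and trim to width.

    Hit sequences are aligned on the start of the core pentamer (reverse
    complemented for minus-strand hits) and per-column base frequencies
    averaged over a +/-``flank`` window.  The estimated motif width is the
    maximal contiguous run of columns containing the core whose
    total-variation distance from the background exceeds ``tolerance``,
    bridging at most ``gap_max`` consecutive sub-threshold columns.
    """
    core_len = len(core)
    ncol = 2 * flank + core_len
    counts = np.zeros((ncol, 4))
    used = 0
    bg_counts = np.zeros(4)
    for hit in hits:
        motif = hit.motif
        if motif is None or motif.core_offset is None:
            raise ValueError("composite_motif requires hits carrying core-anchored motifs")
        cstart = _core_forward_start(hit, motif.core_offset, core_len)
        lo = cstart - flank
        hi = cstart + core_len + flank
        seq = genome.get(hit.site.chrom)
        if seq is None or lo < 0 or hi > len(seq):
            continue
        window = seq[lo:hi]
        if hit.strand == "-":
            window = revcomp(window)
        codes = encode(window)
        for b in range(4):
            counts[:, b] += codes == b
        bg_counts += np.bincount(codes[codes < 4], minlength=4)
        used += 1
    if used == 0:
        raise ValueError("no usable hits for composite construction")
    totals = counts.sum(axis=1, keepdims=True)
    freq = np.where(totals > 0, counts / np.maximum(totals, 1), 0.25)
    pi = bg_counts / bg_counts.sum()

    tv = 0.5 * np.abs(freq - pi).sum(axis=1)
    informative = tv > tolerance
    informative[flank : flank + core_len] = True  # the anchor itself

    def extend(start: int, step: int) -> int:
        last = start
        gap = 0
        i = start + step
        while 0 <= i < ncol:
            if informative[i]:
                last = i
                gap = 0
            else:
                gap += 1
                if gap > gap_max:
                    break
            i += step
        return last

    left = extend(flank, -1)
    right = extend(flank + core_len - 1, +1)
    width = right - left + 1
    theta = freq[left : right + 1].copy()
    theta /= theta.sum(axis=1, keepdims=True)
    motif = MotifModel(name, theta, pi, core_offset=flank - left)
    return CompositeMotif(
        freq=freq,
        estimated_width=width,
        motif=motif,
        n_hits=used,
        flank=flank,
        low_confidence=used < min_hits,
    )


def assign_binding_site(
    peak: Peak,
    motifs: list[MotifModel],
    composite: CompositeMotif,
    genome: dict[str, str],
    p_threshold: float = HIT_P_THRESHOLD,
    core: str = DEFAULT_CORE,
) -> BindingSite | None:
    """Lowest-p-value motif hit in the peak, reported at the composite width.

    Ties on p-value go to the hit nearer the summit, then to the
    upstream-most hit.  Returns None (peak flagged motif-less by the
    caller) when no motif reaches the hit threshold.
    """
    seq = genome[peak.interval.chrom]
    lo, hi = peak.interval.start, peak.interval.end
    window = seq[lo:hi]
    candidates: list[MotifHit] = []
    for motif in motifs:
        candidates.extend(
            scan(motif, window, p_threshold, chrom=peak.interval.chrom, offset=lo)
        )
    if not candidates:
        return None
    candidates.sort(
        key=lambda h: (h.pvalue, abs((h.site.start + h.site.end) // 2 - peak.summit), h.site.start)
    )
    win = candidates[0]
    core_len = len(core)
    co = win.motif.core_offset if win.motif is not None else None
    if co is None:
        # motifs without an annotated core anchor align on the best-scoring
        # core placement
        if win.motif is not None and win.motif.width >= core_len:
            co, _ = locate_core(win.motif, core)
        else:
            co = 0
    cstart = _core_forward_start(win, co, core_len)
    cw = composite.motif.width
    cco = composite.motif.core_offset or 0
    if win.strand == "+":
        start = cstart - cco
    else:
        start = cstart + core_len + cco - cw
    start = max(0, min(start, len(seq) - cw))
    interval = GenomicInterval(peak.interval.chrom, start, start + cw, win.strand)
    return BindingSite(interval=interval, pvalue=win.pvalue, motif_name=win.motif.name, hit=win)


# ---------------------------------------------------------------------------
# MEME minimal text format
# ---------------------------------------------------------------------------


def write_meme(motifs: list[MotifModel], path: str) -> None:
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.theta:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            background = background / background.sum()
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else f"motif_{len(motifs) + 1}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(w):
                rows.append([float(v) for v in lines[i + 1 + k].split()])
            theta = np.asarray(rows)
            theta = theta / theta.sum(axis=1, keepdims=True)
            try:
                co, exact = locate_core(MotifModel("tmp", theta, background))
            except ValueError:
                co, exact = None, True
            motifs.append(MotifModel(name, theta, background, co, exact))
            i += 1 + w
            continue
        i += 1
    return motifs
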