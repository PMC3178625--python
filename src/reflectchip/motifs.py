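"""Motif discovery, comparison, scanning and enrichment testing.

The workflow mirrors a classic promoter-array follow-up: enumerate
over-represented words in ChIP-positive sequences against a Markov
background, refine them into position frequency matrices, merge similar
matrices into a consensus, scan sequences by percent-of-maximum score
(Profit-style, hits at >= 75% similarity by default) and compare the
score distributions of positive and control sequences with a chi-square
homogeneity test.

Discovery is a deliberately simplified word-seeded variant of the
MDscan/MDmodule family: seeds are ranked by observed/expected count,
extended to matrices by collecting sites within a Hamming radius, and
refined by iterative rescanning.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import chi2_contingency

import Bio.motifs

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# lowercase counts as masked only when explicitly requested; by default
# scanning is case-insensitive (soft-masked regions still score).
_CODE_MASK_LOWER = _CODE.copy()
for _b in BASES.lower():
    _CODE_MASK_LOWER[ord(_b)] = 4


def encode(seq: str, mask_lowercase: bool = False) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, other/N=4."""
    table = _CODE_MASK_LOWER if mask_lowercase else _CODE
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[..., ::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


@dataclass
class FrequencyMatrix:
    """A 4 x w position frequency matrix (rows A, C, G, T; columns sum to 1)."""

    probs: np.ndarray
    name: str = "motif"
    n_sites: int = 0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x w array (rows A,C,G,T)")
        if np.any(self.probs < 0):
            raise ValueError("matrix entries must be non-negative")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each matrix column must sum to 1")
        # renormalize away accumulated float error so invariants hold to 1e-9
        self.probs = self.probs / sums

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.0,
                    name: str = "motif", n_sites: int | None = None) -> "FrequencyMatrix":
        counts = np.asarray(counts, dtype=float)
        if n_sites is None:
            n_sites = int(round(counts.sum(axis=0).max()))
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(probs, name=name, n_sites=n_sites, pseudocount=pseudocount)

    @classmethod
    def from_sites(cls, site_codes: np.ndarray, pseudocount: float = 0.0,
                   name: str = "motif") -> "FrequencyMatrix":
        """Build from an (n_sites, w) array of base codes (no N allowed)."""
        site_codes = np.asarray(site_codes)
        if site_codes.ndim != 2 or site_codes.shape[0] == 0:
            raise ValueError("need a non-empty (n_sites, w) code array")
        w = site_codes.shape[1]
        counts = np.zeros((4, w))
        for b in range(4):
            counts[b] = (site_codes == b).sum(axis=0)
        return cls.from_counts(counts, pseudocount=pseudocount, name=name,
                               n_sites=site_codes.shape[0])

    @classmethod
    def from_consensus(cls, consensus: str, pseudocount: float = 0.01,
                       name: str | None = None) -> "FrequencyMatrix":
        codes = encode(consensus.upper())
        if np.any(codes >= 4):
            raise ValueError("consensus must be over ACGT")
        counts = np.zeros((4, len(codes)))
        counts[codes, np.arange(len(codes))] = 1.0
        return cls.from_counts(counts, pseudocount=pseudocount,
                               name=name or consensus.upper(), n_sites=1)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "FrequencyMatrix":
        return replace(self, probs=self.probs[::-1, ::-1].copy(),
                       name=self.name + "_rc")

    def information_content(self) -> tuple[np.ndarray, float]:
        """Per-column bits (uniform background) and their total."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        ic = 2.0 + plogp.sum(axis=0)
        return ic, float(ic.sum())

    def max_score(self) -> float:
        return float(self.probs.max(axis=0).sum())


# ---------------------------------------------------------------------------
# matrix IO (JASPAR / TRANSFAC via Bio.motifs)


def _to_biopython(mat: FrequencyMatrix) -> "Bio.motifs.Motif":
    scale = max(mat.n_sites, 1)
    counts = {b: list(mat.probs[i] * scale) for i, b in enumerate(BASES)}
    m = Bio.motifs.Motif(alphabet="ACGT", counts=counts)
    m.matrix_id = mat.name
    m.name = mat.name
    return m


def _from_biopython(m: "Bio.motifs.Motif") -> FrequencyMatrix:
    counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
    name = getattr(m, "matrix_id", None) or m.name or "motif"
    return FrequencyMatrix.from_counts(counts, name=str(name))


def write_matrices(matrices: Sequence[FrequencyMatrix], path, fmt: str = "jaspar") -> None:
    text = Bio.motifs.write([_to_biopython(m) for m in matrices], fmt)
    with open(path, "w") as fh:
        fh.write(text)


def read_matrices(path, fmt: str = "jaspar") -> list[FrequencyMatrix]:
    with open(path) as fh:
        return [_from_biopython(m) for m in Bio.motifs.parse(fh, fmt)]


def taatta_matrix(pseudocount: float = 0.01) -> FrequencyMatrix:
    """Homeodomain-like TAATTA matrix (synthetic stand-in built from the
    consensus; the binding preference itself was characterised on protein
    binding microarrays, for which no numeric matrix is shipped here)."""
    return FrequencyMatrix.from_consensus("TAATTA", pseudocount=pseudocount,
                                          name="TAATTA_consensus")


# ---------------------------------------------------------------------------
# Markov background


class MarkovBackground:
    """Order-k Markov model of background sequence composition.

    Stores marginal base frequencies plus, for k >= 1, conditional
    probabilities P(base | preceding k-mer). Word probabilities score the
    first k positions with the marginal frequencies and the rest with the
    conditionals.
    """

    def __init__(self, order: int, base_freqs: np.ndarray,
                 trans: np.ndarray | None = None) -> None:
        if order < 0:
            raise ValueError("order must be >= 0")
        self.order = int(order)
        self.base_freqs = np.asarray(base_freqs, dtype=float)
        self.base_freqs = self.base_freqs / self.base_freqs.sum()
        if order > 0:
            trans = np.asarray(trans, dtype=float)
            if trans.shape != (4 ** order, 4):
                raise ValueError("trans must have shape (4^k, 4)")
            self.trans = trans / trans.sum(axis=1, keepdims=True)
        else:
            self.trans = None

    # -- constructors -------------------------------------------------
    @classmethod
    def train(cls, sequences: Iterable[str], order: int) -> "MarkovBackground":
        """Maximum-likelihood conditional frequencies with add-one smoothing."""
        if order < 0:
            raise ValueError("order must be >= 0")
        base_counts = np.ones(4)
        trans_counts = np.ones((4 ** order, 4)) if order > 0 else None
        total = 0
        for seq in _seq_values(sequences):
            codes = encode(seq)
            valid = codes < 4
            total += int(valid.sum())
            base_counts += np.bincount(codes[valid], minlength=4)[:4]
            if order > 0 and len(codes) > order:
                ctx = _context_ids(codes, order)
                nxt = codes[order:]
                ok = (ctx >= 0) & (nxt < 4)
                np.add.at(trans_counts, (ctx[ok], nxt[ok]), 1)
        if total < 10 * 4 ** (order + 1):
            warnings.warn("short training sequence for the requested order; "
                          "estimates are heavily smoothed")
        return cls(order, base_counts, trans_counts)

    @classmethod
    def from_gc(cls, order: int, gc_content: float) -> "MarkovBackground":
        at = (1 - gc_content) / 2
        gc = gc_content / 2
        base = np.array([at, gc, gc, at])
        trans = np.tile(base, (4 ** order, 1)) if order > 0 else None
        return cls(order, base, trans)

    @classmethod
    def random(cls, order: int, seed: int, concentration: float = 5.0) -> "MarkovBackground":
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.full(4, concentration))
        trans = (rng.dirichlet(np.full(4, concentration), size=4 ** order)
                 if order > 0 else None)
        return cls(order, base, trans)

    # -- probabilities ------------------------------------------------
    def log_prob_word(self, word: str) -> float:
        codes = encode(word.upper())
        if np.any(codes >= 4):
            raise ValueError("word must be over ACGT")
        k = self.order
        logp = float(np.log(self.base_freqs[codes[: max(k, 0)]]).sum()) if k else 0.0
        if k == 0:
            return float(np.log(self.base_freqs[codes]).sum())
        for i in range(k, len(codes)):
            ctx = _context_id(codes[i - k:i])
            logp += np.log(self.trans[ctx, codes[i]])
        return logp

    def prob_word(self, word: str) -> float:
        return float(np.exp(self.log_prob_word(word)))

    def expected_count(self, word: str, n_windows: int,
                       both_strands: bool = True) -> float:
        p = self.prob_word(word)
        rc = revcomp(word.upper())
        if both_strands and rc != word.upper():
            p += self.prob_word(rc)
        return p * n_windows

    # -- sampling -----------------------------------------------------
    def sample(self, n_sequences: int, length: int,
               rng: np.random.Generator) -> list[str]:
        codes = np.empty((n_sequences, length), dtype=np.int8)
        for j in range(length):
            if self.order == 0 or j < self.order:
                probs = np.tile(self.base_freqs, (n_sequences, 1))
            else:
                ctx = np.zeros(n_sequences, dtype=np.int64)
                for d in range(self.order):
                    ctx = ctx * 4 + codes[:, j - self.order + d]
                probs = self.trans[ctx]
            u = rng.random(n_sequences)
            codes[:, j] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return ["".join(BASES[c] for c in row) for row in codes]


def _context_id(codes: np.ndarray) -> int:
    out = 0
    for c in codes:
        out = out * 4 + int(c)
    return out


def _context_ids(codes: np.ndarray, order: int) -> np.ndarray:
    """Vectorized context ids for positions order..len-1; -1 where N occurs."""
    n = len(codes) - order
    ids = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for d in range(order):
        col = codes[d:d + n]
        bad |= col >= 4
        ids = ids * 4 + np.where(col >= 4, 0, col)
    ids[bad] = -1
    return ids


def train_background(sequences, order: int) -> MarkovBackground:
    return MarkovBackground.train(sequences, order)


# ---------------------------------------------------------------------------
# scanning


@dataclass
class ScanSummary:
    """Per-sequence best percent-similarity and hit counts for one matrix."""

    best_percent: pd.Series          # indexed by sequence id
    n_hits: pd.Series                # hits >= threshold per sequence
    threshold_percent: float

    @property
    def n_sequences(self) -> int:
        return len(self.best_percent)

    @property
    def n_with_hit(self) -> int:
        return int((self.n_hits > 0).sum())

    @property
    def total_hits(self) -> int:
        return int(self.n_hits.sum())


def _seq_items(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return list(sequences.items())
    out = []
    for i, s in enumerate(sequences):
        if isinstance(s, tuple):
            out.append(s)
        elif hasattr(s, "id") and hasattr(s, "seq"):  # Bio.SeqRecord
            out.append((str(s.id), str(s.seq)))
        else:
            out.append((f"seq{i}", str(s)))
    return out


def _seq_values(sequences) -> list[str]:
    return [s for _, s in _seq_items(sequences)]


def _window_scores(codes: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Scores of every window of width w; score is (5, w) with N row zero."""
    w = score.shape[1]
    windows = sliding_window_view(codes, w)
    return score[windows, np.arange(w)].sum(axis=1)


def profit_scan(sequences, matrix: FrequencyMatrix,
                threshold_percent: float = 75.0) -> tuple[pd.DataFrame, ScanSummary]:
    """Scan both strands of every sequence with a frequency matrix.

    A window's score is the sum of matrix probabilities of its bases; its
    percent similarity is 100 * score / max attainable score. Windows with
    percent >= threshold are reported as hits. Positions read as N (or
    soft-masked when the caller encoded them so) contribute 0.
    """
    if not 0 < threshold_percent <= 100:
        raise ValueError("threshold_percent must be in (0, 100]")
    w = matrix.width
    smax = matrix.max_score()
    score_fwd = np.vstack([matrix.probs, np.zeros((1, w))])
    score_rev = np.vstack([matrix.reverse_complement().probs, np.zeros((1, w))])
    rows = []
    best, nhits = {}, {}
    for sid, seq in _seq_items(sequences):
        codes = encode(seq)
        if len(codes) < w:
            warnings.warn(f"sequence {sid} shorter than matrix width; skipped")
            continue
        pct = {"+": 100.0 * _window_scores(codes, score_fwd) / smax,
               "-": 100.0 * _window_scores(codes, score_rev) / smax}
        best[sid] = float(max(pct["+"].max(), pct["-"].max()))
        count = 0
        for strand in "+-":
            for off in np.flatnonzero(pct[strand] >= threshold_percent):
                rows.append((sid, int(off), strand, float(pct[strand][off])))
                count += 1
        nhits[sid] = count
    hits = pd.DataFrame(rows, columns=["sequence_id", "offset", "strand", "percent"])
    summary = ScanSummary(best_percent=pd.Series(best, dtype=float),
                          n_hits=pd.Series(nhits, dtype=int),
                          threshold_percent=threshold_percent)
    return hits, summary


def best_percent_scores(sequences, matrix: FrequencyMatrix) -> pd.Series:
    _, summary = profit_scan(sequences, matrix, threshold_percent=100.0)
    return summary.best_percent


# ---------------------------------------------------------------------------
# discovery


class MotifDiscovery:
    """Simplified word-seeded motif discovery (MDscan-style).

    Enumerate all width-w words in the positive sequences (strand-folded),
    rank them by log(observed / background-expected count), extend the top
    seeds to frequency matrices from all sites within ``hamming_radius``,
    then iterate: rescan, keep each sequence's best site at >=
    ``min_percent`` similarity, rebuild. Final motifs are ranked by total
    information content times log(number of sites).

    Deterministic: two runs on the same inputs give identical matrices.
    """

    def __init__(self, width: int = 6, n_seeds: int = 10, hamming_radius: int = 1,
                 n_iterations: int = 3, min_percent: float = 75.0,
                 pseudocount: float = 0.5):
        self.width = width
        self.n_seeds = n_seeds
        self.hamming_radius = hamming_radius
        self.n_iterations = n_iterations
        self.min_percent = min_percent
        self.pseudocount = pseudocount

    # sklearn-style param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("width", "n_seeds", "hamming_radius", "n_iterations",
                 "min_percent", "pseudocount")}

    def set_params(self, **params) -> "MotifDiscovery":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, sequences, background: MarkovBackground | None = None) -> "MotifDiscovery":
        items = _seq_items(sequences)
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        w = self.width
        if any(len(s) < w for _, s in items):
            raise ValueError("width exceeds the shortest sequence")
        if background is None:
            background = MarkovBackground.train([s for _, s in items], order=0)
        seq_codes = [encode(s) for _, s in items]
        seeds = self._rank_seeds(seq_codes, background)
        motifs: list[FrequencyMatrix] = []
        seen = set()
        for word in seeds:
            mat = self._seed_to_matrix(word, seq_codes)
            if mat is None:
                continue
            mat = self._refine(mat, items)
            if mat.consensus not in seen:
                seen.add(mat.consensus)
                motifs.append(mat)
        motifs.sort(key=lambda m: (-self.score(m), m.consensus))
        self.motifs_ = motifs
        self.background_ = background
        return self

    @staticmethod
    def score(mat: FrequencyMatrix) -> float:
        _, total_ic = mat.information_content()
        return total_ic * np.log(max(mat.n_sites, 1))

    # -- internals ----------------------------------------------------
    def _all_windows(self, seq_codes: list[np.ndarray]) -> np.ndarray:
        w = self.width
        parts = []
        for codes in seq_codes:
            if len(codes) >= w:
                win = sliding_window_view(codes, w)
                parts.append(win[(win < 4).all(axis=1)])
        if not parts:
            return np.empty((0, w), dtype=np.int8)
        return np.concatenate(parts, axis=0)

    def _rank_seeds(self, seq_codes: list[np.ndarray],
                    background: MarkovBackground) -> list[str]:
        w = self.width
        windows = self._all_windows(seq_codes)
        if windows.shape[0] == 0:
            return []
        ids = np.zeros(windows.shape[0], dtype=np.int64)
        for j in range(w):
            ids = ids * 4 + windows[:, j]
        uniq, counts = np.unique(ids, return_counts=True)
        count_of = dict(zip(uniq.tolist(), counts.tolist()))
        scored = []
        done = set()
        for word_id, count in count_of.items():
            if word_id in done:
                continue
            word = _id_to_word(word_id, w)
            rc = revcomp(word)
            rc_id = _word_to_id(rc)
            done.add(word_id)
            total = count
            if rc_id != word_id:
                done.add(rc_id)
                total += count_of.get(rc_id, 0)
            canonical = min(word, rc)
            expected = background.expected_count(canonical, windows.shape[0])
            ratio = np.log((total + 0.5) / (expected + 0.5))
            if ratio > 0:
                scored.append((ratio, canonical, total))
        scored.sort(key=lambda t: (-t[0], t[1]))
        return [word for _, word, _ in scored[: self.n_seeds]]

    def _seed_to_matrix(self, word: str, seq_codes: list[np.ndarray]) -> FrequencyMatrix | None:
        seed = encode(word)
        seed_rc = _revcomp_codes(seed)
        palindrome = np.array_equal(seed, seed_rc)
        sites = []
        for codes in seq_codes:
            win = sliding_window_view(codes, self.width)
            valid = (win < 4).all(axis=1)
            d_f = (win != seed).sum(axis=1)
            take_f = valid & (d_f <= self.hamming_radius)
            sites.append(win[take_f])
            if not palindrome:
                d_r = (win != seed_rc).sum(axis=1)
                take_r = valid & (d_r <= self.hamming_radius) & ~take_f
                sites.append(_revcomp_codes(win[take_r]))
        site_arr = np.concatenate([s for s in sites if len(s)], axis=0) \
            if any(len(s) for s in sites) else np.empty((0, self.width))
        if site_arr.shape[0] < 2:
            return None
        return FrequencyMatrix.from_sites(site_arr, pseudocount=self.pseudocount,
                                          name=word)

    def _refine(self, mat: FrequencyMatrix, items: list[tuple[str, str]]) -> FrequencyMatrix:
        w = self.width
        for _ in range(self.n_iterations):
            score_fwd = np.vstack([mat.probs, np.zeros((1, w))])
            score_rev = np.vstack([mat.reverse_complement().probs, np.zeros((1, w))])
            smax = mat.max_score()
            sites = []
            for _, seq in items:
                codes = encode(seq)
                if len(codes) < w:
                    continue
                pf = _window_scores(codes, score_fwd)
                pr = _window_scores(codes, score_rev)
                of, orr = int(pf.argmax()), int(pr.argmax())
                if pf[of] >= pr[orr]:
                    best, pct = codes[of:of + w], 100.0 * pf[of] / smax
                else:
                    best, pct = _revcomp_codes(codes[orr:orr + w]), 100.0 * pr[orr] / smax
                if pct >= self.min_percent and (best < 4).all():
                    sites.append(best)
            if len(sites) < 2:
                break
            new = FrequencyMatrix.from_sites(np.asarray(sites),
                                             pseudocount=self.pseudocount,
                                             name=mat.name)
            if np.allclose(new.probs, mat.probs):
                mat = new
                break
            mat = new
        return mat


def _id_to_word(word_id: int, w: int) -> str:
    out = []
    for _ in range(w):
        out.append(BASES[word_id % 4])
        word_id //= 4
    return "".join(reversed(out))


def _word_to_id(word: str) -> int:
    out = 0
    for c in encode(word):
        out = out * 4 + int(c)
    return out


def discover_motifs(sequences, background: MarkovBackground | None = None,
                    width: int = 6, n_seeds: int = 10, hamming_radius: int = 1,
                    n_iterations: int = 3, min_percent: float = 75.0,
                    pseudocount: float = 0.5) -> list[FrequencyMatrix]:
    disc = MotifDiscovery(width=width, n_seeds=n_seeds,
                          hamming_radius=hamming_radius,
                          n_iterations=n_iterations, min_percent=min_percent,
                          pseudocount=pseudocount)
    return disc.fit(sequences, background).motifs_


# ---------------------------------------------------------------------------
# comparison and merging


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 4-vectors; degenerate columns give 1 when
    identical and 0 otherwise."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compare_motifs(m1: FrequencyMatrix, m2: FrequencyMatrix,
                   min_overlap: int = 4) -> tuple[float, int, str]:
    """Best mean column-wise Pearson correlation over all alignments.

    Returns (similarity in [-1, 1], offset of m2 relative to m1, strand).
    Symmetric in its arguments; ties prefer the + strand, then the smallest
    absolute offset.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    w1, w2 = m1.width, m2.width
    if min(w1, w2) < min_overlap:
        raise ValueError("min_overlap exceeds a matrix width; no overlap possible")
    best = (-np.inf, 0, "+")
    for strand, other in (("+", m2), ("-", m2.reverse_complement())):
        for offset in range(-(w2 - min_overlap), w1 - min_overlap + 1):
            lo1, hi1 = max(0, offset), min(w1, offset + w2)
            if hi1 - lo1 < min_overlap:
                continue
            cols1 = m1.probs[:, lo1:hi1]
            cols2 = other.probs[:, lo1 - offset:hi1 - offset]
            sim = float(np.mean([_column_correlation(cols1[:, j], cols2[:, j])
                                 for j in range(hi1 - lo1)]))
            key = (sim, strand == "+", -abs(offset))
            if key > (best[0], best[2] == "+", -abs(best[1])):
                best = (sim, offset, strand)
    return best


def merge_motifs(matrices: Sequence[FrequencyMatrix],
                 similarity_threshold: float = 0.8,
                 min_overlap: int = 4) -> list[FrequencyMatrix]:
    """Single-linkage grouping at a similarity threshold, then per-group
    n_sites-weighted averaging of aligned columns (anchored on the member
    with the most sites)."""
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    n = len(matrices)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            sim, _, _ = compare_motifs(matrices[i], matrices[j], min_overlap)
            if sim >= similarity_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        out.append(_merge_group([matrices[i] for i in members], min_overlap))
    out.sort(key=lambda m: (-m.n_sites, m.consensus))
    return out


def _merge_group(group: list[FrequencyMatrix], min_overlap: int) -> FrequencyMatrix:
    if len(group) == 1:
        return group[0]
    anchor = max(group, key=lambda m: (m.n_sites, m.name))
    w = anchor.width
    weighted = anchor.probs * max(anchor.n_sites, 1)
    weight = np.full(w, float(max(anchor.n_sites, 1)))
    for m in group:
        if m is anchor:
            continue
        _, offset, strand = compare_motifs(anchor, m, min_overlap)
        probs = m.probs if strand == "+" else m.reverse_complement().probs
        lo, hi = max(0, offset), min(w, offset + m.width)
        wgt = max(m.n_sites, 1)
        weighted[:, lo:hi] += probs[:, lo - offset:hi - offset] * wgt
        weight[lo:hi] += wgt
    probs = weighted / weight
    return FrequencyMatrix(probs / probs.sum(axis=0),
                           name="+".join(sorted(m.name for m in group)),
                           n_sites=sum(m.n_sites for m in group),
                           pseudocount=anchor.pseudocount)


def information_content(matrix: FrequencyMatrix) -> tuple[np.ndarray, float]:
    return matrix.information_content()


# ---------------------------------------------------------------------------
# enrichment test


def motif_enrichment_test(positive_scores, control_scores,
                          n_bins: int = 10) -> tuple[float, int, float]:
    """Chi-square homogeneity test comparing two score distributions.

    Scores (per-sequence best percent similarity) are binned by
    pooled-sample quantile edges; bins whose pooled expected count falls
    below 5 are merged with their neighbour. Returns (statistic, degrees of
    freedom, p-value).
    """
    pos = np.asarray(list(positive_scores), dtype=float)
    ctl = np.asarray(list(control_scores), dtype=float)
    if len(pos) == 0 or len(ctl) == 0:
        raise ValueError("both score sets must be non-empty")
    pooled = np.concatenate([pos, ctl])
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1]))
    pos_counts = np.bincount(np.searchsorted(edges, pos, side="right"),
                             minlength=len(edges) + 1)
    ctl_counts = np.bincount(np.searchsorted(edges, ctl, side="right"),
                             minlength=len(edges) + 1)
    table = np.vstack([pos_counts, ctl_counts]).astype(float)
    table = _merge_sparse_bins(table)
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 usable bins after merging")
    if np.array_equal(table[0], table[1]):
        return 0.0, table.shape[1] - 1, 1.0
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def _merge_sparse_bins(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    table = table.copy()
    while table.shape[1] > 1:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        low = np.flatnonzero((expected < min_expected).any(axis=0))
        if len(low) == 0:
            break
        j = int(low[0])
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        lo, hi = min(j, k), max(j, k)
        table[:, lo] += table[:, hi]
        table = np.delete(table, hi, axis=1)
    return table


def discover_and_test(positive_sequences, control_sequences,
                      matrix: FrequencyMatrix | None = None,
                      discovery_fraction: float = 0.5, seed: int = 0,
                      threshold_percent: float = 75.0, n_bins: int = 10,
                      **discovery_params) -> dict:
    """Discover a motif on a held-out split and test its enrichment.

    When no matrix is supplied, the positive set is split: discovery runs
    on ``discovery_fraction`` of it and the chi-square homogeneity test
    compares the held-out positives against the controls. Testing on the
    same sequences the motif was learned from would be anti-conservative
    (the seed is by construction over-represented there), so the split is
    what makes the reported p-value honest.
    """
    pos_items = _seq_items(positive_sequences)
    ctl_items = _seq_items(control_sequences)
    if matrix is None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(pos_items))
        n_disc = max(2, int(round(discovery_fraction * len(pos_items))))
        disc_items = [pos_items[i] for i in order[:n_disc]]
        eval_items = [pos_items[i] for i in order[n_disc:]]
        if not eval_items:
            raise ValueError("no held-out positives left for testing")
        motifs = discover_motifs(disc_items, **discovery_params)
        if not motifs:
            return {"motif": None, "chi2": 0.0, "df": 0, "p": 1.0,
                    "n_discovery": len(disc_items), "n_eval": len(eval_items)}
        matrix = motifs[0]
    else:
        disc_items, eval_items = [], pos_items
    pos_scores = best_percent_scores(eval_items, matrix)
    ctl_scores = best_percent_scores(ctl_items, matrix)
    stat, dof, p = motif_enrichment_test(pos_scores, ctl_scores, n_bins=n_bins)
    _, pos_summary = profit_scan(eval_items, matrix, threshold_percent)
    _, ctl_summary = profit_scan(ctl_items, matrix, threshold_percent)
    return {"motif": matrix, "chi2": stat, "df": dof, "p": p,
            "n_discovery": len(disc_items), "n_eval": len(eval_items),
            "positive_summary": pos_summary, "control_summary": ctl_summary}
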