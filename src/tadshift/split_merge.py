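"""Matching TADs between two conditions and scoring splits/mergers.

Each reference TAD from one condition is matched to an ordered chain of
domains in the other condition by a greedy coding-tree walk over that
condition's boundary densities: starting at the reference left boundary,
the next right edge ``gamma`` is repeatedly chosen to maximize
``f_L(l0) * f_R(gamma) * f_P(l0, gamma)``, the product of the chosen
factors accumulating into the chain probability.

A matched pair is then scored.  The default score is the corner split
ratio (CSR): with ``mu_S`` the mean contact inside the matched sub-TAD
squares and ``mu_K`` the mean over the rest of the big-TAD square (the
"corners"), CSR is the absolute difference of ``mu_K / mu_S`` between the
two conditions.  A genuine split/merger leaves the corner contacts high in
the merged condition and depleted in the split one, so CSR is large; a
stable hierarchy of sub-TADs yields similar ratios and a small CSR.
Three alternative similarity scores (stratum-adjusted correlation,
Laplacian eigenvector similarity, average-hash image similarity) are
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .hic_io import BinInterval, ContactMatrix, TAD, TADSet, ValidationError
from .tad_caller import CallerState

__all__ = [
    "TADMatch",
    "SplitScoreRecord",
    "match_tads",
    "corner_split_ratio",
    "scc_score",
    "lms_score",
    "ihs_score",
    "classify_splits_mergers",
    "zscore_scores",
]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class TADMatch:
    """One reference TAD paired with its matched chain in the other
    condition.

    ``chain`` holds contiguous, ordered, non-overlapping intervals tiling
    the reference TAD; ``chain_probability`` is the accumulated product of
    boundary-density factors from the coding-tree walk.
    """

    big_tad: TAD
    chain: list[BinInterval]
    chain_probability: float

    def chain_intervals(self) -> list[BinInterval]:
        return self.chain

    @property
    def n_sub(self) -> int:
        return len(self.chain)


def match_tads(
    tads_ref: TADSet | list[TAD], state_other: CallerState
) -> list[TADMatch]:
    """Match each reference TAD against the densities of the other
    condition with the greedy coding-tree walk.

    For a reference TAD ``[l, r)`` (right-edge bin ``rb = r - 1``) the walk
    starts at ``l0 = l`` and repeatedly picks the right edge
    ``gamma in (l0, rb]`` maximizing ``f_R(gamma) * f_P(l0, gamma)``
    (``f_L(l0)`` is constant per step), multiplies
    ``f_L(l0) * f_R(gamma) * f_P(l0, gamma)`` into the chain probability,
    and advances ``l0 = gamma`` until the reference right edge is reached.
    Ties are broken toward the smaller ``gamma``.
    """
    fL = state_other.f_left.density
    fR = state_other.f_right.density
    fP = state_other.f_pair.grid
    n = state_other.n
    matches: list[TADMatch] = []
    tads = list(tads_ref)
    for t in tads:
        l, r = t.interval.left, t.interval.right
        if not (0 <= l < r <= n):
            raise ValidationError(
                f"reference TAD {t.interval} outside matrix of {n} bins"
            )
        rb = r - 1
        min_size = state_other.config.min_tad_size
        p = 1.0
        edges: list[int] = []
        l0 = l
        while l0 < rb:
            # a genuine sub-domain split must leave both parts at least
            # min_tad_size long; otherwise close the chain at the
            # reference end
            cand = np.arange(l0 + min_size, rb - min_size + 1)
            cand = np.append(cand, rb)
            vals = fR[cand] * fP[l0, cand]
            if vals.max() > 0.0:
                gamma = int(cand[int(np.argmax(vals))])  # first max: smaller gamma
            else:
                # f_P carries no mass anywhere on this row (the left edge
                # was not among the other condition's strap edges), so
                # every gamma ties at product 0; break the tie with the
                # right-edge density alone, falling back to the reference
                # end when it shows no distinguished peak either
                fr = fR[cand]
                peak = float(fr.max())
                if peak > 5.0 * max(float(np.median(fr)), 1e-300):
                    gamma = int(cand[int(np.argmax(fr))])
                else:
                    gamma = rb
            p *= float(fL[l0] * fR[gamma] * fP[l0, gamma])
            edges.append(gamma)
            l0 = gamma
        if not edges:  # single-bin reference TAD
            p *= float(fL[l] * fR[rb] * fP[l, rb])
            edges.append(rb)
        # edges are inclusive right-edge bins; convert to half-open tiles
        chain: list[BinInterval] = []
        start = l
        for e in edges:
            chain.append(BinInterval(start, e + 1))
            start = e + 1
        matches.append(TADMatch(t, chain, p))
    return matches


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _chain_mask(match: TADMatch) -> tuple[BinInterval, np.ndarray]:
    big = match.big_tad.interval
    size = len(big)
    mask = np.zeros((size, size), dtype=bool)
    for sub in match.chain:
        a = max(sub.left, big.left) - big.left
        b = min(sub.right, big.right) - big.left
        if b > a:
            mask[a:b, a:b] = True
    return big, mask


def corner_split_ratio(
    m1: ContactMatrix, m2: ContactMatrix, match: TADMatch
) -> float:
    """Corner split ratio of a matched TAD between two conditions.

    ``|mu_K1 / mu_S1 - mu_K2 / mu_S2|`` where, per condition, ``mu_S`` is
    the mean contact over the union of on-diagonal chain sub-squares and
    ``mu_K`` the mean over the rest of the big-TAD square.  A chain that is
    the whole big TAD has no corner region; the score is 0 by convention.
    """
    if match.n_sub < 1:
        raise ValidationError("match chain is empty")
    big, mask = _chain_mask(match)
    if m1.n_bins != m2.n_bins:
        raise ValidationError("condition matrices differ in size")
    if big.right > m1.n_bins:
        raise ValidationError("big TAD outside matrix")
    corner = ~mask
    if not corner.any():
        return 0.0
    b1 = m1.values[big.left : big.right, big.left : big.right]
    b2 = m2.values[big.left : big.right, big.left : big.right]
    mu_s1 = b1[mask].mean()
    mu_s2 = b2[mask].mean()
    if mu_s1 == 0 or mu_s2 == 0:
        raise ValidationError("undefined corner split ratio: mu_S is zero")
    mu_k1 = b1[corner].mean()
    mu_k2 = b2[corner].mean()
    return float(abs(mu_k1 / mu_s1 - mu_k2 / mu_s2))


def scc_score(
    sub1: np.ndarray,
    sub2: np.ndarray,
    max_distance: int | None = None,
    smooth: int = 5,
) -> float:
    """Stratum-adjusted correlation between two equal-shaped blocks.

    Both blocks are first mean-filtered with a ``(2*smooth+1)``-wide
    window (the conventional denoising half-width for 10 kb maps; 0
    disables it), then Pearson correlation is computed per
    diagonal-distance stratum and averaged with weights
    ``N_d * sqrt(sd1_d * sd2_d)`` (stratum size times value variability);
    zero-variance strata are skipped.
    """
    a = np.asarray(sub1, dtype=float)
    b = np.asarray(sub2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("blocks must be equal-shaped square matrices")
    side = a.shape[0]
    if side < 3:
        raise ValidationError("blocks must have side >= 3")
    if smooth > 0:
        a = ndimage.uniform_filter(a, size=2 * smooth + 1)
        b = ndimage.uniform_filter(b, size=2 * smooth + 1)
    dmax = side - 1 if max_distance is None else min(max_distance, side - 1)
    num = 0.0
    den = 0.0
    for d in range(dmax + 1):
        x = np.diagonal(a, d)
        y = np.diagonal(b, d)
        if x.size < 2:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        w = x.size * np.sqrt(sx * sy)
        num += w * r
        den += w
    if den == 0:
        raise ValidationError("all strata degenerate; SCC undefined")
    return float(num / den)


def lms_score(
    sub1: np.ndarray, sub2: np.ndarray, r: int = 10, smooth: int = 5
) -> float:
    """Laplacian eigenvector similarity of two equal-shaped blocks.

    Each block (log-scaled and mean-filtered with a ``(2*smooth+1)``-wide
    window, so that block structure rather than shot noise drives the
    spectrum) is treated as a weighted graph; the first ``r`` nontrivial
    eigenvectors of its symmetric normalized Laplacian are compared after
    sign alignment:  ``1 - mean_k ||v_k1 - v_k2|| / sqrt(2)`` in [0, 1].
    """
    a = np.log1p(np.asarray(sub1, dtype=float))
    b = np.log1p(np.asarray(sub2, dtype=float))
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("blocks must be equal-shaped square matrices")
    side = a.shape[0]
    if smooth > 0:
        a = ndimage.uniform_filter(a, size=2 * smooth + 1)
        b = ndimage.uniform_filter(b, size=2 * smooth + 1)
    r = max(1, min(r, side - 1))

    def nontrivial_eigvecs(x: np.ndarray) -> np.ndarray:
        x = 0.5 * (x + x.T)
        deg = x.sum(axis=1)
        deg = np.where(deg > 0, deg, 1.0)
        dinv = 1.0 / np.sqrt(deg)
        lap = np.eye(side) - dinv[:, None] * x * dinv[None, :]
        _, vecs = np.linalg.eigh(lap)
        return vecs[:, 1 : r + 1]  # skip the trivial constant mode

    v1 = nontrivial_eigvecs(a)
    v2 = nontrivial_eigvecs(b)
    total = 0.0
    for k in range(r):
        u, v = v1[:, k], v2[:, k]
        if float(u @ v) < 0:
            v = -v
        total += np.linalg.norm(u - v) / np.sqrt(2.0)
    return float(1.0 - total / r)


def _ahash(block: np.ndarray, hash_size: int) -> np.ndarray:
    x = np.log1p(np.asarray(block, dtype=float))
    rng = x.max() - x.min()
    if rng == 0:
        img = np.zeros_like(x)
    else:
        img = (x - x.min()) / rng * 255.0
    pil = Image.fromarray(img.astype(np.uint8), mode="L")
    small = np.asarray(
        pil.resize((hash_size, hash_size), Image.LANCZOS), dtype=float
    )
    return small > small.mean()


def ihs_score(
    sub1: np.ndarray, sub2: np.ndarray, hash_size: int = 8
) -> float:
    """Average-hash image similarity of two equal-shaped blocks.

    Blocks are rendered to grayscale (log1p scaling, min-max normalized),
    down-sampled to ``hash_size**2`` pixels, thresholded at their mean into
    bit matrices, and compared:  ``1 - Hamming distance / bits`` in [0, 1].
    """
    a = np.asarray(sub1, dtype=float)
    b = np.asarray(sub2, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError("blocks must be equal-shaped matrices")
    h1 = _ahash(a, hash_size)
    h2 = _ahash(b, hash_size)
    return float(1.0 - np.mean(h1 != h2))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class SplitScoreRecord:
    """Scores and classification of one matched TAD.

    ``direction`` encodes where the big TAD lives: a big TAD in condition 1
    whose chain lies in condition 2 is a candidate *split* (in condition 2
    relative to condition 1); the mirror case is a candidate *merger*.
    """

    match: TADMatch
    csr: float
    scc: float | None = None
    lms: float | None = None
    ihs: float | None = None
    direction: str = "split"
    called: bool = False
    chrom: str = "chr1"
    bin_size: int = 10_000
    start_coord: int = 0

    @property
    def big_start_bp(self) -> int:
        return self.start_coord + self.match.big_tad.interval.left * self.bin_size

    @property
    def big_end_bp(self) -> int:
        return self.start_coord + self.match.big_tad.interval.right * self.bin_size

    @property
    def split_sites_bp(self) -> list[int]:
        """Genomic coordinates of the internal chain junctions."""
        if not self.called or self.match.n_sub < 2:
            return []
        return [
            self.start_coord + iv.right * self.bin_size
            for iv in self.match.chain[:-1]
        ]


def classify_splits_mergers(
    records: list[SplitScoreRecord], cutoff: float = 0.45
) -> list[SplitScoreRecord]:
    """Call splits/mergers at a score cutoff.

    A record is called when its corner split ratio reaches the cutoff *and*
    its chain has at least two elements (a single-element chain has no
    junction, hence nothing to call).  Records are modified in place and
    returned.
    """
    for rec in records:
        rec.called = bool(rec.csr >= cutoff and rec.match.n_sub >= 2)
    return records


def zscore_scores(score_series) -> np.ndarray:
    """Z-score normalize per-site scores across stages (last axis).

    Uses the population (1/N) standard deviation; constant series map to
    all zeros.
    """
    x = np.asarray(score_series, dtype=float)
    if x.shape[-1] < 2:
        raise ValidationError("need scores from at least 2 stages")
    if not np.all(np.isfinite(x)):
        raise ValidationError("scores must be finite")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    return np.where(sd > 0, (x - mean) / safe, 0.0)
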