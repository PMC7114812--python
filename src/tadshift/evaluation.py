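"""Benchmarking against simulation truth and end-to-end comparison.

This module wires the simulator, the TAD caller and the split/merger
scorers into reusable pipelines:

* :func:`compare_conditions` — the full two-direction comparison of two
  contact maps (splits and mergers with scores and calls);
* :func:`benchmark_scores` — ROC/AUC of the four differential scores on
  pooled replicate simulations with known merge truth;
* :func:`null_csr_scores` / :func:`calibrate_cutoff` — empirical
  false-positive-rate calibration on unchanged simulated TADs;
* :func:`jaccard_tadsets` — reproducibility of TAD calls between
  replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._rng import derive_seed
from .hic_io import (
    BinInterval,
    ContactMatrix,
    TAD,
    TADSet,
    ValidationError,
    vanilla_coverage_normalize,
)
from .simulator import SimulationConfig, SimulationTruth, simulate_pair
from .split_merge import (
    SplitScoreRecord,
    TADMatch,
    classify_splits_mergers,
    corner_split_ratio,
    ihs_score,
    lms_score,
    match_tads,
    scc_score,
)
from .tad_caller import (
    CallerConfig,
    CallerState,
    call_tads_from_state,
    caller_state,
)

__all__ = [
    "RocResult",
    "roc_auc",
    "calibrate_cutoff",
    "jaccard_tadsets",
    "boundary_recovery",
    "compare_conditions",
    "score_simulated_pair",
    "benchmark_scores",
    "null_csr_scores",
    "count_recovered_merges",
    "SCORERS",
]

SCORERS = ("csr", "scc", "lms", "ihs")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC sweep summary: parallel threshold/FPR/TPR vectors, trapezoidal
    AUC, and the minimum Euclidean distance of the curve to the ideal
    (0, 1) corner."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    distance_to_corner: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC with higher scores meaning "positive".

    Tied scores are swept together (standard step construction), which
    makes the trapezoidal AUC identical to the Mann-Whitney concordant
    pair count with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be parallel vectors")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    dist = float(np.min(np.hypot(fpr, 1.0 - tpr)))
    return RocResult(thresholds, fpr, tpr, auc, dist)


def calibrate_cutoff(null_scores, fpr_target: float) -> float:
    """Score cutoff at an empirical false-positive rate.

    Returns the ``1 - fpr_target`` quantile of the null score distribution
    (scores from unchanged TADs), using the next-higher order statistic so
    that the fraction of null scores at or above the cutoff is at most
    ``fpr_target + 1/n``.
    """
    null = np.asarray(null_scores, dtype=float)
    if not 0 < fpr_target <= 1:
        raise ValidationError("fpr_target must lie in (0, 1]")
    required = int(np.ceil(1.0 / fpr_target))
    if null.size < required:
        raise ValidationError(
            f"need >= {required} null scores for an FPR target of "
            f"{fpr_target}, got {null.size}"
        )
    if fpr_target == 1.0:
        return float(null.min())
    return float(np.quantile(null, 1.0 - fpr_target, method="higher"))


def jaccard_tadsets(
    w1: TADSet, w2: TADSet, tolerance: int = 1
) -> float:
    """Jaccard index of two TAD sets under a boundary tolerance.

    Two TADs overlap when both boundaries agree within ``tolerance`` bins;
    pairing is greedy one-to-one.  ``J = |paired| / (|w1| + |w2| -
    |paired|)``; two empty sets have J = 1 by convention.
    """
    a = list(w1)
    b = list(w2)
    if not a and not b:
        return 1.0
    used = [False] * len(b)
    paired = 0
    for t in a:
        for k, u in enumerate(b):
            if used[k]:
                continue
            if (
                abs(t.interval.left - u.interval.left) <= tolerance
                and abs(t.interval.right - u.interval.right) <= tolerance
            ):
                used[k] = True
                paired += 1
                break
    return paired / (len(a) + len(b) - paired)


def boundary_recovery(
    called: TADSet, layout: list[BinInterval], tolerance: int = 2
) -> float:
    """Fraction of true layout boundaries matched by a called boundary
    within ``tolerance`` bins."""
    truth = sorted({iv.left for iv in layout} | {iv.right for iv in layout})
    found = sorted(
        {t.interval.left for t in called} | {t.interval.right for t in called}
    )
    if not truth:
        return 1.0
    if not found:
        return 0.0
    found_arr = np.asarray(found)
    hits = sum(
        1 for bnd in truth if np.min(np.abs(found_arr - bnd)) <= tolerance
    )
    return hits / len(truth)


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def _normalized(m: ContactMatrix) -> ContactMatrix:
    return m if m.normalized != "raw" else vanilla_coverage_normalize(m)


def _score_matches(
    matches: list[TADMatch],
    norm_big: ContactMatrix,
    norm_other: ContactMatrix,
    scorers: tuple[str, ...],
    direction: str,
    chrom: str,
    bin_size: int,
) -> list[SplitScoreRecord]:
    records = []
    for match in matches:
        big = match.big_tad.interval
        b1 = norm_big.values[big.left : big.right, big.left : big.right]
        b2 = norm_other.values[big.left : big.right, big.left : big.right]
        rec = SplitScoreRecord(
            match=match,
            csr=corner_split_ratio(norm_big, norm_other, match),
            direction=direction,
            chrom=chrom,
            bin_size=bin_size,
        )
        if "scc" in scorers:
            try:
                rec.scc = scc_score(b1, b2)
            except ValidationError:
                rec.scc = None
        if "lms" in scorers:
            rec.lms = lms_score(b1, b2)
        if "ihs" in scorers:
            rec.ihs = ihs_score(b1, b2)
        records.append(rec)
    return records


def compare_conditions(
    m1: ContactMatrix,
    m2: ContactMatrix,
    caller_config: CallerConfig | None = None,
    cutoff: float = 0.45,
    scorers: tuple[str, ...] = ("csr",),
    chrom: str = "chr1",
) -> tuple[list[SplitScoreRecord], TADSet, TADSet]:
    """Full two-direction split/merger comparison of two contact maps.

    Both matrices are vanilla-coverage normalized if raw, TADs are called
    in each, each condition's TADs are matched against the other
    condition's boundary densities, and every match is scored and
    classified at ``cutoff``.  Returns the records plus the two TAD sets.
    """
    if m1.n_bins != m2.n_bins:
        raise ValidationError(
            f"matrix sizes differ: {m1.n_bins} vs {m2.n_bins}"
        )
    cfg = caller_config or CallerConfig()
    # boundary detection uses the matrices as given (vanilla coverage
    # normalization systematically inflates low-coverage boundary bins and
    # blunts the very contact steps the caller relies on); the differential
    # scores are computed on normalized maps, the dialect of Eq-style
    # corner ratios
    n1 = _normalized(m1)
    n2 = _normalized(m2)
    state1 = caller_state(m1, replace(cfg, seed=derive_seed(cfg.seed, "c1")))
    state2 = caller_state(m2, replace(cfg, seed=derive_seed(cfg.seed, "c2")))
    tads1 = call_tads_from_state(state1)
    tads2 = call_tads_from_state(state2)
    records = _score_matches(
        match_tads(tads1, state2), n1, n2, scorers, "split",
        chrom, m1.bin_size,
    ) + _score_matches(
        match_tads(tads2, state1), n2, n1, scorers, "merger",
        chrom, m1.bin_size,
    )
    classify_splits_mergers(records, cutoff)
    return records, tads1, tads2


def _locate_reference_tads(
    called: TADSet, truth_layout: list[BinInterval], tolerance: int = 3
) -> list[TAD]:
    """Reference TADs for benchmark scoring: for each truth TAD, the
    called TAD with both boundaries within ``tolerance`` bins (closest
    total deviation), falling back to the truth interval when the caller
    missed it."""
    refs: list[TAD] = []
    for iv in truth_layout:
        best = None
        best_dev = tolerance * 2 + 1
        for t in called:
            dev = abs(t.interval.left - iv.left) + abs(
                t.interval.right - iv.right
            )
            if (
                abs(t.interval.left - iv.left) <= tolerance
                and abs(t.interval.right - iv.right) <= tolerance
                and dev < best_dev
            ):
                best = t
                best_dev = dev
        refs.append(best if best is not None else TAD(iv, 0.0))
    return refs


def score_simulated_pair(
    m1: ContactMatrix,
    m2: ContactMatrix,
    truth: SimulationTruth,
    caller_config: CallerConfig | None = None,
    scorers: tuple[str, ...] = SCORERS,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Score every reference TAD of a simulated pair with each scorer.

    The reference side is the second condition (it carries the merged
    super-TADs); its called TADs are matched against the first condition's
    boundary densities.  Similarity scores (SCC/LMS/IHS) are negated so
    that higher always means "more changed".  Returns per-scorer score
    vectors and the truth labels.
    """
    cfg = caller_config or CallerConfig()
    n1 = _normalized(m1)
    n2 = _normalized(m2)
    # TAD detection on the raw maps; differential scoring on normalized
    state1 = caller_state(m1, replace(cfg, seed=derive_seed(cfg.seed, "c1")))
    state2 = caller_state(m2, replace(cfg, seed=derive_seed(cfg.seed, "c2")))
    called2 = call_tads_from_state(state2)
    refs = _locate_reference_tads(called2, truth.layout_c2)
    matches = match_tads(refs, state1)
    out: dict[str, list[float]] = {sc: [] for sc in scorers}
    for match in matches:
        big = match.big_tad.interval
        b1 = n1.values[big.left : big.right, big.left : big.right]
        b2 = n2.values[big.left : big.right, big.left : big.right]
        if "csr" in scorers:
            out["csr"].append(corner_split_ratio(n2, n1, match))
        if "scc" in scorers:
            try:
                out["scc"].append(-scc_score(b1, b2))
            except ValidationError:
                out["scc"].append(0.0)
        if "lms" in scorers:
            out["lms"].append(-lms_score(b1, b2))
        if "ihs" in scorers:
            out["ihs"].append(-ihs_score(b1, b2))
    labels = np.asarray(truth.labels, dtype=bool)
    return {sc: np.asarray(v) for sc, v in out.items()}, labels


def benchmark_scores(
    replicates: int,
    config: SimulationConfig | None = None,
    scorers: tuple[str, ...] = SCORERS,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
) -> dict[str, RocResult]:
    """Pooled ROC per scorer over seeded replicate simulations."""
    if replicates < 1:
        raise ValidationError("need at least 1 replicate")
    config = config or SimulationConfig()
    pooled: dict[str, list[np.ndarray]] = {sc: [] for sc in scorers}
    all_labels: list[np.ndarray] = []
    for rep in range(replicates):
        rep_cfg = replace(config, seed=derive_seed(seed, "sim", rep))
        ccfg = replace(
            caller_config or CallerConfig(),
            seed=derive_seed(seed, "caller", rep),
        )
        m1, m2, truth = simulate_pair(rep_cfg)
        scores, labels = score_simulated_pair(
            m1, m2, truth, caller_config=ccfg, scorers=scorers
        )
        for sc in scorers:
            pooled[sc].append(scores[sc])
        all_labels.append(labels)
    labels = np.concatenate(all_labels)
    return {
        sc: roc_auc(np.concatenate(pooled[sc]), labels) for sc in scorers
    }


def null_csr_scores(
    n_scores: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
) -> np.ndarray:
    """Corner-split-ratio scores on simulated *unchanged* TAD pairs.

    Pairs share their layout (``n_merges = 0``) and differ only by
    independent Poisson noise, so every score is a null draw; replicate
    pairs are accumulated until ``n_scores`` scores are collected.
    """
    base = config or SimulationConfig()
    if base.n_merges != 0:
        base = replace(base, n_merges=0)
    out: list[float] = []
    rep = 0
    while len(out) < n_scores:
        rep_cfg = replace(base, seed=derive_seed(seed, "null-sim", rep))
        ccfg = replace(
            caller_config or CallerConfig(),
            seed=derive_seed(seed, "null-caller", rep),
        )
        m1, m2, truth = simulate_pair(rep_cfg)
        scores, _ = score_simulated_pair(
            m1, m2, truth, caller_config=ccfg, scorers=("csr",)
        )
        out.extend(scores["csr"].tolist())
        rep += 1
    return np.asarray(out[:n_scores])


def count_recovered_merges(
    records: list[SplitScoreRecord],
    truth: SimulationTruth,
    tolerance: int = 10,
) -> int:
    """Number of true merged super-TADs recovered as called mergers."""
    merged = [
        BinInterval(a.left, b.right) for a, b in truth.merged_pairs
    ]
    recovered = 0
    for iv in merged:
        for rec in records:
            if rec.direction != "merger" or not rec.called:
                continue
            big = rec.match.big_tad.interval
            if (
                abs(big.left - iv.left) <= tolerance
                and abs(big.right - iv.right) <= tolerance
            ):
                recovered += 1
                break
    return recovered
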