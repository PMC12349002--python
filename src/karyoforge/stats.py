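"""Block-level statistics: collinearity degree, one-way ANOVA, the arm-length
randomization test, and TE-class composition in blocks vs 30-gene flanks.

The randomization test asks whether syntenic blocks fall on ancestral
chromosome arms in proportion to arm length: under the null each block lands
on arm *a* with probability ``length_a / total_length``; the observed chi-square
form statistic is compared against multinomial simulations, with the +1
Monte-Carlo correction so p is never exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .io import TE_CLASSES, GeneTable

logger = logging.getLogger(__name__)


@dataclass
class DegreeRecord:
    """Gene pairs per syntenic block — higher means longer, better-preserved blocks."""

    comparison_id: str
    n_gene_pairs: int
    n_blocks: int
    degree: float  # NaN when n_blocks == 0


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    permutation_p: float | None = None
    n_perm: int = 0
    seed: int | None = None


@dataclass
class RandomizationResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    p_value: float
    n_sim: int
    seed: int
    arm_ids: list = field(default_factory=list)


@dataclass
class TECompositionRow:
    region_id: str
    region_kind: str  # block | flank_up | flank_down
    chromosome: str
    span_bp: int
    percents: dict  # te_class -> percent of span covered
    truncated: bool = False


# ---------------------------------------------------------------------------


def collinearity_degree(blocks, comparison_id: str = "") -> DegreeRecord:
    """Total anchor pairs / block count."""
    n_blocks = len(blocks)
    n_pairs = sum(b.n_pairs for b in blocks)
    if n_blocks == 0:
        warnings.warn(f"{comparison_id or 'comparison'}: zero blocks, degree undefined", stacklevel=2)
        return DegreeRecord(comparison_id, 0, 0, float("nan"))
    return DegreeRecord(comparison_id, n_pairs, n_blocks, n_pairs / n_blocks)


def anova_oneway(groups: dict, n_perm: int = 1000, seed: int = 0) -> AnovaResult:
    """Classical one-way F test across labeled groups of degree values, plus a
    label-permutation p as a robustness companion.

    All-identical values give F = 0, p = 1 (no variance to explain).
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("anova_oneway needs at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    if not any(len(a) >= 2 for a in arrays):
        raise ValueError("at least one group needs >= 2 values")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return AnovaResult(0.0, 1.0, 1.0, n_perm, seed)
    f_obs, p = sps.f_oneway(*arrays)
    rng = np.random.default_rng(seed)
    sizes = [len(a) for a in arrays]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        f_p, _ = sps.f_oneway(*parts)
        if f_p >= f_obs:
            count += 1
    return AnovaResult(float(f_obs), float(p), (1 + count) / (n_perm + 1), n_perm, seed)


def arm_randomization_test(
    observed,
    arm_lengths,
    n_sim: int = 10000,
    seed: int = 0,
    arm_ids: list | None = None,
) -> RandomizationResult:
    """Monte-Carlo test of block allocation proportional to arm lengths.

    ``observed`` and ``arm_lengths`` are parallel per-arm vectors (or dicts with
    matching keys).  statistic = sum (obs - exp)^2 / exp;
    p = (1 + #{sim >= obs}) / (n_sim + 1).
    """
    if isinstance(observed, dict):
        arm_ids = sorted(observed)
        lengths = np.array([arm_lengths[a] for a in arm_ids], dtype=float)
        obs = np.array([observed[a] for a in arm_ids], dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
        lengths = np.asarray(arm_lengths, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least two arms")
    if (lengths <= 0).any():
        raise ValueError("nonpositive arm length")
    n = int(obs.sum())
    if n < 1:
        raise ValueError("need at least one observed block")
    probs = lengths / lengths.sum()
    expected = n * probs
    statistic = float(((obs - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, probs, size=n_sim)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=1)
    p = (1 + int((sim_stats >= statistic).sum())) / (n_sim + 1)
    return RandomizationResult(
        observed=obs, expected=expected, statistic=statistic,
        p_value=p, n_sim=n_sim, seed=seed, arm_ids=list(arm_ids or []),
    )


def calibration_pvalues(
    arm_lengths, n_blocks: int, n_replicates: int = 500, n_sim: int = 4000, seed: int = 0
) -> np.ndarray:
    """p-values of the arm randomization test when the observed counts are
    themselves drawn from the null — used to check uniformity / type-I error."""
    lengths = np.asarray(arm_lengths, dtype=float)
    probs = lengths / lengths.sum()
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        obs = rng.multinomial(n_blocks, probs)
        res = arm_randomization_test(obs, lengths, n_sim=n_sim, seed=int(rng.integers(2**31 - 1)))
        out[i] = res.p_value
    return out


# ---------------------------------------------------------------------------
# TE composition
# ---------------------------------------------------------------------------


def _merged_coverage(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int) -> int:
    """Total bp of the union of intervals clipped to [lo, hi)."""
    s = np.clip(starts, lo, hi)
    e = np.clip(ends, lo, hi)
    keep = e > s
    s, e = s[keep], e[keep]
    if len(s) == 0:
        return 0
    order = np.argsort(s, kind="mergesort")
    s, e = s[order], e[order]
    total, cur_s, cur_e = 0, s[0], e[0]
    for i in range(1, len(s)):
        if s[i] <= cur_e:
            cur_e = max(cur_e, e[i])
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s[i], e[i]
    total += cur_e - cur_s
    return int(total)


def te_composition(
    blocks,
    te_intervals,
    genetable: GeneTable,
    flank_genes: int = 30,
    side: str = "b",
) -> list[TECompositionRow]:
    """Per-class TE percent of span for each block and its two flanks.

    A block's region runs from the first to the last anchor gene in bp; flanks
    are the ``flank_genes`` genes immediately up/downstream (truncated at
    chromosome ends and flagged).  Same-class intervals are merged before
    measuring so overlaps never double-count.
    """
    trees = {}
    for te in te_intervals:
        trees.setdefault((te.chromosome, te.te_class), IntervalTree()).addi(te.start, te.end)
    te_chroms = {te.chromosome for te in te_intervals}

    def measure(chrom, lo_bp, hi_bp):
        span = hi_bp - lo_bp
        out = {}
        for cls in TE_CLASSES:
            tree = trees.get((chrom, cls))
            if tree is None or span <= 0:
                out[cls] = 0.0
                continue
            hits = tree.overlap(lo_bp, hi_bp)
            if not hits:
                out[cls] = 0.0
                continue
            starts = np.fromiter((h.begin for h in hits), dtype=np.int64)
            ends = np.fromiter((h.end for h in hits), dtype=np.int64)
            out[cls] = 100.0 * _merged_coverage(starts, ends, lo_bp, hi_bp) / span
        return out

    rows = []
    for b in blocks:
        chrom = b.chrom_b if side == "b" else b.chrom_a
        lo, hi = b.span_b if side == "b" else b.span_a
        size = genetable.chrom_size(chrom)
        if chrom not in te_chroms:
            warnings.warn(f"block {b.block_id}: chromosome {chrom} missing from TE annotation", stacklevel=2)
        lo_bp, hi_bp = genetable.bp_span(chrom, lo, hi)
        rows.append(TECompositionRow(b.block_id, "block", chrom, hi_bp - lo_bp, measure(chrom, lo_bp, hi_bp)))
        # upstream flank
        up_lo = max(0, lo - flank_genes)
        if up_lo < lo:
            f_lo, f_hi = genetable.bp_span(chrom, up_lo, lo - 1)
            rows.append(
                TECompositionRow(b.block_id, "flank_up", chrom, f_hi - f_lo,
                                 measure(chrom, f_lo, f_hi), truncated=(lo - up_lo) < flank_genes)
            )
        else:
            rows.append(TECompositionRow(b.block_id, "flank_up", chrom, 0,
                                         {c: 0.0 for c in TE_CLASSES}, truncated=True))
        # downstream flank
        down_hi = min(size - 1, hi + flank_genes)
        if down_hi > hi:
            f_lo, f_hi = genetable.bp_span(chrom, hi + 1, down_hi)
            rows.append(
                TECompositionRow(b.block_id, "flank_down", chrom, f_hi - f_lo,
                                 measure(chrom, f_lo, f_hi), truncated=(down_hi - hi) < flank_genes)
            )
        else:
            rows.append(TECompositionRow(b.block_id, "flank_down", chrom, 0,
                                         {c: 0.0 for c in TE_CLASSES}, truncated=True))
    return rows


def composition_contrast(rows) -> dict:
    """Descriptive block-minus-flank percent per class, span-weighted over regions."""
    sums = {kind: {c: 0.0 for c in TE_CLASSES} for kind in ("block", "flank_up", "flank_down")}
    spans = {kind: 0 for kind in sums}
    for r in rows:
        for c in TE_CLASSES:
            sums[r.region_kind][c] += r.percents[c] * r.span_bp
        spans[r.region_kind] += r.span_bp
    mean = {
        kind: {c: (sums[kind][c] / spans[kind] if spans[kind] else 0.0) for c in TE_CLASSES}
        for kind in sums
    }
    flank_span = spans["flank_up"] + spans["flank_down"]
    flank = {
        c: ((sums["flank_up"][c] + sums["flank_down"][c]) / flank_span if flank_span else 0.0)
        for c in TE_CLASSES
    }
    return {
        "block": mean["block"],
        "flank": flank,
        "difference": {c: mean["block"][c] - flank[c] for c in TE_CLASSES},
    }
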