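"""Anchor construction and collinear-block chaining in gene-rank space.

Homologous gene pairs become *anchors*, points in the rank-by-rank dot plot of a
chromosome pair.  Blocks are extracted per chromosome pair by iterated
best-chain dynamic programming: a legal chain is strictly monotone in both rank
coordinates (increasing/increasing for "+" blocks, increasing/decreasing for
"-"), with consecutive anchors at most ``max_gap`` genes apart on either axis.
The chain score is its anchor count; the best chain is removed and extraction
repeats until the best score drops below ``min_pairs``.  Ties are broken by
smaller rank_a span, then smaller starting rank_a, then "+" orientation, which
makes the output deterministic.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import GeneTable, HomologyPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    """One homologous gene pair placed in the rank space of two chromosomes."""

    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str
    gene_a: str
    gene_b: str


@dataclass
class ChainParams:
    """Chaining/filtering knobs.  ``self_mode`` drops the trivial identity
    diagonal when a genome is compared with itself."""

    max_gap: int = 25
    min_pairs: int = 5
    self_mode: bool = False

    def __post_init__(self):
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")


@dataclass
class SyntenyBlock:
    """A chained run of homologous gene pairs between two chromosomes."""

    block_id: str
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    orientation: str
    anchors: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        ra = [a.rank_a for a in self.anchors]
        return min(ra), max(ra)

    @property
    def span_b(self) -> tuple[int, int]:
        rb = [a.rank_b for a in self.anchors]
        return min(rb), max(rb)


@dataclass
class DepthProfile:
    """Per-gene block coverage counts on a reference genome."""

    depths: dict  # chromosome -> np.ndarray of per-rank counts
    modal_ratio: str
    no_signal: bool

    def nonzero_depths(self) -> np.ndarray:
        vals = np.concatenate([v for v in self.depths.values()]) if self.depths else np.array([])
        return vals[vals > 0]


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def build_anchors(table_a: GeneTable, table_b: GeneTable, pairs) -> list[Anchor]:
    """One anchor per homology pair whose genes both sit on chromosomes.

    Pairs referencing genes absent from either table (scaffold-excluded, or
    simply not in the genome) are skipped; the skip count is logged.
    """
    anchors = []
    skipped = 0
    for p in pairs:
        if p.query_id not in table_a or p.subject_id not in table_b:
            skipped += 1
            continue
        anchors.append(
            Anchor(
                rank_a=table_a.rank_of(p.query_id),
                rank_b=table_b.rank_of(p.subject_id),
                chrom_a=table_a.chrom_of(p.query_id),
                chrom_b=table_b.chrom_of(p.subject_id),
                gene_a=p.query_id,
                gene_b=p.subject_id,
            )
        )
    if skipped:
        logger.info(
            "build_anchors %s vs %s: skipped %d pairs with unknown genes",
            table_a.species_id, table_b.species_id, skipped,
        )
    build_anchors.last_skipped = skipped
    return anchors


build_anchors.last_skipped = 0


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _best_chain(ra: np.ndarray, rb: np.ndarray, max_gap: int):
    """Best strictly-increasing chain of the points (ra, rb).

    Returns (score, span_a, start_a, member_indices) where ties were broken by
    smaller rank_a span then smaller starting rank_a.  Indices refer to the
    input arrays.
    """
    n = len(ra)
    if n == 0:
        return 0, 0, 0, []
    order = np.lexsort((rb, ra))
    ra_s, rb_s = ra[order], rb[order]
    L = np.ones(n, dtype=np.int64)
    first = ra_s.copy()          # chain start rank_a (for span tie-breaks)
    pred = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        da = ra_s[i] - ra_s[:i]
        db = rb_s[i] - rb_s[:i]
        ok = (da >= 1) & (da <= max_gap) & (db >= 1) & (db <= max_gap)
        if not ok.any():
            continue
        cand = np.nonzero(ok)[0]
        lc = L[cand]
        best_len = lc.max()
        top = cand[lc == best_len]
        # same endpoint: minimising span == maximising chain start
        j = top[np.argmax(first[top])]
        L[i] = best_len + 1
        first[i] = first[j]
        pred[i] = j
    span = ra_s - first
    # pick the globally best end: max score, min span, min start, then stable
    best = 0
    for i in range(1, n):
        key_i = (L[i], -span[i], -first[i])
        key_b = (L[best], -span[best], -first[best])
        if key_i > key_b:
            best = i
    members = []
    i = best
    while i >= 0:
        members.append(order[i])
        i = pred[i]
    members.reverse()
    return int(L[best]), int(span[best]), int(first[best]), members


def chain_anchors(anchors, params: ChainParams, species_a: str = "A", species_b: str = "B") -> list[SyntenyBlock]:
    """Extract collinear blocks per chromosome pair by iterated best-chain DP."""
    groups = defaultdict(list)
    for a in anchors:
        groups[(a.chrom_a, a.chrom_b)].append(a)
    blocks = []
    counter = 0
    for (ca, cb) in sorted(groups):
        group = sorted(groups[(ca, cb)], key=lambda a: (a.rank_a, a.rank_b, a.gene_a, a.gene_b))
        live = np.ones(len(group), dtype=bool)
        ra_all = np.array([a.rank_a for a in group], dtype=np.int64)
        rb_all = np.array([a.rank_b for a in group], dtype=np.int64)
        while live.sum() >= params.min_pairs:
            idx = np.nonzero(live)[0]
            ra, rb = ra_all[idx], rb_all[idx]
            sf, spf, stf, mf = _best_chain(ra, rb, params.max_gap)
            sr, spr, str_, mr = _best_chain(ra, -rb, params.max_gap)
            # score desc, span asc, start asc, '+' preferred on exact tie
            if (sf, -spf, -stf) >= (sr, -spr, -str_):
                score, members, orient = sf, mf, "+"
            else:
                score, members, orient = sr, mr, "-"
            if score < params.min_pairs:
                break
            counter += 1
            chosen = [group[idx[m]] for m in members]
            blocks.append(
                SyntenyBlock(
                    block_id=f"{species_a}.{species_b}.{counter:05d}",
                    species_a=species_a, species_b=species_b,
                    chrom_a=ca, chrom_b=cb, orientation=orient, anchors=chosen,
                )
            )
            live[idx[members]] = False
    return blocks


def filter_blocks(blocks, params: ChainParams) -> list[SyntenyBlock]:
    """Drop undersized blocks; in self mode also drop the identity diagonal
    (same chromosome, >=90% of anchors with rank_a == rank_b)."""
    out = []
    for b in blocks:
        if b.n_pairs < params.min_pairs:
            continue
        if params.self_mode and b.chrom_a == b.chrom_b:
            diag = sum(1 for a in b.anchors if a.rank_a == a.rank_b)
            if diag >= 0.9 * b.n_pairs:
                continue
        out.append(b)
    return out


# ---------------------------------------------------------------------------
# coverage / homology relations / depth
# ---------------------------------------------------------------------------


def _covered_ranks(spans, size) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for lo, hi in spans:
        mask[max(lo, 0): min(hi, size - 1) + 1] = True
    return mask


def coverage(blocks, table: GeneTable, side: str = "a") -> dict:
    """Fraction of each chromosome's genes inside the union of block anchor spans,
    keyed by (chromosome, partner chromosome).  ``side`` selects which side of the
    blocks lives on ``table``."""
    spans = defaultdict(list)
    for b in blocks:
        if side == "a":
            spans[(b.chrom_a, b.chrom_b)].append(b.span_a)
        else:
            spans[(b.chrom_b, b.chrom_a)].append(b.span_b)
    out = {}
    for (chrom, partner), sp in spans.items():
        size = table.chrom_size(chrom)
        out[(chrom, partner)] = float(_covered_ranks(sp, size).sum()) / size if size else 0.0
    return out


def classify_chromosome_homology(
    blocks,
    table_a: GeneTable,
    table_b: GeneTable,
    theta_whole: float = 0.6,
    theta_arm: float = 0.6,
    centromeres: dict | None = None,
    classify_arms: bool = False,
) -> dict:
    """Relation per chromosome pair in {whole, arm, segmental, none}.

    whole: reciprocal coverage >= theta_whole both ways and each chromosome is
    the other's top partner.  arm (only with centromere ranks, keyed
    ``(species_id, chromosome) -> rank``): the coverage of one partner is
    concentrated within a single arm of the other.  segmental: any block
    survives.  Pairs with no blocks are simply absent ("none").
    """
    if classify_arms and centromeres is None:
        raise ValueError("arm classification requested but no centromere ranks given")
    cov_a = coverage(blocks, table_a, side="a")
    cov_b = coverage(blocks, table_b, side="b")
    top_a = {}
    for (ca, cb), v in cov_a.items():
        if ca not in top_a or v > cov_a[(ca, top_a[ca])]:
            top_a[ca] = cb
    top_b = {}
    for (cb, ca), v in cov_b.items():
        if cb not in top_b or v > cov_b[(cb, top_b[cb])]:
            top_b[cb] = ca

    by_pair = defaultdict(list)
    for b in blocks:
        by_pair[(b.chrom_a, b.chrom_b)].append(b)
    relations = {}
    for (ca, cb), bl in by_pair.items():
        va = cov_a.get((ca, cb), 0.0)
        vb = cov_b.get((cb, ca), 0.0)
        if va >= theta_whole and vb >= theta_whole and top_a.get(ca) == cb and top_b.get(cb) == ca:
            relations[(ca, cb)] = "whole"
            continue
        if classify_arms:
            rel = None
            for chrom, table, side in ((cb, table_b, "b"), (ca, table_a, "a")):
                cen = centromeres.get((table.species_id, chrom))
                if cen is None:
                    continue
                size = table.chrom_size(chrom)
                spans = [b.span_b if side == "b" else b.span_a for b in bl]
                mask = _covered_ranks(spans, size)
                left, right = mask[:cen].sum(), mask[cen:].sum()
                total_cov = left + right
                if total_cov == 0:
                    continue
                for arm_cov, arm_len in ((left, cen), (right, size - cen)):
                    if arm_len > 0 and arm_cov / arm_len >= theta_arm and arm_cov / total_cov >= theta_arm:
                        rel = "arm"
                        break
                if rel:
                    break
            if rel:
                relations[(ca, cb)] = rel
                continue
        relations[(ca, cb)] = "segmental"
    return relations


def syntenic_depth(blocks, reference: GeneTable) -> DepthProfile:
    """Per reference gene, the number of blocks whose rank_a span contains it.

    The modal ratio is the mode of the nonzero depths expressed ``mode:1`` —
    a 2:1 mode against a putative ancestor is the classic single-WGD signature.
    """
    depths = {c: np.zeros(reference.chrom_size(c), dtype=np.int64) for c in reference.chromosomes}
    for b in blocks:
        if b.chrom_a in depths:
            lo, hi = b.span_a
            depths[b.chrom_a][lo: hi + 1] += 1
    nz = np.concatenate([v for v in depths.values()]) if depths else np.array([], dtype=np.int64)
    nz = nz[nz > 0]
    if len(nz) == 0:
        logger.warning("syntenic_depth: no duplication signal (all depths zero)")
        return DepthProfile(depths=depths, modal_ratio="0:1", no_signal=True)
    mode = Counter(nz.tolist()).most_common(1)[0][0]
    return DepthProfile(depths=depths, modal_ratio=f"{mode}:1", no_signal=False)
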