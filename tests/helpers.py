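"""Shared fixtures-in-code for the test suite: tiny deterministic gene tables,
homology pairs, hand-built blocks, and an independent chaining oracle."""

from __future__ import annotations

import functools

import pandas as pd

from karyoforge.io import GeneTable, HomologyPair
from karyoforge.synteny import Anchor, SyntenyBlock


def gene_id(species: str, chrom: str, rank: int) -> str:
    return f"{species}.{chrom}.g{rank:04d}"


def make_table(species: str, chrom_sizes: dict, gene_len: int = 1000, gap: int = 500) -> GeneTable:
    """A gene table with ``chrom_sizes[chrom]`` equally spaced genes per chromosome."""
    rows = []
    for chrom in sorted(chrom_sizes):
        pos = 0
        for i in range(chrom_sizes[chrom]):
            start = pos + gap
            end = start + gene_len
            rows.append((gene_id(species, chrom, i), chrom, start, end, "+"))
            pos = end
    frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GeneTable(species, frame)


def pairs_between(ta: GeneTable, tb: GeneTable, mapping, evalue: float = 1e-20, bitscore: float = 500.0):
    """HomologyPairs from a list of (chrom_a, rank_a, chrom_b, rank_b)."""
    return [
        HomologyPair(
            gene_id(ta.species_id, ca, ra), gene_id(tb.species_id, cb, rb), evalue, bitscore
        )
        for ca, ra, cb, rb in mapping
    ]


def block_from_ranks(bid, sa, sb, ca, cb, rank_pairs, orientation="+") -> SyntenyBlock:
    anchors = [Anchor(ra, rb, ca, cb, f"a{ra}", f"b{rb}") for ra, rb in rank_pairs]
    return SyntenyBlock(bid, sa, sb, ca, cb, orientation, anchors)


def best_chain_oracle(ra, rb, max_gap: int) -> int:
    """Length of the longest legal chain over anchors (ra[i], rb[i]).

    A legal chain is strictly increasing in rank_a and strictly monotone in
    rank_b (one orientation), with consecutive steps at most ``max_gap`` apart
    on both axes.  Exhaustive longest-path search with memoisation, written
    independently of the library's vectorised DP.
    """
    n = len(ra)
    best = 0
    for sign in (1, -1):

        @functools.lru_cache(maxsize=None)
        def longest(i, _sign=sign):
            length = 1
            for j in range(n):
                da = ra[j] - ra[i]
                db = _sign * (rb[j] - rb[i])
                if 1 <= da <= max_gap and 1 <= db <= max_gap:
                    length = max(length, 1 + longest(j))
            return length

        for i in range(n):
            best = max(best, longest(i))
        longest.cache_clear()
    return best
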