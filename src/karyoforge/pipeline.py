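"""End-to-end orchestration: homology -> anchors -> blocks -> relations ->
two-round reconstruction -> painting -> recovery scoring."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .ancestor import (
    AncestralKaryotype,
    Painting,
    agk_gene_table,
    build_ancestral_karyotype,
    karyotype_from_genome,
    project_karyotype,
)
from .io import GeneTable, HomologyPair, filter_homology
from .simulate import SimDataset, evaluate_recovery, homology_for_filter
from .synteny import (
    ChainParams,
    build_anchors,
    chain_anchors,
    classify_chromosome_homology,
    filter_blocks,
)


@dataclass
class ReconstructionParams:
    chain: ChainParams = field(default_factory=ChainParams)
    evalue_max: float = 1e-5
    top_k: int = 5
    theta_whole: float = 0.6
    theta_arm: float = 0.6
    min_species: int = 3
    smooth_window: int = 30


def blocks_for_pair(table_a: GeneTable, table_b: GeneTable, pairs, chain: ChainParams):
    """Anchors -> chained blocks -> filtered blocks for one genome pair."""
    anchors = build_anchors(table_a, table_b, pairs)
    blocks = chain_anchors(anchors, chain, species_a=table_a.species_id, species_b=table_b.species_id)
    return filter_blocks(blocks, chain)


def reconstruct(tables: dict, species_order: list, pair_provider, params: ReconstructionParams):
    """Build the ancestral karyotype from the configured species.

    ``pair_provider(s1, s2)`` must return filtered HomologyPairs with queries
    from s1.  Returns (karyotype, agk_table, agk_provenance, blocks_by_pair,
    relations_by_pair).
    """
    blocks_by_pair, relations = {}, {}
    for sa, sb in combinations(species_order, 2):
        blocks = blocks_for_pair(tables[sa], tables[sb], pair_provider(sa, sb), params.chain)
        blocks_by_pair[(sa, sb)] = blocks
        relations[(sa, sb)] = classify_chromosome_homology(
            blocks, tables[sa], tables[sb],
            theta_whole=params.theta_whole, theta_arm=params.theta_arm,
        )
    karyotype = build_ancestral_karyotype(
        tables, blocks_by_pair, species_order, relations, min_species=params.min_species
    )
    agk_table, provenance = agk_gene_table(karyotype, tables)
    return karyotype, agk_table, provenance, blocks_by_pair, relations


def agk_target_pairs(
    provenance: dict,
    target_species: str,
    frame_provider,
    evalue_max: float = 1e-5,
    top_k: int = 5,
) -> list[HomologyPair]:
    """Homology between the mixed-species AGK gene set and one target genome.

    Each ancestral gene inherits the hits of its source gene from the relevant
    species-pair table (``frame_provider(s1, s2)`` -> raw table, queries from
    s1); the combined table is then E-value filtered and best-hit capped like
    any other.
    """
    prov = pd.DataFrame(
        [(gid, sp, orig) for gid, (sp, orig) in provenance.items()],
        columns=["agk_gid", "species", "orig"],
    )
    parts = []
    for sp in sorted(prov["species"].unique()):
        sub = prov[prov["species"] == sp]
        frame = frame_provider(sp, target_species)
        if frame is None or not len(frame):
            continue
        merged = sub.merge(frame, left_on="orig", right_on="query_id", how="inner")
        parts.append(merged[["agk_gid", "subject_id", "evalue", "bitscore"]])
    if not parts:
        return []
    df = pd.concat(parts, ignore_index=True).rename(columns={"agk_gid": "query_id"})
    return filter_homology(df, evalue_max=evalue_max, top_k=top_k)


def identity_pairs(provenance: dict) -> list[HomologyPair]:
    """Perfect self-hits between AGK genes and their own source genes."""
    return [
        HomologyPair(gid, orig, 0.0, 1e4)
        for gid, (_sp, orig) in sorted(provenance.items())
    ]


def paint_target(
    agk_table: GeneTable,
    target: GeneTable,
    pairs,
    params: ReconstructionParams,
) -> tuple[Painting, list]:
    """Chain AGK-vs-target blocks and paint the target genome."""
    blocks = blocks_for_pair(agk_table, target, pairs, params.chain)
    painting = project_karyotype(agk_table, target, blocks, smooth_window=params.smooth_window)
    return painting, blocks


def self_projection(table: GeneTable, params: ReconstructionParams | None = None):
    """Project a genome onto the karyotype built from itself (identity check)."""
    params = params or ReconstructionParams()
    karyotype = karyotype_from_genome(table)
    agk_table, provenance = agk_gene_table(karyotype, {table.species_id: table})
    painting, blocks = paint_target(agk_table, table, identity_pairs(provenance), params)
    return karyotype, painting, blocks


# ---------------------------------------------------------------------------
# simulated-data entry points
# ---------------------------------------------------------------------------


def dataset_pair_provider(dataset: SimDataset, params: ReconstructionParams):
    def get(s1: str, s2: str):
        frame = homology_for_filter(dataset.homology_frame(s1, s2))
        return filter_homology(frame, evalue_max=params.evalue_max, top_k=params.top_k)

    return get


def dataset_frame_provider(dataset: SimDataset):
    def get(s1: str, s2: str):
        return homology_for_filter(dataset.homology_frame(s1, s2))

    return get


def run_recovery(dataset: SimDataset, params: ReconstructionParams | None = None):
    """Reconstruct from a simulated dataset, paint every descendant, and score
    the result against the truth.  Returns (report, karyotype, paintings)."""
    params = params or ReconstructionParams()
    species_order = list(dataset.config.species)
    tables = dataset.tables
    pair_provider = dataset_pair_provider(dataset, params)
    karyotype, agk_table, provenance, _blocks, _rel = reconstruct(
        tables, species_order, pair_provider, params
    )
    frame_provider = dataset_frame_provider(dataset)
    paintings = {}
    for sp in species_order:
        pairs = agk_target_pairs(provenance, sp, frame_provider,
                                 evalue_max=params.evalue_max, top_k=params.top_k)
        paintings[sp], _ = paint_target(agk_table, tables[sp], pairs, params)
    report = evaluate_recovery(karyotype, paintings, dataset)
    return report, karyotype, paintings
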