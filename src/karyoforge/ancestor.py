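"""Two-round ancestral-karyotype reconstruction, painting and arm mapping.

Round 1 seeds proto-chromosomes from *whole-chromosome* homology relations
between divergent species pairs: chromosome pairs homologous across their
entire lengths (inversions ignored) are unified transitively into seeds.
Round 2 assigns the residual chromosomes/segments to seeds (or founds new
protos) when at least ``min_species`` species exhibit blocks linking a segment
consistently to the same proto context.  Partial protos are then consolidated
when two species co-localise them on single chromosomes without contradiction,
and for every homologous region the most continuous candidate segment is
selected as the representative.  Proto-chromosomes are finally named AGK1,
AGK2, ... by descending gene count.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .io import GeneTable
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """A gene-rank interval (inclusive) of one source chromosome."""

    species: str
    chromosome: str
    rank_lo: int
    rank_hi: int

    @property
    def size(self) -> int:
        return self.rank_hi - self.rank_lo + 1

    def contains(self, rank: int) -> bool:
        return self.rank_lo <= rank <= self.rank_hi


@dataclass
class ProtoChromosome:
    proto_id: str
    segments: list  # representative Segments, in proto order
    gene_count: int
    centromere_rank: int | None = None


@dataclass
class AncestralKaryotype:
    protos: list
    provenance: list = field(default_factory=list)

    def proto_ids(self) -> list[str]:
        return [p.proto_id for p in self.protos]


@dataclass(frozen=True)
class PaintingSegment:
    chromosome: str
    start_rank: int
    end_rank: int
    proto_id: str | None
    n_support: int


class Painting:
    """Per-gene assignment of a target genome's genes to proto-chromosomes."""

    def __init__(self, species_id: str, labels: dict, support: dict | None = None):
        self.species_id = species_id
        self.labels = labels  # chromosome -> list[proto_id or None], one per rank
        self.support = support or {c: [None] * len(v) for c, v in labels.items()}

    @classmethod
    def from_segments(cls, species_id: str, segments) -> "Painting":
        sizes = defaultdict(int)
        for s in segments:
            sizes[s.chromosome] = max(sizes[s.chromosome], s.end_rank + 1)
        labels = {c: [None] * n for c, n in sizes.items()}
        for s in segments:
            for r in range(s.start_rank, s.end_rank + 1):
                labels[s.chromosome][r] = s.proto_id
        return cls(species_id, labels)

    @property
    def segments(self) -> list[PaintingSegment]:
        out = []
        for chrom in sorted(self.labels):
            lab = self.labels[chrom]
            sup = self.support[chrom]
            i = 0
            while i < len(lab):
                j = i
                while j + 1 < len(lab) and lab[j + 1] == lab[i]:
                    j += 1
                n_support = sum(1 for k in range(i, j + 1) if sup[k] == lab[i] and lab[i] is not None)
                out.append(PaintingSegment(chrom, i, j, lab[i], n_support))
                i = j + 1
        return out

    def painted_fraction(self) -> float:
        total = sum(len(v) for v in self.labels.values())
        painted = sum(1 for v in self.labels.values() for x in v if x is not None)
        return painted / total if total else 0.0

    def __eq__(self, other):
        return (
            isinstance(other, Painting)
            and self.species_id == other.species_id
            and self.labels == other.labels
        )


@dataclass
class ArmTable:
    """Left/right arm split of each proto at its centromere rank.

    L holds ranks < centromere, R holds ranks >= centromere.
    """

    centromere_ranks: dict  # proto_id -> rank
    arm_lengths: dict       # proto_id -> (L genes, R genes)

    @classmethod
    def from_centromeres(cls, centromeres: dict, proto_sizes: dict) -> "ArmTable":
        lengths = {}
        for proto, n in proto_sizes.items():
            if proto not in centromeres:
                raise ValueError(f"no centromere rank for proto {proto}")
            cen = centromeres[proto]
            if not 0 < cen < n:
                raise ValueError(f"centromere rank {cen} outside proto {proto} (size {n})")
            lengths[proto] = (cen, n - cen)
        return cls(centromere_ranks=dict(centromeres), arm_lengths=lengths)

    def arms(self) -> list[str]:
        return [f"{p}{a}" for p in sorted(self.arm_lengths) for a in ("L", "R")]


# ---------------------------------------------------------------------------
# block index helpers
# ---------------------------------------------------------------------------


class BlockIndex:
    """Lookup of filtered blocks by (species, chromosome) on either side."""

    def __init__(self, blocks_by_pair: dict):
        self._by_chrom_pair = defaultdict(list)   # (s1,c1,s2,c2) -> [(block, side_of_s1)]
        self._partners = defaultdict(set)         # (s1,c1,s2) -> {c2}
        for (sa, sb), blocks in blocks_by_pair.items():
            for b in blocks:
                self._by_chrom_pair[(sa, b.chrom_a, sb, b.chrom_b)].append((b, "a"))
                self._by_chrom_pair[(sb, b.chrom_b, sa, b.chrom_a)].append((b, "b"))
                self._partners[(sa, b.chrom_a, sb)].add(b.chrom_b)
                self._partners[(sb, b.chrom_b, sa)].add(b.chrom_a)

    def between(self, s1: str, c1: str, s2: str, c2: str):
        return self._by_chrom_pair.get((s1, c1, s2, c2), [])

    def partners(self, s1: str, c1: str, s2: str):
        return sorted(self._partners.get((s1, c1, s2), ()))


def _anchor_ranks(block: SyntenyBlock, side: str):
    """(this-side ranks, other-side ranks) for a block viewed from ``side``."""
    ra = np.fromiter((a.rank_a for a in block.anchors), dtype=np.int64)
    rb = np.fromiter((a.rank_b for a in block.anchors), dtype=np.int64)
    return (ra, rb) if side == "a" else (rb, ra)


def _anchors_into_segment(index: BlockIndex, species: str, chrom: str, seg: Segment):
    """Ranks on (species, chrom) of anchors whose far end falls inside ``seg``."""
    hits = []
    for block, side in index.between(species, chrom, seg.species, seg.chromosome):
        near, far = _anchor_ranks(block, side)
        sel = (far >= seg.rank_lo) & (far <= seg.rank_hi)
        if sel.any():
            hits.append(near[sel])
    return np.concatenate(hits) if hits else np.array([], dtype=np.int64)


# ---------------------------------------------------------------------------
# round 1: whole-chromosome seeds
# ---------------------------------------------------------------------------


@dataclass
class ProtoBuild:
    """A proto-chromosome under construction: candidate segments + evidence."""

    candidates: list = field(default_factory=list)  # Segments
    members: set = field(default_factory=set)       # {(species, chromosome)}
    round1: bool = False
    evidence: list = field(default_factory=list)


def seed_round1(
    relations_by_pair: dict,
    species_order: list,
    tables: dict,
    max_copies_per_species: int = 2,
) -> list[ProtoBuild]:
    """Seed protos from whole-chromosome relations, unified transitively.

    ``relations_by_pair`` maps (species_a, species_b) -> {(chrom_a, chrom_b):
    relation}.  Each connected component of whole-relations becomes one seed; a
    component drawing more than ``max_copies_per_species`` chromosomes from one
    species signals a conflicting unification and is a hard error (two are
    allowed so that both homoeologous copies of a WGD lineage can join their
    proto).
    """
    g = nx.Graph()
    for (sa, sb), rels in relations_by_pair.items():
        for (ca, cb), rel in rels.items():
            if rel == "whole":
                g.add_edge((sa, ca), (sb, cb))
    seeds = []
    order_idx = {s: i for i, s in enumerate(species_order)}
    components = sorted(nx.connected_components(g), key=lambda comp: sorted(comp))
    for comp in components:
        per_species = defaultdict(list)
        for sp, chrom in comp:
            per_species[sp].append(chrom)
        for sp, chroms in per_species.items():
            if len(chroms) > max_copies_per_species:
                raise ValueError(
                    "conflicting seed unification: species "
                    f"{sp} contributes {sorted(chroms)} to one seed component "
                    f"{sorted(comp)}"
                )
        members = sorted(comp, key=lambda m: (order_idx.get(m[0], len(order_idx)), m[0], m[1]))
        build = ProtoBuild(round1=True)
        for sp, chrom in members:
            build.candidates.append(Segment(sp, chrom, 0, tables[sp].chrom_size(chrom) - 1))
            build.members.add((sp, chrom))
        rep = members[0]
        build.evidence.append({"round": 1, "members": members, "provisional_representative": rep})
        seeds.append(build)
    return seeds


# ---------------------------------------------------------------------------
# round 2: residual segments
# ---------------------------------------------------------------------------


def assign_round2(
    residuals: list,
    protos: list,
    index: BlockIndex,
    tables: dict,
    min_species: int = 3,
    max_overlap_frac: float = 0.2,
):
    """Assign residual chromosomes to protos supported by >= min_species species.

    A residual chromosome's evidence for a proto is the set of anchors linking
    it to the proto's round-1 member chromosomes; the supporting species count
    includes the residual's own species.  Non-overlapping evidence hulls let one
    chromosome split across protos (fusion/translocation products); heavily
    overlapping hulls pointing at different protos are a conflict and stay
    unassigned.  Returns (assigned records, unassigned records).
    """
    assigned, unassigned = [], []
    for sp, chrom in residuals:
        cands = []
        for pi, proto in enumerate(protos):
            supporters, rank_hits, n_anchors = set(), [], 0
            for seg in proto.candidates:
                if seg.species == sp:
                    continue
                near = _anchors_into_segment(index, sp, chrom, seg)
                if len(near):
                    supporters.add(seg.species)
                    rank_hits.append(near)
                    n_anchors += len(near)
            support = len(supporters) + 1  # the residual's own species counts
            if supporters and support >= min_species:
                ranks = np.concatenate(rank_hits)
                cands.append(
                    {"proto": pi, "support": support, "anchors": n_anchors,
                     "lo": int(ranks.min()), "hi": int(ranks.max())}
                )
        if not cands:
            unassigned.append({"species": sp, "chromosome": chrom, "reason": "insufficient support"})
            continue
        cands.sort(key=lambda c: (-c["support"], -c["anchors"], c["proto"]))
        size = tables[sp].chrom_size(chrom)
        covered = np.zeros(size, dtype=bool)
        any_ok = False
        for c in cands:
            lo, hi = c["lo"], c["hi"]
            span = np.arange(lo, hi + 1)
            free = span[~covered[lo: hi + 1]]
            if len(free) < (1 - max_overlap_frac) * len(span):
                unassigned.append(
                    {"species": sp, "chromosome": chrom, "proto": c["proto"],
                     "reason": "conflicting proto links"}
                )
                continue
            lo2, hi2 = int(free.min()), int(free.max())
            covered[lo2: hi2 + 1] = True
            seg = Segment(sp, chrom, lo2, hi2)
            protos[c["proto"]].candidates.append(seg)
            protos[c["proto"]].members.add((sp, chrom))
            rec = {"round": 2, "segment": seg, "proto": c["proto"],
                   "support": c["support"], "anchors": c["anchors"]}
            protos[c["proto"]].evidence.append(rec)
            assigned.append(rec)
            any_ok = True
        if not any_ok and not cands:
            unassigned.append({"species": sp, "chromosome": chrom, "reason": "no evidence"})
    return assigned, unassigned


def found_new_protos(
    leftovers: list,
    index: BlockIndex,
    tables: dict,
    species_order: list,
    min_species: int = 3,
):
    """Group still-unassigned residual chromosomes into new protos when a
    connected component of mutual collinearity spans >= min_species species."""
    g = nx.Graph()
    g.add_nodes_from(leftovers)
    for i, (s1, c1) in enumerate(leftovers):
        for s2, c2 in leftovers[i + 1:]:
            if s1 == s2:
                continue
            if index.between(s1, c1, s2, c2):
                g.add_edge((s1, c1), (s2, c2))
    order_idx = {s: i for i, s in enumerate(species_order)}
    new_protos, still_unassigned = [], []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)):
        species = {sp for sp, _ in comp}
        members = sorted(comp, key=lambda m: (order_idx.get(m[0], len(order_idx)), m[0], m[1]))
        if len(species) >= min_species:
            build = ProtoBuild()
            for sp, chrom in members:
                build.candidates.append(Segment(sp, chrom, 0, tables[sp].chrom_size(chrom) - 1))
                build.members.add((sp, chrom))
            build.evidence.append({"round": 2, "founded_from": members})
            new_protos.append(build)
        else:
            for sp, chrom in members:
                still_unassigned.append(
                    {"species": sp, "chromosome": chrom, "reason": "candidate, <min_species support"}
                )
    return new_protos, still_unassigned


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------


def _chroms_linked_to_proto(proto: ProtoBuild, species: str, index: BlockIndex, all_chroms: dict):
    """Chromosomes of ``species`` bearing blocks into any candidate segment of
    ``proto``, excluding the proto's own source chromosomes."""
    own = {(seg.species, seg.chromosome) for seg in proto.candidates}
    linked = set()
    for chrom in all_chroms[species]:
        if (species, chrom) in own:
            continue
        for seg in proto.candidates:
            if seg.species == species:
                continue
            if len(_anchors_into_segment(index, species, chrom, seg)):
                linked.add(chrom)
                break
    return linked


def consolidate(protos: list, index: BlockIndex, tables: dict) -> list[ProtoBuild]:
    """Merge two partial protos when >=2 species each carry one chromosome
    bearing blocks to both, and no species anchors them to chromosomes already
    assigned to different protos."""
    all_chroms = {sp: t.chromosomes for sp, t in tables.items()}
    protos = list(protos)
    merged = True
    while merged:
        merged = False
        owner = {}
        for pi, proto in enumerate(protos):
            for sp, chrom in proto.members:
                owner.setdefault((sp, chrom), pi)
        linked_cache = {}

        def linked(pi, sp):
            if (pi, sp) not in linked_cache:
                linked_cache[(pi, sp)] = _chroms_linked_to_proto(protos[pi], sp, index, all_chroms)
            return linked_cache[(pi, sp)]

        for i in range(len(protos)):
            for j in range(i + 1, len(protos)):
                if protos[i].round1 and protos[j].round1:
                    continue  # complete round-1 seeds are not merge candidates
                support, contradiction = 0, False
                for sp in sorted(all_chroms):
                    li, lj = linked(i, sp), linked(j, sp)
                    if li & lj:
                        support += 1
                    for ci in li:
                        pi_owner = owner.get((sp, ci))
                        if pi_owner is None or pi_owner in (i, j):
                            continue
                        for cj in lj:
                            pj_owner = owner.get((sp, cj))
                            if pj_owner is None or pj_owner in (i, j):
                                continue
                            if pi_owner != pj_owner:
                                contradiction = True
                if support >= 2 and not contradiction:
                    protos[i].candidates.extend(protos[j].candidates)
                    protos[i].members |= protos[j].members
                    protos[i].evidence.append(
                        {"merged": True, "support": support, "from": sorted(protos[j].members)}
                    )
                    del protos[j]
                    merged = True
                    break
            if merged:
                break
    return protos


# ---------------------------------------------------------------------------
# representative selection and final karyotype
# ---------------------------------------------------------------------------


def _segments_linked(index: BlockIndex, s1: Segment, s2: Segment) -> bool:
    for block, side in index.between(s1.species, s1.chromosome, s2.species, s2.chromosome):
        near, far = _anchor_ranks(block, side)
        if (((near >= s1.rank_lo) & (near <= s1.rank_hi)
             & (far >= s2.rank_lo) & (far <= s2.rank_hi)).any()):
            return True
    return False


def _region_anchor_ranks(index: BlockIndex, seg: Segment, others: list) -> np.ndarray:
    """Distinct ranks of ``seg`` genes that anchor into any other segment of its
    region (sorted, deduplicated)."""
    ranks = []
    for other in others:
        if other is seg or other.species == seg.species:
            continue
        for block, side in index.between(seg.species, seg.chromosome, other.species, other.chromosome):
            near, far = _anchor_ranks(block, side)
            sel = ((near >= seg.rank_lo) & (near <= seg.rank_hi)
                   & (far >= other.rank_lo) & (far <= other.rank_hi))
            if sel.any():
                ranks.append(near[sel])
    if not ranks:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(ranks))


def _segment_anchor_genes(index: BlockIndex, seg: Segment, others: list) -> int:
    """Distinct genes of ``seg`` that anchor into any other segment of its region."""
    return len(_region_anchor_ranks(index, seg, others))


def select_representatives(
    protos: list,
    index: BlockIndex,
    tables: dict,
    species_order: list,
) -> AncestralKaryotype:
    """Pick, per homologous region, the candidate that carries the region most
    completely and continuously; name protos by descending gene count.

    Primary criterion is region coverage (distinct anchor-bearing genes of the
    segment — a scale-free density ratio would let a short, fully-anchored
    translocation fragment outrank an intact chromosome); ties fall to
    continuity (coverage / rank span), then lexicographic (species, chromosome).
    The winner is trimmed to the hull of its anchors into the region, so a
    fusion chromosome contributes only its homologous part.
    """
    order_idx = {s: i for i, s in enumerate(species_order)}
    finished = []
    for proto in protos:
        if not proto.candidates:
            raise ValueError("proto with zero candidate segments (invariant breach upstream)")
        # homologous regions: connected components of block-linked segments
        g = nx.Graph()
        g.add_nodes_from(range(len(proto.candidates)))
        for i in range(len(proto.candidates)):
            for j in range(i + 1, len(proto.candidates)):
                si, sj = proto.candidates[i], proto.candidates[j]
                if si.species != sj.species and _segments_linked(index, si, sj):
                    g.add_edge(i, j)
        reps, region_records = [], []
        for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)):
            members = [proto.candidates[i] for i in sorted(comp)]
            scored = []
            for seg in members:
                anchor_ranks = _region_anchor_ranks(index, seg, members)
                continuity = len(anchor_ranks) / seg.size if seg.size else 0.0
                scored.append((seg, continuity, anchor_ranks))
            scored.sort(key=lambda t: (-len(t[2]), -t[1], t[0].species, t[0].chromosome, t[0].rank_lo))
            best, _, best_ranks = scored[0]
            if len(best_ranks):
                best = Segment(best.species, best.chromosome,
                               int(best_ranks.min()), int(best_ranks.max()))
            reps.append(best)
            region_records.append(
                {"representative": best, "continuity": scored[0][1],
                 "candidates": [(s.species, s.chromosome, s.rank_lo, s.rank_hi) for s in members]}
            )
        reps.sort(key=lambda s: (order_idx.get(s.species, len(order_idx)), s.species, s.chromosome, s.rank_lo))
        finished.append((reps, proto.evidence + [{"regions": region_records}]))
    # name by descending gene count
    finished.sort(key=lambda t: -sum(s.size for s in t[0]))
    protos_out, provenance = [], []
    for k, (reps, evidence) in enumerate(finished, start=1):
        pid = f"AGK{k}"
        protos_out.append(ProtoChromosome(proto_id=pid, segments=reps, gene_count=sum(s.size for s in reps)))
        provenance.append({"proto_id": pid, "evidence": evidence})
    return AncestralKaryotype(protos=protos_out, provenance=provenance)


def agk_gene_table(karyotype: AncestralKaryotype, tables: dict, species_id: str = "AGK", gap: int = 200):
    """Materialise the ancestral gene list as a GeneTable (one chromosome per
    proto), plus provenance mapping each ancestral gene to its source gene."""
    rows, provenance = [], {}
    for proto in karyotype.protos:
        pos = 0
        for seg in proto.segments:
            genes = tables[seg.species].genes_on(seg.chromosome).iloc[seg.rank_lo: seg.rank_hi + 1]
            for g in genes.itertuples():
                gid = f"{seg.species}|{g.gene_id}"
                length = int(g.end - g.start)
                rows.append((gid, proto.proto_id, pos, pos + length, g.strand))
                provenance[gid] = (seg.species, g.gene_id)
                pos += length + gap
    import pandas as pd

    frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GeneTable(species_id, frame), provenance


def build_ancestral_karyotype(
    tables: dict,
    blocks_by_pair: dict,
    species_order: list,
    relations_by_pair: dict,
    min_species: int = 3,
) -> AncestralKaryotype:
    """Run both reconstruction rounds, consolidation and representative selection."""
    index = BlockIndex(blocks_by_pair)
    seeds = seed_round1(relations_by_pair, species_order, tables)
    seeded = set().union(*(s.members for s in seeds)) if seeds else set()
    residuals = sorted(
        (sp, chrom)
        for sp in species_order
        for chrom in tables[sp].chromosomes
        if (sp, chrom) not in seeded
    )
    assigned, unassigned = assign_round2(residuals, seeds, index, tables, min_species=min_species)
    assigned_chroms = {(r["segment"].species, r["segment"].chromosome) for r in assigned}
    leftovers = [rc for rc in residuals if rc not in assigned_chroms]
    new_protos, still_un = found_new_protos(leftovers, index, tables, species_order, min_species=min_species)
    protos = consolidate(seeds + new_protos, index, tables)
    karyotype = select_representatives(protos, index, tables, species_order)
    karyotype.provenance.append({"unassigned": unassigned + still_un})
    if unassigned or still_un:
        logger.info("reconstruction left %d residual records unassigned", len(unassigned) + len(still_un))
    return karyotype


def karyotype_from_genome(table: GeneTable) -> AncestralKaryotype:
    """Trivial karyotype with one proto per chromosome of a single genome,
    named by descending gene count — the degenerate one-species ancestor."""
    chroms = sorted(table.chromosomes, key=lambda c: (-table.chrom_size(c), c))
    protos, provenance = [], []
    for k, chrom in enumerate(chroms, start=1):
        pid = f"AGK{k}"
        seg = Segment(table.species_id, chrom, 0, table.chrom_size(chrom) - 1)
        protos.append(ProtoChromosome(proto_id=pid, segments=[seg], gene_count=seg.size))
        provenance.append({"proto_id": pid, "evidence": [{"round": 0, "members": [(table.species_id, chrom)]}]})
    return AncestralKaryotype(protos=protos, provenance=provenance)


# ---------------------------------------------------------------------------
# painting
# ---------------------------------------------------------------------------


def project_karyotype(
    agk_table: GeneTable,
    target: GeneTable,
    blocks,
    smooth_window: int = 30,
) -> Painting:
    """Paint a target genome by proto-chromosome via AGK-vs-target blocks.

    Each target gene inside a block's span takes the block's proto (the AGK-side
    chromosome); where blocks overlap the larger block wins.  Short discordant
    runs (< 3 genes) are then absorbed by majority vote within a centered
    ``smooth_window``-gene window.  Genes in no block stay NA.
    """
    labels = {c: [None] * target.chrom_size(c) for c in target.chromosomes}
    ordered = sorted(blocks, key=lambda b: (-b.n_pairs, b.block_id))
    for b in ordered:
        lab = labels.get(b.chrom_b)
        if lab is None:
            continue
        lo, hi = b.span_b
        for r in range(max(lo, 0), min(hi, len(lab) - 1) + 1):
            if lab[r] is None:
                lab[r] = b.chrom_a
    support = {c: list(v) for c, v in labels.items()}  # pre-smoothing assignment

    for chrom, lab in labels.items():
        n = len(lab)
        for _ in range(5):
            changed = False
            runs = []
            i = 0
            while i < n:
                j = i
                while j + 1 < n and lab[j + 1] == lab[i]:
                    j += 1
                runs.append((i, j, lab[i]))
                i = j + 1
            for k, (i, j, val) in enumerate(runs):
                if j - i + 1 >= 3 or k == 0 or k == len(runs) - 1:
                    continue
                left, right = runs[k - 1][2], runs[k + 1][2]
                if left != right or left is None:
                    continue
                mid = (i + j) // 2
                w0, w1 = max(0, mid - smooth_window // 2), min(n, mid + smooth_window // 2 + 1)
                counts = defaultdict(int)
                for r in range(w0, w1):
                    if lab[r] is not None:
                        counts[lab[r]] += 1
                if counts:
                    major = max(sorted(counts), key=lambda x: counts[x])
                    if major != val:
                        for r in range(i, j + 1):
                            lab[r] = major
                        changed = True
            if not changed:
                break
    return Painting(target.species_id, labels, support)


# ---------------------------------------------------------------------------
# arm mapping
# ---------------------------------------------------------------------------


def map_blocks_to_arms(blocks, arms: ArmTable):
    """Assign each AGK-vs-target block to the proto arm holding the larger share
    of its AGK-side rank span (exact ties go left).  Returns (counts, labels)."""
    counts = {f"{p}{a}": 0 for p in sorted(arms.arm_lengths) for a in ("L", "R")}
    labels = []
    for b in blocks:
        proto = b.chrom_a
        if proto not in arms.centromere_ranks:
            raise ValueError(f"no centromere rank for proto {proto}")
        cen = arms.centromere_ranks[proto]
        lo, hi = b.span_a
        left = max(0, min(hi, cen - 1) - lo + 1)
        right = (hi - lo + 1) - left
        arm = "L" if left >= right else "R"
        counts[f"{proto}{arm}"] += 1
        labels.append((b.block_id, f"{proto}{arm}"))
    return counts, labels
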