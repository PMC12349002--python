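"""Forward simulation of karyotype evolution with known ground truth.

An ancestor of ``n_protos`` chromosomes evolves along a star tree into
descendant genomes via whole-genome duplication, reciprocal translocations,
fissions, fusions, inversions, gene loss (fractionation) and gene gain.
Evolution happens in gene-rank space; bp coordinates are synthesised afterwards
from per-gene lengths and intergenic gaps so interval statistics have real
spans to work on.  The simulator also emits noisy homology tables, class-
labelled TE intervals (optionally LINE1-enriched inside designated blocks) and
the truth painting used to score reconstruction recovery.

Gene identifiers encode nothing about ancestry; truth lives only in the
returned :class:`SimDataset`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .io import GeneTable, TEInterval

# gene record inside a genome state: [uid, origin_uid, strand(+1/-1), length_bp, subgenome]
_UID, _ORIGIN, _STRAND, _LEN, _SUB = range(5)

EVENT_ORDER = ("wgd", "translocation", "fission", "fusion", "inversion", "loss", "gain")


@dataclass
class BranchRates:
    """Per-branch event counts and probabilities."""

    n_inversions: int = 5
    n_translocations: int = 1
    n_fissions: int = 0
    n_fusions: int = 0
    wgd: bool = False
    loss_fraction: float = 0.05
    gain_fraction: float = 0.02
    loss_bias: float = 1.0  # multiplier on loss probability for WGD subgenome 2


@dataclass
class SimulationConfig:
    species: list
    seed: int
    n_protos: int = 12
    genes_per_chromosome: tuple = (200, 500)
    rates: dict = field(default_factory=dict)  # species -> BranchRates (default otherwise)
    default_rates: BranchRates = field(default_factory=BranchRates)
    p_missing: float = 0.05
    p_spurious: float = 0.05
    gene_len_range: tuple = (1000, 5000)
    intergap_range: tuple = (2000, 10000)
    te_intensity: dict = field(default_factory=lambda: {"Copia": 25, "Gypsy": 40, "LINE1": 25, "Other": 20})
    te_mean_len: dict = field(default_factory=lambda: {"Copia": 1500, "Gypsy": 2000, "LINE1": 500, "Other": 400})
    line1_block_multiplier: float = 1.0
    designated_blocks_per_chromosome: int = 0
    designated_block_genes: int = 60

    def __post_init__(self):
        for p in (self.p_missing, self.p_spurious):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rates_for(self, species: str) -> BranchRates:
        return self.rates.get(species, self.default_rates)

    @classmethod
    def moderate(cls, seed: int, n_species: int = 5, wgd_species: str | None = "auto", **kw) -> "SimulationConfig":
        """The default recovery scenario: a 5-species star tree with per-branch
        5 inversions, 1 reciprocal translocation, 5% loss and 2% gain, plus one
        whole-genome-duplicated lineage — a stable-karyotype clade with one
        multiplied lineage."""
        species = [f"sp{i + 1}" for i in range(n_species)]
        rates = {}
        if wgd_species == "auto":
            wgd_species = species[-1]
        if wgd_species:
            rates[wgd_species] = BranchRates(wgd=True)
        return cls(species=species, seed=seed, rates=rates, **kw)


@dataclass
class EventRecord:
    species: str
    type: str
    params: dict


@dataclass
class EventLog:
    records: list = field(default_factory=list)

    def for_species(self, species: str) -> list:
        return [r for r in self.records if r.species == species]


@dataclass
class RecoveryReport:
    inferred_proto_count: int
    true_proto_count: int
    painting_accuracy: float   # among painted, truth-known genes
    overall_accuracy: float    # among all truth-known genes (NA counts as wrong)
    partition_agreement: float  # adjusted Rand index
    unpainted_fraction: float


class _GenomeState:
    def __init__(self, chroms: dict, uid_counter: int):
        self.chroms = chroms  # name -> list of gene records
        self.uid_counter = uid_counter

    def copy(self) -> "_GenomeState":
        return _GenomeState({k: [list(g) for g in v] for k, v in self.chroms.items()}, self.uid_counter)

    def new_uid(self) -> int:
        self.uid_counter += 1
        return self.uid_counter

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chroms.values())

    def sorted_names(self) -> list:
        return sorted(self.chroms)


# ---------------------------------------------------------------------------
# event application (replayable: the record fully determines the outcome)
# ---------------------------------------------------------------------------


def apply_event(state: _GenomeState, record: EventRecord) -> _GenomeState:
    p = record.params
    if record.type == "wgd":
        new = {}
        for name in state.sorted_names():
            genes = state.chroms[name]
            new[f"{name}#1"] = [list(g) for g in genes]
            copy2 = []
            for g in genes:
                g2 = list(g)
                g2[_UID] = state.new_uid()
                g2[_SUB] = 2
                copy2.append(g2)
            new[f"{name}#2"] = copy2
        state.chroms = new
    elif record.type == "inversion":
        genes = state.chroms[p["chrom"]]
        i, j = p["i"], p["j"]
        if not (0 <= i < j < len(genes)):
            raise ValueError(f"illegal inversion {p}")
        seg = genes[i: j + 1][::-1]
        for g in seg:
            g[_STRAND] = -g[_STRAND]
        state.chroms[p["chrom"]] = genes[:i] + seg + genes[j + 1:]
    elif record.type == "translocation":
        c1, c2, k1, k2 = p["chrom1"], p["chrom2"], p["k1"], p["k2"]
        g1, g2 = state.chroms[c1], state.chroms[c2]
        if not (0 < k1 < len(g1) and 0 < k2 < len(g2)):
            raise ValueError(f"illegal translocation {p}")
        state.chroms[c1], state.chroms[c2] = g1[:k1] + g2[k2:], g2[:k2] + g1[k1:]
    elif record.type == "fission":
        c, at = p["chrom"], p["at"]
        genes = state.chroms.pop(c)
        if not 0 < at < len(genes):
            raise ValueError(f"illegal fission {p}")
        state.chroms[f"{c}/1"] = genes[:at]
        state.chroms[f"{c}/2"] = genes[at:]
    elif record.type == "fusion":
        c1, c2 = p["chrom1"], p["chrom2"]
        g1 = state.chroms.pop(c1)
        g2 = state.chroms.pop(c2)
        state.chroms[f"{c1}+{c2}"] = g1 + g2
    elif record.type == "loss":
        lost = set(p["genes"])
        for name in state.sorted_names():
            state.chroms[name] = [g for g in state.chroms[name] if g[_UID] not in lost]
    elif record.type == "gain":
        for chrom, pos, uid, length, strand in p["insertions"]:
            state.chroms[chrom].insert(pos, [uid, -1, strand, length, 0])
            state.uid_counter = max(state.uid_counter, uid)
    else:
        raise ValueError(f"unknown event type {record.type!r}")
    return state


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------


def _sample_events(state: _GenomeState, species: str, rates: BranchRates, rng) -> list:
    records = []

    def attempt(sampler, n, kind):
        failures = 0
        made = 0
        while made < n:
            params = sampler()
            if params is None:
                failures += 1
                if failures > 100:
                    raise RuntimeError(f"{species}: could not sample a feasible {kind} event")
                continue
            rec = EventRecord(species, kind, params)
            apply_event(state, rec)
            records.append(rec)
            made += 1

    if rates.wgd:
        rec = EventRecord(species, "wgd", {})
        apply_event(state, rec)
        records.append(rec)

    def sample_translocation():
        names = [n for n in state.sorted_names() if len(state.chroms[n]) >= 2]
        if len(names) < 2:
            return None
        c1, c2 = rng.choice(len(names), size=2, replace=False)
        c1, c2 = names[c1], names[c2]
        return {
            "chrom1": c1, "k1": int(rng.integers(1, len(state.chroms[c1]))),
            "chrom2": c2, "k2": int(rng.integers(1, len(state.chroms[c2]))),
        }

    attempt(sample_translocation, rates.n_translocations, "translocation")

    def sample_fission():
        names = [n for n in state.sorted_names() if len(state.chroms[n]) >= 2]
        if not names:
            return None
        c = names[int(rng.integers(len(names)))]
        return {"chrom": c, "at": int(rng.integers(1, len(state.chroms[c])))}

    attempt(sample_fission, rates.n_fissions, "fission")

    def sample_fusion():
        names = state.sorted_names()
        if len(names) < 2:
            return None
        i, j = rng.choice(len(names), size=2, replace=False)
        return {"chrom1": names[i], "chrom2": names[j]}

    attempt(sample_fusion, rates.n_fusions, "fusion")

    def sample_inversion():
        names = [n for n in state.sorted_names() if len(state.chroms[n]) >= 2]
        if not names:
            return None
        c = names[int(rng.integers(len(names)))]
        n = len(state.chroms[c])
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))
        return {"chrom": c, "i": i, "j": j}

    attempt(sample_inversion, rates.n_inversions, "inversion")

    if rates.loss_fraction > 0:
        lost = []
        for name in state.sorted_names():
            for g in state.chroms[name]:
                p = rates.loss_fraction * (rates.loss_bias if g[_SUB] == 2 else 1.0)
                if rng.random() < min(p, 1.0):
                    lost.append(g[_UID])
        if lost:
            rec = EventRecord(species, "loss", {"genes": lost})
            apply_event(state, rec)
            records.append(rec)

    if rates.gain_fraction > 0:
        n_gain = int(round(rates.gain_fraction * state.n_genes))
        insertions = []
        lo, hi = 1000, 5000
        for _ in range(n_gain):
            names = state.sorted_names()
            c = names[int(rng.integers(len(names)))]
            pos = int(rng.integers(0, len(state.chroms[c]) + 1))
            uid = state.new_uid()
            ins = (c, pos, uid, int(rng.integers(lo, hi)), int(rng.choice([-1, 1])))
            insertions.append(ins)
            state.chroms[c].insert(pos, [uid, -1, ins[4], ins[3], 0])
        if insertions:
            # already applied in-place while sampling; log for replay
            records.append(EventRecord(species, "gain", {"insertions": insertions}))
    return records


# ---------------------------------------------------------------------------
# finalisation: rank space -> GeneTable with bp coordinates
# ---------------------------------------------------------------------------


def _finalize(state: _GenomeState, species: str, intergap_range, seed: int):
    """Name chromosomes/genes and lay out bp coordinates.  Chromosomes are
    numbered by descending gene count (mirrors assembly convention)."""
    rng = np.random.default_rng(seed)
    names = sorted(state.sorted_names(), key=lambda n: (-len(state.chroms[n]), n))
    rows, origin_map, counter = [], {}, 0
    for ci, name in enumerate(names, start=1):
        chrom = f"{species}_chr{ci:02d}"
        pos = 0
        for g in state.chroms[name]:
            counter += 1
            gid = f"{species}g{counter:06d}"
            start = pos + int(rng.integers(*intergap_range))
            end = start + g[_LEN]
            rows.append((gid, chrom, start, end, "+" if g[_STRAND] > 0 else "-"))
            origin_map[gid] = g[_ORIGIN]
            pos = end
    frame = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GeneTable(species, frame), origin_map


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    config: SimulationConfig
    ancestor: GeneTable
    tables: dict                  # species -> GeneTable (excludes ancestor)
    origin_maps: dict             # species (incl. "ancestor") -> {gene_id: origin uid, -1 for gained}
    truth: dict                   # species -> {chromosome: [proto or None per rank]}
    origin_to_proto: dict         # ancestor gene uid -> proto id ("P1"..)
    event_log: EventLog
    te: dict                      # species -> [TEInterval]
    designated_blocks: dict       # species -> [(chromosome, rank_lo, rank_hi)]
    _ancestor_state: _GenomeState
    _finalize_seeds: dict
    _homology_seeds: dict
    _homology_cache: dict = field(default_factory=dict)

    def all_tables(self) -> dict:
        return {"ancestor": self.ancestor, **self.tables}

    def truth_label(self, species: str, chromosome: str, rank: int):
        return self.truth[species][chromosome][rank]

    def homology_frame(self, s1: str, s2: str) -> pd.DataFrame:
        """Noisy outfmt-6-style homology table with query genes from ``s1``."""
        key = (s1, s2)
        if key not in self._homology_cache:
            self._homology_cache[key] = _make_homology(self, s1, s2)
        return self._homology_cache[key]

    def replay(self, species: str) -> GeneTable:
        """Reapply the logged events from the stored ancestor; must reproduce
        the emitted GeneTable exactly."""
        state = self._ancestor_state.copy()
        for rec in self.event_log.for_species(species):
            apply_event(state, rec)
        table, _ = _finalize(state, species, self.config.intergap_range, self._finalize_seeds[species])
        return table


def _make_homology(ds: SimDataset, s1: str, s2: str) -> pd.DataFrame:
    cfg = ds.config
    seed = ds._homology_seeds.get((s1, s2)) or ds._homology_seeds.get((s2, s1))
    if seed is None:
        raise KeyError(f"no homology seed for pair ({s1}, {s2})")
    rng = np.random.default_rng(seed)
    by_origin_1, by_origin_2 = {}, {}
    for gid, origin in ds.origin_maps[s1].items():
        if origin >= 0:
            by_origin_1.setdefault(origin, []).append(gid)
    for gid, origin in ds.origin_maps[s2].items():
        if origin >= 0:
            by_origin_2.setdefault(origin, []).append(gid)
    pairs = []
    if s1 == s2:
        for gid in sorted(ds.origin_maps[s1]):
            pairs.append((gid, gid, 0.0, 5000.0, True))  # self-hit, never dropped
        for origin in sorted(by_origin_1):
            group = sorted(by_origin_1[origin])
            for g1 in group:
                for g2 in group:
                    if g1 != g2:
                        pairs.append((g1, g2, None, None, False))
    else:
        for origin in sorted(set(by_origin_1) & set(by_origin_2)):
            for g1 in sorted(by_origin_1[origin]):
                for g2 in sorted(by_origin_2[origin]):
                    pairs.append((g1, g2, None, None, False))
    rows = []
    n_true = 0
    for g1, g2, ev, bs, keep in pairs:
        if not keep and rng.random() < cfg.p_missing:
            continue
        n_true += 1
        if ev is None:
            ev = 10.0 ** (-rng.uniform(20, 180))
            bs = float(np.round(rng.uniform(300, 3000), 1))
        rows.append((g1, g2, ev, bs))
    genes1 = sorted(ds.origin_maps[s1])
    genes2 = sorted(ds.origin_maps[s2])
    n_spurious = int(round(cfg.p_spurious * n_true))
    for _ in range(n_spurious):
        g1 = genes1[int(rng.integers(len(genes1)))]
        g2 = genes2[int(rng.integers(len(genes2)))]
        ev = 10.0 ** (-rng.uniform(5.1, 30))
        rows.append((g1, g2, ev, float(np.round(rng.uniform(60, 250), 1))))
    df = pd.DataFrame(rows, columns=["query_id", "subject_id", "evalue", "bitscore"])
    # fill the standard aligner tabular columns around the essentials
    out = pd.DataFrame(
        {
            0: df["query_id"], 1: df["subject_id"],
            2: 80.0, 3: 300, 4: 50, 5: 2, 6: 1, 7: 300, 8: 1, 9: 300,
            10: df["evalue"], 11: df["bitscore"],
        }
    )
    return out


def homology_for_filter(frame: pd.DataFrame) -> pd.DataFrame:
    """Adapt a 12-column simulated table to filter_homology's expected columns."""
    sub = frame.iloc[:, [0, 1, 10, 11]].copy()
    sub.columns = ["query_id", "subject_id", "evalue", "bitscore"]
    return sub


# ---------------------------------------------------------------------------
# TE landscapes
# ---------------------------------------------------------------------------


def _make_te(table: GeneTable, cfg: SimulationConfig, rng, designated: list) -> list:
    intervals = []
    desig_by_chrom = {}
    for chrom, lo, hi in designated:
        desig_by_chrom.setdefault(chrom, []).append(table.bp_span(chrom, lo, hi))

    def scatter(chrom, lo_bp, hi_bp, cls, intensity):
        span = hi_bp - lo_bp
        n = rng.poisson(intensity * span / 1e6)
        mean = cfg.te_mean_len[cls]
        for _ in range(n):
            length = int(rng.integers(max(50, mean // 2), mean + mean // 2))
            start = int(rng.integers(lo_bp, max(lo_bp + 1, hi_bp - length)))
            intervals.append(TEInterval(chrom, start, start + length, cls))

    for chrom in table.chromosomes:
        chrom_len = table.chrom_lengths[chrom]
        for cls, intensity in sorted(cfg.te_intensity.items()):
            scatter(chrom, 0, chrom_len, cls, intensity)
        if cfg.line1_block_multiplier > 1.0:
            for lo_bp, hi_bp in desig_by_chrom.get(chrom, []):
                extra = cfg.te_intensity["LINE1"] * (cfg.line1_block_multiplier - 1.0)
                scatter(chrom, lo_bp, hi_bp, "LINE1", extra)
    intervals.sort(key=lambda t: (t.chromosome, t.start, t.end, t.te_class))
    return intervals


def _pick_designated(table: GeneTable, cfg: SimulationConfig, rng, margin: int = 40) -> list:
    """Rank intervals for LINE1-enriched blocks, kept clear of chromosome ends
    and of each other so 30-gene flanks stay at background density."""
    out = []
    want = cfg.designated_blocks_per_chromosome
    glen = cfg.designated_block_genes
    for chrom in table.chromosomes:
        size = table.chrom_size(chrom)
        if size < glen + 2 * margin:
            continue
        placed = []
        for _ in range(want):
            for _try in range(50):
                lo = int(rng.integers(margin, size - glen - margin + 1))
                hi = lo + glen - 1
                if all(hi + margin < plo or lo - margin > phi for plo, phi in placed):
                    placed.append((lo, hi))
                    out.append((chrom, lo, hi))
                    break
    return out


# ---------------------------------------------------------------------------
# top-level simulation
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimDataset:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4 + len(config.species))
    anc_rng = np.random.default_rng(children[0])

    # ancestor genome
    chroms = {}
    uid = 0
    origin_to_proto = {}
    for p in range(config.n_protos):
        n_genes = int(anc_rng.integers(config.genes_per_chromosome[0], config.genes_per_chromosome[1] + 1))
        genes = []
        for _ in range(n_genes):
            uid += 1
            genes.append([uid, uid, int(anc_rng.choice([-1, 1])),
                          int(anc_rng.integers(*config.gene_len_range)), 0])
            origin_to_proto[uid] = f"P{p + 1}"
        chroms[f"c{p:02d}"] = genes
    ancestor_state = _GenomeState(chroms, uid)

    finalize_seeds = {"ancestor": int(np.random.default_rng(children[1]).integers(2**31 - 1))}
    ancestor_table, anc_origin = _finalize(
        ancestor_state, "ancestor", config.intergap_range, finalize_seeds["ancestor"]
    )

    log = EventLog()
    tables, origin_maps, truth = {}, {"ancestor": anc_origin}, {}
    te, designated = {}, {}
    for i, sp in enumerate(config.species):
        sp_ss = children[4 + i]
        sub = sp_ss.spawn(4)
        ev_rng = np.random.default_rng(sub[0])
        state = ancestor_state.copy()
        log.records.extend(_sample_events(state, sp, config.rates_for(sp), ev_rng))
        finalize_seeds[sp] = int(np.random.default_rng(sub[1]).integers(2**31 - 1))
        table, origin_map = _finalize(state, sp, config.intergap_range, finalize_seeds[sp])
        tables[sp] = table
        origin_maps[sp] = origin_map
        truth[sp] = {
            c: [origin_to_proto.get(origin_map[g.gene_id]) for g in table.genes_on(c).itertuples()]
            for c in table.chromosomes
        }
        desig_rng = np.random.default_rng(sub[2])
        designated[sp] = (
            _pick_designated(table, config, desig_rng)
            if config.designated_blocks_per_chromosome else []
        )
        te_rng = np.random.default_rng(sub[3])
        te[sp] = _make_te(table, config, te_rng, designated[sp])

    # independent homology noise per pair (incl. self and ancestor pairs)
    hom_rng = np.random.default_rng(children[2])
    homology_seeds = {}
    all_species = ["ancestor"] + list(config.species)
    for a in range(len(all_species)):
        for b in range(a, len(all_species)):
            homology_seeds[(all_species[a], all_species[b])] = int(hom_rng.integers(2**31 - 1))

    return SimDataset(
        config=config, ancestor=ancestor_table, tables=tables, origin_maps=origin_maps,
        truth=truth, origin_to_proto=origin_to_proto, event_log=log, te=te,
        designated_blocks=designated, _ancestor_state=ancestor_state,
        _finalize_seeds=finalize_seeds, _homology_seeds=homology_seeds,
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def evaluate_recovery(karyotype, paintings: dict, dataset: SimDataset) -> RecoveryReport:
    """Score an inferred karyotype + paintings against the simulation truth.

    Inferred proto labels are matched to true protos by maximum-agreement
    assignment on the contingency table; gained genes (no ancestral origin) are
    excluded from every denominator.
    """
    inferred, true = [], []
    for sp, painting in paintings.items():
        if sp not in dataset.truth:
            raise ValueError(f"painting species {sp!r} absent from the simulation truth")
        for chrom, labels in painting.labels.items():
            t = dataset.truth[sp][chrom]
            if len(t) != len(labels):
                raise ValueError(f"painting/truth size mismatch on {sp}:{chrom}")
            for lab, tl in zip(labels, t):
                if tl is None:
                    continue
                inferred.append(lab)
                true.append(tl)
    inferred = np.array(inferred, dtype=object)
    true = np.array(true, dtype=object)
    total = len(true)
    painted = inferred != None  # noqa: E711  (element-wise)
    unpainted_fraction = 1.0 - painted.sum() / total if total else 0.0

    inf_p, true_p = inferred[painted], true[painted]
    if len(inf_p):
        inf_ids = sorted(set(inf_p))
        true_ids = sorted(set(true_p))
        cont = np.zeros((len(inf_ids), len(true_ids)), dtype=np.int64)
        inf_idx = {k: i for i, k in enumerate(inf_ids)}
        true_idx = {k: i for i, k in enumerate(true_ids)}
        for a, b in zip(inf_p, true_p):
            cont[inf_idx[a], true_idx[b]] += 1
        ri, ci = linear_sum_assignment(cont, maximize=True)
        matched = int(cont[ri, ci].sum())
        ari = float(adjusted_rand_score([str(x) for x in true_p], [str(x) for x in inf_p]))
    else:
        matched, ari = 0, 0.0
    return RecoveryReport(
        inferred_proto_count=len(karyotype.protos),
        true_proto_count=dataset.config.n_protos,
        painting_accuracy=matched / painted.sum() if painted.sum() else 0.0,
        overall_accuracy=matched / total if total else 0.0,
        partition_agreement=ari,
        unpainted_fraction=unpainted_fraction,
    )
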