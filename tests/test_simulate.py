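"""Forward simulator: replayability, bookkeeping, noise model, scoring."""

import numpy as np
import pytest

from karyoforge.ancestor import Painting
from karyoforge.simulate import (
    BranchRates,
    EventRecord,
    SimulationConfig,
    _GenomeState,
    apply_event,
    evaluate_recovery,
    simulate,
)


def _quiet_rates(**kw):
    base = dict(n_inversions=0, n_translocations=0, n_fissions=0, n_fusions=0,
                loss_fraction=0.0, gain_fraction=0.0)
    base.update(kw)
    return BranchRates(**base)


def _config(seed=0, species=("s1",), **rates_kw):
    return SimulationConfig(
        species=list(species), seed=seed,
        rates={sp: _quiet_rates(**rates_kw) for sp in species},
    )


# -- determinism / replay ---------------------------------------------------


def test_simulation_deterministic():
    cfg = SimulationConfig.moderate(seed=9, n_species=3)
    ds1, ds2 = simulate(cfg), simulate(SimulationConfig.moderate(seed=9, n_species=3))
    for sp in cfg.species:
        assert ds1.tables[sp] == ds2.tables[sp]
        assert ds1.homology_frame(sp, sp).equals(ds2.homology_frame(sp, sp))
    assert ds1.ancestor == ds2.ancestor


def test_event_log_replay_reproduces_tables():
    cfg = SimulationConfig.moderate(seed=4, n_species=3)
    ds = simulate(cfg)
    for sp in cfg.species:
        assert ds.replay(sp) == ds.tables[sp]


# -- event semantics --------------------------------------------------------


def _toy_state(n=6):
    genes = [[i + 1, i + 1, 1, 100, 0] for i in range(n)]
    return _GenomeState({"c0": genes}, n)


def test_inversion_reverses_order_and_strand():
    st = _toy_state()
    apply_event(st, EventRecord("x", "inversion", {"chrom": "c0", "i": 1, "j": 3}))
    uids = [g[0] for g in st.chroms["c0"]]
    strands = [g[2] for g in st.chroms["c0"]]
    assert uids == [1, 4, 3, 2, 5, 6]
    assert strands == [1, -1, -1, -1, 1, 1]


def test_illegal_inversion_raises():
    with pytest.raises(ValueError, match="illegal inversion"):
        apply_event(_toy_state(), EventRecord("x", "inversion", {"chrom": "c0", "i": 3, "j": 3}))


def test_wgd_duplicates_every_gene_with_fresh_uids():
    st = _toy_state()
    apply_event(st, EventRecord("x", "wgd", {}))
    assert set(st.chroms) == {"c0#1", "c0#2"}
    copy1 = st.chroms["c0#1"]
    copy2 = st.chroms["c0#2"]
    assert [g[1] for g in copy1] == [g[1] for g in copy2]     # same origins
    assert {g[0] for g in copy1}.isdisjoint({g[0] for g in copy2})  # fresh uids
    assert all(g[4] == 2 for g in copy2)


def test_translocation_is_reciprocal_and_conservative():
    st = _GenomeState({"a": [[1, 1, 1, 100, 0], [2, 2, 1, 100, 0]],
                       "b": [[3, 3, 1, 100, 0], [4, 4, 1, 100, 0]]}, 4)
    apply_event(st, EventRecord("x", "translocation", {"chrom1": "a", "k1": 1, "chrom2": "b", "k2": 1}))
    assert [g[0] for g in st.chroms["a"]] == [1, 4]
    assert [g[0] for g in st.chroms["b"]] == [3, 2]


def test_fission_fusion_conserve_genes():
    st = _toy_state()
    apply_event(st, EventRecord("x", "fission", {"chrom": "c0", "at": 2}))
    assert sorted(st.chroms) == ["c0/1", "c0/2"]
    assert st.n_genes == 6
    apply_event(st, EventRecord("x", "fusion", {"chrom1": "c0/1", "chrom2": "c0/2"}))
    assert list(st.chroms) == ["c0/1+c0/2"]
    assert [g[0] for g in st.chroms["c0/1+c0/2"]] == [1, 2, 3, 4, 5, 6]


# -- bookkeeping ------------------------------------------------------------


def test_quiet_branch_preserves_gene_count_and_truth():
    ds = simulate(_config(seed=2))
    sp = "s1"
    assert ds.tables[sp].n_genes == ds.ancestor.n_genes
    labels = [l for c in ds.truth[sp] for l in ds.truth[sp][c]]
    assert None not in labels
    assert len(set(labels)) == ds.config.n_protos


def test_loss_and_gain_bookkeeping():
    ds = simulate(_config(seed=3, loss_fraction=0.1, gain_fraction=0.05))
    sp = "s1"
    lost = sum(len(r.params["genes"]) for r in ds.event_log.for_species(sp) if r.type == "loss")
    gained = sum(len(r.params["insertions"]) for r in ds.event_log.for_species(sp) if r.type == "gain")
    assert ds.tables[sp].n_genes == ds.ancestor.n_genes - lost + gained
    # gained genes carry no ancestral origin and no truth label
    n_unlabeled = sum(l is None for c in ds.truth[sp] for l in ds.truth[sp][c])
    assert n_unlabeled == gained


def test_wgd_doubles_gene_count():
    ds = simulate(_config(seed=4, wgd=True))
    assert ds.tables["s1"].n_genes == 2 * ds.ancestor.n_genes
    assert len(ds.tables["s1"].chromosomes) == 2 * len(ds.ancestor.chromosomes)


# -- homology noise ---------------------------------------------------------


def test_homology_noise_bounds():
    cfg = SimulationConfig(species=["s1", "s2"], seed=6,
                           rates={sp: _quiet_rates() for sp in ("s1", "s2")},
                           p_missing=0.2, p_spurious=0.1)
    ds = simulate(cfg)
    frame = ds.homology_frame("s1", "s2")
    n_genes = ds.ancestor.n_genes
    n_true = n_genes  # quiet branches: one orthologous pair per ancestral gene
    kept = len(frame)
    # kept = Binomial(n_true, 0.8) + round(0.1 * that); bound within 5 sigma
    sigma = (n_true * 0.2 * 0.8) ** 0.5
    n_kept_true = kept / 1.1
    assert abs(n_kept_true - 0.8 * n_true) < 5 * sigma


def test_self_homology_always_contains_identity():
    ds = simulate(_config(seed=7, wgd=True))
    frame = ds.homology_frame("s1", "s1")
    self_hits = frame[frame[0] == frame[1]]
    assert len(self_hits) == ds.tables["s1"].n_genes
    assert (self_hits[10] == 0.0).all()


def test_spurious_hit_count_is_exact():
    cfg = SimulationConfig(species=["s1"], seed=8, rates={"s1": _quiet_rates()},
                           p_missing=0.0, p_spurious=0.5)
    ds = simulate(cfg)
    frame = ds.homology_frame("s1", "ancestor") if False else ds.homology_frame("ancestor", "s1")
    n_true = ds.ancestor.n_genes
    assert len(frame) == n_true + round(0.5 * n_true)


# -- TE landscape -----------------------------------------------------------


def test_te_intensity_matches_poisson_expectation():
    ds = simulate(_config(seed=10))
    table = ds.tables["s1"]
    genome_bp = sum(table.chrom_lengths.values())
    n_gypsy = sum(1 for t in ds.te["s1"] if t.te_class == "Gypsy")
    lam = 40 * genome_bp / 1e6
    assert abs(n_gypsy - lam) < 5 * lam ** 0.5


def test_designated_blocks_respect_margins():
    cfg = SimulationConfig(species=["s1"], seed=11, rates={"s1": _quiet_rates()},
                           designated_blocks_per_chromosome=2, designated_block_genes=60,
                           line1_block_multiplier=4.0)
    ds = simulate(cfg)
    for chrom, lo, hi in ds.designated_blocks["s1"]:
        size = ds.tables["s1"].chrom_size(chrom)
        assert lo >= 40 and hi <= size - 41
        assert hi - lo + 1 == 60


# -- recovery scoring -------------------------------------------------------


def _perfect_paintings(ds, rename=None):
    out = {}
    for sp, per_chrom in ds.truth.items():
        labels = {c: [(rename or {}).get(l, l) for l in v] for c, v in per_chrom.items()}
        out[sp] = Painting(sp, labels)
    return out


def test_evaluate_recovery_perfect():
    ds = simulate(_config(seed=12, species=("s1", "s2")))
    from karyoforge.ancestor import AncestralKaryotype, ProtoChromosome

    k = AncestralKaryotype([ProtoChromosome(f"P{i+1}", [], 0) for i in range(12)])
    rep = evaluate_recovery(k, _perfect_paintings(ds), ds)
    assert rep.painting_accuracy == 1.0 and rep.overall_accuracy == 1.0
    assert rep.partition_agreement == pytest.approx(1.0)
    assert rep.unpainted_fraction == 0.0


def test_evaluate_recovery_label_permutation_invariant():
    """Scoring matches labels by assignment, so renaming protos changes nothing."""
    ds = simulate(_config(seed=13, species=("s1", "s2")))
    rename = {f"P{i+1}": f"X{i+1}" for i in range(12)}
    from karyoforge.ancestor import AncestralKaryotype, ProtoChromosome

    k = AncestralKaryotype([ProtoChromosome(v, [], 0) for v in rename.values()])
    rep = evaluate_recovery(k, _perfect_paintings(ds, rename), ds)
    assert rep.painting_accuracy == 1.0
    assert rep.partition_agreement == pytest.approx(1.0)


def test_evaluate_recovery_random_labels_near_zero_ari():
    ds = simulate(_config(seed=14))
    rng = np.random.default_rng(0)
    paintings = {}
    for sp, per_chrom in ds.truth.items():
        labels = {c: [f"P{int(rng.integers(1, 13))}" for _ in v] for c, v in per_chrom.items()}
        paintings[sp] = Painting(sp, labels)
    from karyoforge.ancestor import AncestralKaryotype, ProtoChromosome

    k = AncestralKaryotype([ProtoChromosome(f"P{i+1}", [], 0) for i in range(12)])
    rep = evaluate_recovery(k, paintings, ds)
    assert abs(rep.partition_agreement) < 0.05
    assert rep.painting_accuracy < 0.3


def test_config_validation():
    with pytest.raises(ValueError, match="probabilities"):
        SimulationConfig(species=["a"], seed=1, p_missing=1.5)
    with pytest.raises(ValueError, match="seed"):
        SimulationConfig(species=["a"], seed=None)
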