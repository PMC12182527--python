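"""Trait-architecture arithmetic and phenotype simulation."""

import numpy as np
import pytest

from wildqtl.genmap import generate_genetic_map
from wildqtl.genome import DiploidGenome, elite_origin_id
from wildqtl.traits import (
    DegenerateVarianceError,
    PhenotypeModel,
    TraitArchitectureError,
    assign_elite_effects,
    assign_qtl_effects,
    assign_wild_background,
    build_effect_table,
    gamete_values,
    genotypic_value,
    qtl_allele_frequencies,
    simulate_phenotypes,
)


def _poly_dosages(rng, n, m):
    """Dosage matrix guaranteed polymorphic at every marker."""
    d = rng.integers(0, 3, (n, m))
    d[0] = 0
    d[1] = 2
    return d


def test_geometric_effect_series():
    rng = np.random.default_rng(0)
    sub = _poly_dosages(rng, 10, 50)
    qtl = assign_qtl_effects(sub, 5, rng)
    np.testing.assert_allclose(qtl.effects, [5.0, 2.5, 1.25, 0.625, 0.3125])
    np.testing.assert_allclose(qtl.effects[:-1] / qtl.effects[1:], 2.0)
    np.testing.assert_allclose(
        qtl.effect_percents(100.0), [5.0, 2.5, 1.25, 0.625, 0.3125]
    )
    single = assign_qtl_effects(sub, 1, rng)
    assert single.effects.tolist() == [5.0]


def test_background_totals():
    gmap = generate_genetic_map(50, 1, 49.0, "even")
    rng = np.random.default_rng(1)
    sub = _poly_dosages(rng, 10, 50)
    q1 = assign_qtl_effects(sub, 1, rng)
    bg1 = assign_wild_background(gmap, q1)
    assert bg1.sum() == pytest.approx(45.0)
    q5 = assign_qtl_effects(sub, 5, rng)
    bg5 = assign_wild_background(gmap, q5)
    assert bg5.sum() == pytest.approx(40.3125)
    assert np.all(bg1[q1.qtl_markers] == 0)


def test_wild_total_is_half_elite_total_exactly():
    gmap = generate_genetic_map(64, 2, 63.0, "even")
    rng = np.random.default_rng(2)
    sub = _poly_dosages(rng, 12, 64)
    for n_qtl in (1, 2, 5):
        effects, qtl = build_effect_table(gmap, sub, n_qtl, rng)
        # haploid wild total: background plus QTL effects on the effect alleles
        wild_total = effects.wild.max(axis=0).sum()
        elite_total = effects.elite[0].sum()
        assert wild_total == pytest.approx(elite_total / 2)
        assert elite_total == pytest.approx(effects.elite_total)


def test_too_large_qtl_effects_rejected():
    gmap = generate_genetic_map(20, 1, 19.0, "even")
    rng = np.random.default_rng(3)
    sub = _poly_dosages(rng, 8, 20)
    qtl = assign_qtl_effects(sub, 1, rng, emax_percent=60.0)
    with pytest.raises(TraitArchitectureError):
        assign_wild_background(gmap, qtl)


def test_monomorphic_markers_never_chosen():
    rng = np.random.default_rng(4)
    sub = np.zeros((10, 30), dtype=int)
    sub[:5, 7] = 1  # only marker 7 is polymorphic
    for _ in range(50):
        qtl = assign_qtl_effects(sub, 1, rng)
        assert qtl.qtl_markers[0] == 7
    with pytest.raises(TraitArchitectureError):
        assign_qtl_effects(sub, 2, rng)


def test_elite_infinitesimal_effect_per_marker():
    gmap = generate_genetic_map(16076, 9, 625.0, "even")
    elite = assign_elite_effects(gmap, 100.0)
    assert elite[0, 0] == pytest.approx(100.0 / 16076)
    assert elite[1].sum() == pytest.approx(100.0)


def test_pure_elite_homozygote_scores_twice_elite_total():
    gmap = generate_genetic_map(40, 2, 39.0, "even")
    rng = np.random.default_rng(5)
    sub = _poly_dosages(rng, 10, 40)
    effects, _ = build_effect_table(gmap, sub, 1, rng)
    m = gmap.n_markers
    elite = DiploidGenome(
        np.zeros((2, m), np.uint8), np.full((2, m), elite_origin_id(0, 0), np.int32)
    )
    assert genotypic_value(elite, effects) == pytest.approx(200.0)
    zero_table = effects
    wildless = DiploidGenome(
        np.ones((2, m), np.uint8), np.full((2, m), elite_origin_id(0, 1), np.int32)
    )
    assert genotypic_value(wildless, zero_table) == pytest.approx(200.0)


def test_two_marker_toy_enumeration():
    """QTL at marker 0 (allele 1, e=5), elite infinitesimal elsewhere."""
    gmap = generate_genetic_map(2, 1, 1.0, "even")
    rng = np.random.default_rng(6)
    sub = np.array([[0, 0], [2, 2], [1, 1]])
    # force QTL to marker 0 / allele 1 by drawing until it lands there
    while True:
        effects, qtl = build_effect_table(gmap, sub, 1, rng)
        if qtl.qtl_markers[0] == 0 and qtl.qtl_alleles[0] == 1:
            break
    bg = effects.wild[0, 1]  # background per wild copy at the non-QTL marker
    e_elite = effects.elite[0, 0]
    for dosage in (0, 1, 2):
        alleles = np.zeros((2, 2), np.uint8)
        alleles[:dosage, 0] = 1
        origins = np.stack(
            [np.array([0, 0], np.int32), np.array([1, 1], np.int32)]
        )
        g = DiploidGenome(alleles, origins)  # fully wild individual
        expected = dosage * 5.0 + 2 * bg
        assert genotypic_value(g, effects) == pytest.approx(expected)
    assert e_elite == pytest.approx(50.0)  # E/M with M=2


def test_gamete_values_additivity(small_pop, rng):
    from wildqtl.genome import gamete_batch

    gmap = small_pop.gmap
    sub = small_pop.dosage_matrix()[:20]
    effects, _ = build_effect_table(gmap, sub, 1, rng)
    parent = small_pop.genomes[0]
    g = gamete_batch(parent, gmap, rng, 4)
    for i in range(4):
        single = DiploidGenome(
            np.stack([g.alleles[i], g.alleles[i]]),
            np.stack([g.origins[i], g.origins[i]]),
        )
        assert genotypic_value(single, effects) == pytest.approx(
            2 * gamete_values(g.alleles[i : i + 1], g.origins[i : i + 1], effects)[0]
        )


def test_phenotype_model_variance_relations():
    m = PhenotypeModel.from_genetic_variance(0.5, 2.0)
    assert m.v_e == pytest.approx(2.0)  # h2=0.5 -> v_e = v_g
    m9 = PhenotypeModel.from_genetic_variance(0.9, 9.0)
    assert m9.v_e == pytest.approx(1.0)
    with pytest.raises(DegenerateVarianceError):
        PhenotypeModel.from_genetic_variance(0.5, 0.0)


class _FakeEntry:
    def __init__(self, v):
        self.genotypic_value = v
        self.phenotype = None


class _FakeMpop:
    def __init__(self, values):
        self.entries = [_FakeEntry(v) for v in values]


def test_h2_one_phenotype_equals_genotype(rng):
    values = rng.normal(size=30)
    mpop = _FakeMpop(values)
    phen, model = simulate_phenotypes(mpop, 1.0, rng)
    np.testing.assert_allclose(phen, values)
    assert model.v_e == 0.0


def test_noise_variance_matches_v_e(rng):
    values = np.repeat(rng.normal(size=40), 1)
    diffs = []
    for i in range(1000):
        mpop = _FakeMpop(values)
        phen, model = simulate_phenotypes(mpop, 0.5, np.random.default_rng(i))
        diffs.append(phen - values)
    emp = np.var(np.concatenate(diffs))
    assert emp == pytest.approx(model.v_e, rel=0.1)


def test_heritability_recovery_at_300_entries(rng):
    """v_g / (v_g + Var(noise)) recovers the set h2 within 0.05."""
    values = rng.normal(0, np.sqrt(4.0), 300)
    for h2 in (0.5, 0.7, 0.9):
        mpop = _FakeMpop(values)
        phen, model = simulate_phenotypes(mpop, h2, rng)
        noise_var = np.var(phen - values, ddof=1)
        est = model.v_g / (model.v_g + noise_var)
        assert est == pytest.approx(h2, abs=0.05)


def test_entry_value_and_phenotype_roundtrip(small_pop, small_founders, rng):
    from wildqtl.designs import build_entry
    from wildqtl.traits import entry_value_and_phenotype

    elite, tester = small_founders
    gmap = small_pop.gmap
    sub = small_pop.dosage_matrix()[:20]
    effects, _ = build_effect_table(gmap, sub, 1, rng)
    entry = build_entry("M1", small_pop.genomes[0], elite, tester, 8, gmap, rng)
    model = PhenotypeModel(h2=1.0, v_g=1.0, v_e=0.0)
    value, phen = entry_value_and_phenotype(entry, effects, model, rng)
    assert phen == value  # v_e = 0: phenotype equals the genotypic value
    assert entry.genotypic_value == value
    expected = np.mean([genotypic_value(p, effects) for p in entry.progeny])
    assert value == pytest.approx(expected)


def test_effect_table_serializes_to_long_frame(rng):
    gmap = generate_genetic_map(30, 1, 29.0, "even")
    sub = _poly_dosages(rng, 8, 30)
    effects, qtl = build_effect_table(gmap, sub, 2, rng)
    frame = effects.to_frame(gmap)
    assert set(frame.columns) == {"marker_id", "allele", "origin", "effect"}
    wild_total = frame.loc[
        (frame.origin == "wild")
        & frame.marker_id.isin(np.array(gmap.marker_names)[qtl.qtl_markers]),
        "effect",
    ].sum()
    assert wild_total == pytest.approx(qtl.effects.sum())


def test_qtl_allele_frequency_accounting():
    sub = np.zeros((300, 5), dtype=int)
    sub[0, 2] = 1  # one single allele copy at marker 2
    from wildqtl.traits import QTLConfig

    qtl = QTLConfig(
        qtl_markers=np.array([2]),
        qtl_alleles=np.array([1], np.int8),
        effects=np.array([5.0]),
        emax_percent=5.0,
    )
    freq = qtl_allele_frequencies(qtl, sub)
    assert freq[0] == pytest.approx(1 / 600)
    assert round(100 * freq[0], 2) == 0.17
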