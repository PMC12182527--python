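"""Haploblock catalog, rarity scoring and greedy diversity selection."""

import numpy as np
import pytest

from wildqtl.genmap import GeneticMap, generate_genetic_map
from wildqtl.genome import DiploidGenome
from wildqtl.subset import (
    build_catalog,
    rarity_score,
    select_diverse_subset,
)
from wildqtl.synthetic import FounderPopulation


def _pop_from_haplotypes(haps, gmap, ids_start=0):
    """Build a population from a (2N, M) haplotype matrix."""
    genomes = []
    m = haps.shape[1]
    for i in range(haps.shape[0] // 2):
        origins = np.stack(
            [np.full(m, 2 * i, np.int32), np.full(m, 2 * i + 1, np.int32)]
        )
        genomes.append(
            DiploidGenome(np.array(haps[2 * i : 2 * i + 2], np.uint8), origins)
        )
    return FounderPopulation(genomes, gmap)


def test_catalog_block_arithmetic():
    """2 individuals, 10 markers, window 5 -> 2 blocks of 4 haplotypes each."""
    gmap = generate_genetic_map(10, 1, 9.0, "even")
    haps = np.random.default_rng(0).integers(0, 2, (4, 10))
    cat = build_catalog(_pop_from_haplotypes(haps, gmap), window_size=5)
    assert cat.n_blocks == 2
    for b in range(2):
        assert cat.counts[cat.labels[b] + cat.offsets[b]].size == 4
        total = sum(
            cat.counts[c]
            for c in np.unique(cat.labels[b] + cat.offsets[b])
        )
        assert total == 4


def test_catalog_identical_haplotypes_single_class():
    gmap = generate_genetic_map(10, 1, 9.0, "even")
    haps = np.tile(np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0]), (6, 1))
    cat = build_catalog(_pop_from_haplotypes(haps, gmap), window_size=5)
    assert np.array_equal(cat.counts, [6, 6])


def test_catalog_hand_tally():
    """One block, strings {A x5, B x2, C x1} -> counts 5, 2, 1."""
    gmap = generate_genetic_map(5, 1, 4.0, "even")
    a = [0, 0, 0, 0, 0]
    b = [1, 1, 1, 1, 1]
    c = [0, 1, 0, 1, 0]
    haps = np.array([a, a, a, a, a, b, b, c])
    cat = build_catalog(_pop_from_haplotypes(haps, gmap), window_size=5)
    assert sorted(cat.counts.tolist()) == [1, 2, 5]


def test_rarity_score_direct_formula():
    """Counts {5, 1} on the two haplotypes of one block -> 1/5 + 1 = 1.2."""
    gmap = generate_genetic_map(5, 1, 4.0, "even")
    a = [0, 0, 0, 0, 0]
    c = [1, 1, 1, 1, 1]
    # individual 0 carries one 'a' (count 5) and the unique 'c' (count 1)
    haps = np.array([a, c, a, a, a, a])
    cat = build_catalog(_pop_from_haplotypes(haps, gmap), window_size=5)
    assert rarity_score(0, cat) == pytest.approx(1 / 5 + 1)


def test_rarity_uniform_population_is_2b_over_2n(small_pop):
    """If every block string had count 2N the score would be 2B/(2N)."""
    gmap = generate_genetic_map(20, 2, 18.0, "even")
    haps = np.tile(np.random.default_rng(1).integers(0, 2, 20), (8, 1))
    cat = build_catalog(_pop_from_haplotypes(haps, gmap), window_size=5)
    b = cat.n_blocks
    assert rarity_score(0, cat) == pytest.approx(2 * b / 8)


def _brute_force_greedy(pop, cat, seed_ids, n_total):
    """Independent dict-based reimplementation of the greedy stage."""
    eligible = {c for c in range(cat.counts.size) if cat.counts[c] >= 2}
    member = {
        i: set(cat.individual_classes(i).tolist()) for i in range(pop.n_individuals)
    }
    covered = set()
    for i in seed_ids:
        covered |= member[i] & eligible
    chosen = list(seed_ids)
    while len(chosen) < n_total:
        gains = {
            i: len((member[i] & eligible) - covered)
            for i in range(pop.n_individuals)
            if i not in chosen
        }
        best_gain = max(gains.values())
        best = min(i for i, g in gains.items() if g == best_gain)
        chosen.append(best)
        covered |= member[best] & eligible
    return chosen


def test_greedy_matches_brute_force_oracle():
    gmap = generate_genetic_map(10, 1, 9.0, "even")
    rng = np.random.default_rng(7)
    haps = rng.integers(0, 2, (12, 10))
    haps[4] = haps[0]  # create sharing so counts >= 2 exist
    haps[7] = haps[2]
    haps[9] = haps[0]
    pop = _pop_from_haplotypes(haps, gmap)
    cat = build_catalog(pop, window_size=5)
    selected = select_diverse_subset(pop, cat, n_total=5, n_seed=2)
    oracle = _brute_force_greedy(pop, cat, selected[:2], 5)
    assert selected == oracle


def test_singleton_haplotypes_never_add_coverage():
    """An individual whose blocks are all unique contributes zero gain."""
    gmap = generate_genetic_map(5, 1, 4.0, "even")
    shared = [0, 0, 0, 0, 0]
    uniq1 = [1, 0, 1, 0, 1]
    uniq2 = [0, 1, 1, 0, 0]
    haps = np.array([shared, shared, shared, shared, uniq1, uniq2])
    pop = _pop_from_haplotypes(haps, gmap)
    cat = build_catalog(pop, window_size=5)
    eligible = cat.counts >= 2
    cls = cat.individual_classes(2)  # the individual carrying uniq1/uniq2
    assert not np.any(eligible[cls] & (cat.counts[cls] < 2))
    assert np.count_nonzero(eligible[cat.individual_classes(2)]) == 0


def test_select_everyone_when_n_total_is_population_size(small_pop):
    selected = select_diverse_subset(small_pop, n_total=small_pop.n_individuals)
    assert sorted(selected) == list(range(small_pop.n_individuals))


def test_selection_oversize_rejected(small_pop):
    with pytest.raises(ValueError):
        select_diverse_subset(small_pop, n_total=small_pop.n_individuals + 1)


def test_selection_deterministic_and_coverage_monotone(small_pop):
    cat = build_catalog(small_pop)
    s1 = select_diverse_subset(small_pop, cat, n_total=30, n_seed=5)
    s2 = select_diverse_subset(small_pop, cat, n_total=30, n_seed=5)
    assert s1 == s2
    eligible = cat.counts >= 2
    covered = np.zeros(cat.counts.size, bool)
    sizes = []
    for i in s1:
        covered[cat.individual_classes(i)] = True
        sizes.append(np.count_nonzero(covered & eligible))
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))


def test_selected_subset_beats_random_subsets(small_pop):
    cat = build_catalog(small_pop)
    eligible = cat.counts >= 2

    def coverage(ids):
        covered = np.zeros(cat.counts.size, bool)
        for i in ids:
            covered[cat.individual_classes(i)] = True
        return np.count_nonzero(covered & eligible)

    chosen = select_diverse_subset(small_pop, cat, n_total=25, n_seed=5)
    rng = np.random.default_rng(0)
    for _ in range(20):
        rand = rng.choice(small_pop.n_individuals, 25, replace=False)
        assert coverage(chosen) >= coverage(rand)
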