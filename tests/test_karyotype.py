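"""Meiotic pairing engine: printed cytogenetic examples, independent oracles,
segregation and pedigree enumeration."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from agrodelim.karyotype import (
    ArmUniverse,
    DiploidGenotype,
    HaploidKaryotype,
    KaryotypeValidationError,
    PedigreeScenario,
    SpeciesKaryotypeSpec,
    achievable_visible_counts,
    build_default_two_species_model,
    classify_karyotype_consistency,
    cross,
    enumerate_balanced_gametes,
    gamete_distribution,
    pair_meiosis,
)


def het_genotype(n_arms: int, fused=("a1", "a2")) -> DiploidGenotype:
    """One haplotype with a single two-arm fusion, the other fully unfused."""
    uni = ArmUniverse(tuple(f"a{i}" for i in range(1, n_arms + 1)))
    return DiploidGenotype(
        HaploidKaryotype.from_fusions(uni, [fused]),
        HaploidKaryotype.from_fusions(uni),
    )


# ---------------------------------------------------------------------------
# pairing engine


@pytest.mark.parametrize(
    "n_arms, expect_visible, expect_bivalents, expect_trivalents",
    [
        # fusion heterozygote over 42 arms: 40 bivalents + 1 trivalent (2n=83)
        (42, 41, 40, 1),
        # fusion heterozygote over 43 arms: 41 bivalents + 1 trivalent (2n=85)
        (43, 42, 41, 1),
    ],
)
def test_fusion_heterozygote_pairing(n_arms, expect_visible, expect_bivalents,
                                     expect_trivalents):
    config = pair_meiosis(het_genotype(n_arms))
    assert config.visible_count == expect_visible
    assert config.count_kind("bivalent") == expect_bivalents
    assert config.count_kind("trivalent") == expect_trivalents


def test_homozygote_pairs_into_all_bivalents():
    uni = ArmUniverse(tuple(f"a{i}" for i in range(12)))
    hap = HaploidKaryotype.from_fusions(uni, [("a0", "a1"), ("a2", "a3")])
    config = pair_meiosis(DiploidGenotype(hap, hap))
    assert config.visible_count == hap.n
    assert all(e.kind == "bivalent" for e in config.elements)


def test_pairing_conserves_arms_and_arities():
    genotype = het_genotype(10, fused=("a1", "a2"))
    config = pair_meiosis(genotype)
    assert sum(e.arity for e in config.elements) == genotype.diploid_number
    arm_cover = [a for e in config.elements
                 for side in (e.members_a, e.members_b)
                 for c in side for a in c]
    assert sorted(arm_cover) == sorted(list(genotype.universe.arms) * 2)


def test_invalid_partition_names_offending_arm():
    uni = ArmUniverse(("x", "y", "z"))
    with pytest.raises(KaryotypeValidationError, match="z"):
        HaploidKaryotype(uni, frozenset({frozenset({"x", "y"})}))


# --- independent disjoint-set-union oracle -------------------------------


def dsu_visible_count(chroms_a, chroms_b, arms) -> int:
    """Union-find over chromosome nodes, independent of the engine's BFS."""
    nodes = [("a", c) for c in chroms_a] + [("b", c) for c in chroms_b]
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    carrier_a = {arm: ("a", c) for c in chroms_a for arm in c}
    carrier_b = {arm: ("b", c) for c in chroms_b for arm in c}
    for arm in arms:
        ra, rb = find(carrier_a[arm]), find(carrier_b[arm])
        if ra != rb:
            parent[ra] = rb
    return len({find(v) for v in nodes})


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def random_partition(arms, rng):
    k = rng.integers(1, len(arms) + 1)
    assignment = rng.integers(0, k, size=len(arms))
    blocks = {}
    for arm, block in zip(arms, assignment):
        blocks.setdefault(block, set()).add(arm)
    return frozenset(frozenset(b) for b in blocks.values())


def test_component_counts_match_dsu_exhaustively_small():
    """Exhaustive agreement with the union-find oracle for <=5 arms."""
    for n_arms in (2, 3, 5):
        arms = [f"a{i}" for i in range(n_arms)]
        uni = ArmUniverse(tuple(arms))
        partitions = [frozenset(frozenset(b) for b in p)
                      for p in set_partitions(arms)]
        for pa, pb in itertools.product(partitions, repeat=2):
            genotype = DiploidGenotype(HaploidKaryotype(uni, pa),
                                       HaploidKaryotype(uni, pb))
            assert pair_meiosis(genotype).visible_count == \
                dsu_visible_count(pa, pb, arms)


def test_component_counts_match_dsu_random():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n_arms = int(rng.integers(2, 13))
        arms = [f"a{i}" for i in range(n_arms)]
        uni = ArmUniverse(tuple(arms))
        pa, pb = random_partition(arms, rng), random_partition(arms, rng)
        genotype = DiploidGenotype(HaploidKaryotype(uni, pa),
                                   HaploidKaryotype(uni, pb))
        assert pair_meiosis(genotype).visible_count == \
            dsu_visible_count(pa, pb, arms)


# ---------------------------------------------------------------------------
# balanced segregation


def test_trivalent_segregates_two_ways():
    config = pair_meiosis(het_genotype(2))
    gametes = enumerate_balanced_gametes(config)
    options = {g.chromosomes for g in gametes}
    assert options == {
        frozenset({frozenset({"a1", "a2"})}),
        frozenset({frozenset({"a1"}), frozenset({"a2"})}),
    }


def test_homozygote_yields_single_gamete():
    uni = ArmUniverse(("a", "b", "c"))
    hap = HaploidKaryotype.from_fusions(uni, [("a", "b")])
    gametes = enumerate_balanced_gametes(pair_meiosis(DiploidGenotype(hap, hap)))
    assert len(gametes) == 1
    assert gametes[0].chromosomes == hap.chromosomes


def test_chained_quadrivalent_matches_subset_bruteforce():
    """{AB, C} vs {A, BC}: enumerate exact covers by filtering all subsets."""
    uni = ArmUniverse(("A", "B", "C"))
    hap1 = HaploidKaryotype.from_fusions(uni, [("A", "B")])
    hap2 = HaploidKaryotype.from_fusions(uni, [("B", "C")])
    config = pair_meiosis(DiploidGenotype(hap1, hap2))
    assert config.visible_count == 1 and config.elements[0].kind == "quadrivalent"

    chroms = sorted(hap1.chromosomes | hap2.chromosomes, key=sorted)
    brute = set()
    for r in range(len(chroms) + 1):
        for combo in itertools.combinations(chroms, r):
            arms = [a for c in combo for a in c]
            if len(arms) == 3 and set(arms) == {"A", "B", "C"}:
                brute.add(frozenset(combo))
    assert {g.chromosomes for g in enumerate_balanced_gametes(config)} == brute


def test_gametes_partition_universe_and_probabilities_sum_to_one():
    config = pair_meiosis(het_genotype(6, fused=("a3", "a4")))
    dist = gamete_distribution(config)
    assert sum(dist.values()) == Fraction(1)
    for gamete in dist:
        assert gamete.universe.arms == frozenset(
            a for c in gamete.chromosomes for a in c)


# ---------------------------------------------------------------------------
# crosses and pedigree scenarios


def test_homozygote_selfcross_single_offspring(default_model):
    orphicus, _, _ = default_model
    parent = DiploidGenotype(orphicus.haplotype({next(iter(orphicus.polymorphic_fusions)): True}),
                             orphicus.haplotype({next(iter(orphicus.polymorphic_fusions)): True}))
    offspring = cross(parent, parent)
    assert len(offspring) == 1
    assert sum(offspring.values()) == Fraction(1)


def test_f1_heterozygous_exactly_at_differing_fusions(default_model):
    orphicus, lurae, _ = default_model
    for state_a, state_b in itertools.product([False, True], repeat=2):
        hap_o = orphicus.haplotype({next(iter(orphicus.polymorphic_fusions)): state_a})
        hap_l = lurae.haplotype({next(iter(lurae.polymorphic_fusions)): state_b})
        mismatched_arms = {a for c in hap_o.chromosomes ^ hap_l.chromosomes
                           for a in c}
        # pair F always differs (the fixed difference); pair P differs unless
        # the orphicus gamete carries the fusion (lurae is fixed fused); pair
        # Q differs unless the lurae gamete carries the fusion
        expected = {"F1", "F2"}
        if not state_a:
            expected |= {"P1", "P2"}
        if not state_b:
            expected |= {"Q1", "Q2"}
        assert mismatched_arms == expected


def test_default_model_printed_counts(default_model):
    orphicus, lurae, universe = default_model
    assert len(universe) == 44
    pair_p = next(iter(orphicus.polymorphic_fusions))
    pair_q = next(iter(lurae.polymorphic_fusions))
    assert orphicus.haplotype({pair_p: True}).n == 41   # fully fused: 2n=82
    assert orphicus.haplotype({pair_p: False}).n == 42  # 2n=84
    assert lurae.haplotype({pair_q: True}).n == 42      # 2n=84
    assert lurae.haplotype({pair_q: False}).n == 43     # two unfused pairs: 2n=86
    # exactly one fixed fused/unfused difference (pair F)
    fixed_diff = orphicus.fixed_fusions - lurae.fixed_fusions - set(lurae.polymorphic_fusions)
    assert len(fixed_diff) == 1


def test_f1_visible_count_invariant_41(default_model):
    orphicus, lurae, _ = default_model
    counts = achievable_visible_counts(PedigreeScenario("F1", orphicus, lurae))
    assert set(counts) == {41}
    assert sum(counts.values()) == Fraction(1)


def test_backcross_count_set_and_nesting(default_model):
    orphicus, lurae, _ = default_model
    f1 = set(achievable_visible_counts(PedigreeScenario("F1", orphicus, lurae)))
    bc1 = achievable_visible_counts(PedigreeScenario("BC1", orphicus, lurae))
    assert set(bc1) == {41, 42, 43}
    assert f1 <= set(bc1)
    assert sum(bc1.values()) == Fraction(1)


def test_pure_scenario_supports(default_model):
    orphicus, lurae, _ = default_model
    assert set(achievable_visible_counts(
        PedigreeScenario("pure-A", orphicus, lurae))) == {41, 42}
    assert set(achievable_visible_counts(
        PedigreeScenario("pure-B", orphicus, lurae))) == {42, 43}


@pytest.mark.parametrize("observed_n, haplogroup, category", [
    (42, "orph2", "pure-orphicus-consistent"),
    (43, "orph2", "backcross-consistent"),
    (41, "aroa3", "inconsistent"),
    (42, "aroa3", "pure-lurae-consistent"),
])
def test_classify_karyotype_consistency(observed_n, haplogroup, category):
    call = classify_karyotype_consistency(observed_n, haplogroup)
    assert call.category == category
    if category == "backcross-consistent":
        assert "F1" not in call.matching_scenarios


def test_classify_f1_under_study_population_model(albanian_model):
    """With orphicus fixed at n=42, a 41-count orph2 specimen is F1-like."""
    spec_a, spec_b, _ = albanian_model
    call = classify_karyotype_consistency(41, "orph2", model=(spec_a, spec_b))
    assert call.category == "F1-consistent"


def test_spec_config_roundtrip(tmp_path, default_model):
    from agrodelim.karyotype import read_model_json, write_model_json

    orphicus, lurae, _ = default_model
    path = tmp_path / "model.json"
    write_model_json(path, orphicus, lurae)
    loaded = read_model_json(path)
    assert loaded[0] == orphicus and loaded[1] == lurae


def test_overlapping_fusions_rejected():
    uni = ArmUniverse(("a", "b", "c"))
    with pytest.raises(KaryotypeValidationError):
        SpeciesKaryotypeSpec(
            "bad", uni,
            fixed_fusions=frozenset({frozenset({"a", "b"})}),
            polymorphic_fusions={frozenset({"b", "c"}): 0.5},
        )
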