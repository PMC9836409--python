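"""Meiotic fusion/fission pairing model for Robertsonian karyotype variation.

Chromosome-number variation in many Lepidoptera (notably the *Agrodiaetus*
"anomalous blues") is driven by chromosome fusions and fissions.  A karyotype
is modelled here as a partition of a fixed universe of ancestral chromosome
*arms* into chromosomes: an unfused chromosome carries one arm, a fused
chromosome carries two or more.  At metaphase I (MI) of meiosis, homologous
arms pair; a fusion heterozygote therefore forms a trivalent (the fused
chromosome plus the two unfused homologues) and, when fusions chain across
arms, higher multivalents.  The number of *visible elements* — bivalents plus
multivalents — is what a cytogeneticist counts in an MI spread, and is the
quantity that discriminates pure species, F1 hybrids and backcrosses when two
taxa differ by fixed and polymorphic fusions.

The model is purely structural: pairing is the connected-component structure
of the homology graph (chromosomes as nodes, one edge per shared arm), and
multivalents are assumed to segregate in a balanced fashion (each gamete
receives every arm exactly once), with equal weight on each balanced option.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ArmUniverse",
    "HaploidKaryotype",
    "DiploidGenotype",
    "MeioticElement",
    "MeioticConfiguration",
    "SpeciesKaryotypeSpec",
    "PedigreeScenario",
    "KaryotypeValidationError",
    "build_default_two_species_model",
    "pair_meiosis",
    "enumerate_balanced_gametes",
    "gamete_distribution",
    "cross",
    "achievable_visible_counts",
    "classify_karyotype_consistency",
    "ConsistencyCall",
]

Chromosome = frozenset  # frozenset of arm ids

ELEMENT_KINDS = {2: "bivalent", 3: "trivalent", 4: "quadrivalent"}


class KaryotypeValidationError(ValueError):
    """A karyotype does not partition its arm universe."""


@dataclass(frozen=True)
class ArmUniverse:
    """The finest arm segmentation shared by all karyotypes under comparison."""

    arm_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.arm_ids:
            raise KaryotypeValidationError("arm universe must be non-empty")
        if len(set(self.arm_ids)) != len(self.arm_ids):
            raise KaryotypeValidationError("arm identifiers must be unique")

    @property
    def arms(self) -> frozenset:
        return frozenset(self.arm_ids)

    def __len__(self) -> int:
        return len(self.arm_ids)


@dataclass(frozen=True)
class HaploidKaryotype:
    """A haploid complement: a partition of the arm universe into chromosomes.

    ``n`` (the haploid chromosome number counted at MII) is simply the number
    of chromosomes in the partition.
    """

    universe: ArmUniverse
    chromosomes: frozenset  # frozenset of Chromosome

    def __post_init__(self) -> None:
        seen: set = set()
        for chrom in self.chromosomes:
            if not chrom:
                raise KaryotypeValidationError("empty chromosome")
            dup = seen & chrom
            if dup:
                raise KaryotypeValidationError(
                    f"arm(s) {sorted(dup)} appear in more than one chromosome"
                )
            seen |= chrom
        missing = self.universe.arms - seen
        extra = seen - self.universe.arms
        if missing:
            raise KaryotypeValidationError(f"arm(s) {sorted(missing)} missing")
        if extra:
            raise KaryotypeValidationError(f"arm(s) {sorted(extra)} not in universe")

    @classmethod
    def from_fusions(
        cls, universe: ArmUniverse, fusions: Iterable[Iterable[str]] = ()
    ) -> "HaploidKaryotype":
        """All arms unfused except the given fused arm-sets (pairwise disjoint)."""
        fused = [frozenset(f) for f in fusions]
        in_fusion = set().union(*fused) if fused else set()
        chroms = set(fused)
        chroms.update(frozenset([a]) for a in universe.arms - in_fusion)
        return cls(universe, frozenset(chroms))

    @property
    def n(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class DiploidGenotype:
    """Two haploid complements over one arm universe; 2n = n_a + n_b."""

    haplotype_a: HaploidKaryotype
    haplotype_b: HaploidKaryotype

    def __post_init__(self) -> None:
        if self.haplotype_a.universe != self.haplotype_b.universe:
            raise KaryotypeValidationError("haplotypes use different arm universes")

    @property
    def universe(self) -> ArmUniverse:
        return self.haplotype_a.universe

    @property
    def diploid_number(self) -> int:
        return self.haplotype_a.n + self.haplotype_b.n

    def key(self) -> frozenset:
        """Unordered genotype identity (maternal/paternal phase ignored)."""
        return frozenset([self.haplotype_a.chromosomes, self.haplotype_b.chromosomes])


@dataclass(frozen=True)
class MeioticElement:
    """One MI pairing element: the chromosomes linked through shared arms."""

    members_a: frozenset  # chromosomes contributed by haplotype_a
    members_b: frozenset

    @property
    def arity(self) -> int:
        return len(self.members_a) + len(self.members_b)

    @property
    def arms(self) -> frozenset:
        out: frozenset = frozenset()
        for chrom in self.members_a:
            out |= chrom
        return out

    @property
    def kind(self) -> str:
        return ELEMENT_KINDS.get(self.arity, "multivalent")


@dataclass(frozen=True)
class MeioticConfiguration:
    """The MI pairing outcome of a genotype: its visible elements."""

    genotype: DiploidGenotype
    elements: tuple[MeioticElement, ...]
    stage: str = "MI"

    @property
    def visible_count(self) -> int:
        return len(self.elements)

    def count_kind(self, kind: str) -> int:
        return sum(1 for e in self.elements if e.kind == kind)


def pair_meiosis(genotype: DiploidGenotype) -> MeioticConfiguration:
    """Compute the MI pairing configuration of a diploid genotype.

    Builds the homology graph — every chromosome of both haplotypes is a node
    and each arm contributes one edge joining its carrier in haplotype A to
    its carrier in haplotype B — and returns the connected components as
    pairing elements.  A fusion homozygote yields a bivalent, a simple fusion
    heterozygote a trivalent, chained heterozygous fusions quadrivalents and
    higher multivalents.
    """
    carrier_a = {arm: chrom for chrom in genotype.haplotype_a.chromosomes for arm in chrom}
    carrier_b = {arm: chrom for chrom in genotype.haplotype_b.chromosomes for arm in chrom}

    # union-find-free traversal: components of the bipartite homology graph
    nodes = [("a", c) for c in genotype.haplotype_a.chromosomes]
    nodes += [("b", c) for c in genotype.haplotype_b.chromosomes]
    adjacency: dict = {node: set() for node in nodes}
    for arm in genotype.universe.arms:
        u, v = ("a", carrier_a[arm]), ("b", carrier_b[arm])
        adjacency[u].add(v)
        adjacency[v].add(u)

    seen: set = set()
    elements = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nbr in adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        elements.append(MeioticElement(
            members_a=frozenset(c for side, c in comp if side == "a"),
            members_b=frozenset(c for side, c in comp if side == "b"),
        ))
    elements.sort(key=lambda e: sorted(e.arms)[0])
    return MeioticConfiguration(genotype=genotype, elements=tuple(elements))


def _element_balanced_choices(element: MeioticElement) -> list[frozenset]:
    """Balanced segregation options for one element.

    A balanced gametic contribution from an element is a subset of its member
    chromosomes covering each of the element's arms exactly once (an exact
    cover).  Unbalanced (aneuploid) products are excluded.
    """
    members = sorted(element.members_a | element.members_b, key=sorted)
    arms = element.arms
    choices = []
    for r in range(1, len(members) + 1):
        for combo in itertools.combinations(members, r):
            covered: list = []
            for chrom in combo:
                covered.extend(chrom)
            if len(covered) == len(arms) and set(covered) == arms:
                choices.append(frozenset(combo))
    if not choices:
        raise KaryotypeValidationError(
            f"element over arms {sorted(arms)} admits no balanced segregation"
        )
    return sorted(set(choices), key=lambda c: sorted(map(sorted, c)))


def gamete_distribution(config: MeioticConfiguration) -> dict:
    """Balanced gametes and their probabilities under equal per-element weights.

    Returns ``{HaploidKaryotype: Fraction}``; probabilities sum to 1 exactly.
    """
    per_element = [_element_balanced_choices(e) for e in config.elements]
    out: dict = {}
    for combo in itertools.product(*per_element):
        chroms: set = set()
        for choice in combo:
            chroms |= choice
        gamete = HaploidKaryotype(config.genotype.universe, frozenset(chroms))
        prob = Fraction(1)
        for choice, choices in zip(combo, per_element):
            prob /= len(choices)
        out[gamete] = out.get(gamete, Fraction(0)) + prob
    return out


def enumerate_balanced_gametes(config: MeioticConfiguration) -> list[HaploidKaryotype]:
    """All distinct balanced gametes of a pairing configuration."""
    return list(gamete_distribution(config))


def cross(parent1: DiploidGenotype, parent2: DiploidGenotype) -> dict:
    """Offspring genotype distribution of a cross, ``{DiploidGenotype: Fraction}``.

    Gametes are drawn independently from each parent's balanced-gamete
    distribution; offspring that differ only in which parent contributed which
    haplotype are merged.
    """
    if parent1.universe != parent2.universe:
        raise KaryotypeValidationError("parents use different arm universes")
    g1 = gamete_distribution(pair_meiosis(parent1))
    g2 = gamete_distribution(pair_meiosis(parent2))
    merged: dict = {}
    rep: dict = {}
    for (ga, pa), (gb, pb) in itertools.product(g1.items(), g2.items()):
        key = frozenset([ga.chromosomes, gb.chromosomes])
        merged[key] = merged.get(key, Fraction(0)) + pa * pb
        rep.setdefault(key, DiploidGenotype(ga, gb))
    return {rep[k]: p for k, p in merged.items()}


# ---------------------------------------------------------------------------
# Species-level specifications and pedigree scenarios


@dataclass(frozen=True)
class SpeciesKaryotypeSpec:
    """Fusion state of a taxon: fixed fusions plus segregating polymorphisms.

    ``polymorphic_fusions`` maps each segregating arm-set to its fused-allele
    frequency; haplotypes are drawn per fusion independently and genotypes
    follow Hardy-Weinberg proportions within the taxon.
    """

    name: str
    universe: ArmUniverse
    fixed_fusions: frozenset = frozenset()
    polymorphic_fusions: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_sets = list(self.fixed_fusions) + list(self.polymorphic_fusions)
        for i, a in enumerate(all_sets):
            for b in all_sets[i + 1:]:
                if set(a) & set(b):
                    raise KaryotypeValidationError(
                        f"fusion arm-sets {sorted(a)} and {sorted(b)} overlap"
                    )
        for f, q in self.polymorphic_fusions.items():
            if not 0 <= q <= 1:
                raise KaryotypeValidationError(f"frequency {q} for {sorted(f)} not in [0,1]")

    def haplotype(self, fused_states: Mapping | None = None) -> HaploidKaryotype:
        """Haplotype with the given fused/unfused state per polymorphic fusion."""
        fused_states = dict(fused_states or {})
        fusions = list(self.fixed_fusions)
        for f in self.polymorphic_fusions:
            if fused_states.get(f, False):
                fusions.append(f)
        return HaploidKaryotype.from_fusions(self.universe, fusions)

    def haplotype_variants(self) -> dict:
        """All haplotypes with their allele-frequency probabilities."""
        polys = list(self.polymorphic_fusions)
        out: dict = {}
        for states in itertools.product([False, True], repeat=len(polys)):
            prob = Fraction(1)
            for f, fused in zip(polys, states):
                q = Fraction(self.polymorphic_fusions[f]).limit_denominator(10**9)
                prob *= q if fused else 1 - q
            hap = self.haplotype(dict(zip(polys, states)))
            out[hap] = out.get(hap, Fraction(0)) + prob
        return out

    def genotype_distribution(self) -> dict:
        """Hardy-Weinberg genotype distribution within the taxon."""
        haps = self.haplotype_variants()
        merged: dict = {}
        rep: dict = {}
        for (ha, pa), (hb, pb) in itertools.product(haps.items(), repeat=2):
            key = frozenset([ha.chromosomes, hb.chromosomes])
            merged[key] = merged.get(key, Fraction(0)) + pa * pb
            rep.setdefault(key, DiploidGenotype(ha, hb))
        return {rep[k]: p for k, p in merged.items()}

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "arms": list(self.universe.arm_ids),
            "fixed_fusions": sorted(sorted(f) for f in self.fixed_fusions),
            "polymorphic_fusions": [
                {"arms": sorted(f), "fused_frequency": float(q)}
                for f, q in sorted(self.polymorphic_fusions.items(), key=lambda kv: sorted(kv[0]))
            ],
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "SpeciesKaryotypeSpec":
        uni = ArmUniverse(tuple(cfg["arms"]))
        return cls(
            name=cfg["name"],
            universe=uni,
            fixed_fusions=frozenset(frozenset(f) for f in cfg.get("fixed_fusions", [])),
            polymorphic_fusions={
                frozenset(p["arms"]): p["fused_frequency"]
                for p in cfg.get("polymorphic_fusions", [])
            },
        )


@dataclass(frozen=True)
class PedigreeScenario:
    """A named crossing scheme over two parental species specifications.

    Supported labels: ``pure-A`` / ``pure-B`` (random mating within a taxon),
    ``F1`` (A x B), ``BC1`` (F1 x B, i.e. backcross to the second taxon) and
    ``F2`` (F1 x F1).
    """

    label: str
    species_a: SpeciesKaryotypeSpec
    species_b: SpeciesKaryotypeSpec

    LABELS = ("pure-A", "pure-B", "F1", "BC1", "F2")

    def genotype_distribution(self) -> dict:
        if self.label not in self.LABELS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.label == "pure-A":
            return self.species_a.genotype_distribution()
        if self.label == "pure-B":
            return self.species_b.genotype_distribution()
        f1 = _hybridize(self.species_a, self.species_b)
        if self.label == "F1":
            return f1
        if self.label == "BC1":
            return _cross_distributions(f1, self.species_b.genotype_distribution())
        return _cross_distributions(f1, f1)  # F2


def _hybridize(a: SpeciesKaryotypeSpec, b: SpeciesKaryotypeSpec) -> dict:
    """F1 genotype distribution: one haplotype variant from each species."""
    merged: dict = {}
    rep: dict = {}
    for (ha, pa), (hb, pb) in itertools.product(
        a.haplotype_variants().items(), b.haplotype_variants().items()
    ):
        key = frozenset([ha.chromosomes, hb.chromosomes])
        merged[key] = merged.get(key, Fraction(0)) + pa * pb
        rep.setdefault(key, DiploidGenotype(ha, hb))
    return {rep[k]: p for k, p in merged.items()}


def _cross_distributions(dist1: dict, dist2: dict) -> dict:
    out: dict = {}
    rep: dict = {}
    for (p1, w1), (p2, w2) in itertools.product(dist1.items(), dist2.items()):
        for child, w in cross(p1, p2).items():
            key = frozenset([child.haplotype_a.chromosomes, child.haplotype_b.chromosomes])
            out[key] = out.get(key, Fraction(0)) + w1 * w2 * w
            rep.setdefault(key, child)
    return {rep[k]: p for k, p in out.items()}


def achievable_visible_counts(scenario: PedigreeScenario) -> dict:
    """Distribution of MI visible-element counts under a pedigree scenario.

    Returns ``{visible_count: Fraction}``; the support is the achievable set
    (entries with zero probability — e.g. an allele frequency of exactly 0 or
    1 — are dropped).
    """
    dist = scenario.genotype_distribution()
    if not dist:
        raise ValueError("empty scenario")
    out: dict = {}
    for genotype, prob in dist.items():
        if prob == 0:
            continue
        count = pair_meiosis(genotype).visible_count
        out[count] = out.get(count, Fraction(0)) + prob
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# The two-species default model and consistency classification


def build_default_two_species_model(
    freq_fused_a: float = 0.5, freq_fused_b: float = 0.5
) -> tuple[SpeciesKaryotypeSpec, SpeciesKaryotypeSpec, ArmUniverse]:
    """Default fusion/fission model for the *orphicus* / *lurae* species pair.

    44 ancestral arms: 38 singletons shared by both taxa plus three two-arm
    pairs —

    * pair P: polymorphic fusion in *orphicus* (haploid n = 41 fused / 42
      unfused), fixed fused in *lurae*;
    * pair F: fixed fused in *orphicus*, fixed unfused in *lurae* — the one
      fixed fusion/fission difference separating the taxa;
    * pair Q: fixed fused in *orphicus*, polymorphic in *lurae* (n = 42 fused
      / 43 unfused).

    This is the unique disjoint-arm reconstruction (up to relabeling) giving
    *orphicus* n in {41, 42}, *lurae* n in {42, 43}, exactly one fixed
    difference and distinct polymorphic pairs; under it every F1 variant
    shows 41 visible elements at MI.
    """
    arms = tuple(f"s{i:02d}" for i in range(1, 39)) + ("P1", "P2", "F1", "F2", "Q1", "Q2")
    universe = ArmUniverse(arms)
    pair_p = frozenset({"P1", "P2"})
    pair_f = frozenset({"F1", "F2"})
    pair_q = frozenset({"Q1", "Q2"})
    orphicus = SpeciesKaryotypeSpec(
        name="orphicus",
        universe=universe,
        fixed_fusions=frozenset({pair_f, pair_q}),
        polymorphic_fusions={pair_p: freq_fused_a},
    )
    lurae = SpeciesKaryotypeSpec(
        name="lurae",
        universe=universe,
        fixed_fusions=frozenset({pair_p}),
        polymorphic_fusions={pair_q: freq_fused_b},
    )
    return orphicus, lurae, universe


#: haplogroup -> parental taxon role under the default model ("A" = orphicus,
#: "B" = lurae); aroa1/aroa2 belong to allopatric relatives outside the model.
DEFAULT_HAPLOGROUP_TAXA = {
    "orph1": "A",
    "orph2": "A",
    "aroa3": "B",
}


@dataclass(frozen=True)
class ConsistencyCall:
    """Outcome of classify_karyotype_consistency."""

    category: str
    matching_scenarios: tuple[str, ...]
    observed_n: int
    haplogroup: str


def classify_karyotype_consistency(
    observed_n: int,
    haplogroup: str,
    model: tuple[SpeciesKaryotypeSpec, SpeciesKaryotypeSpec] | None = None,
    haplogroup_taxa: Mapping | None = None,
    maternal_hybrid_taxon: str = "A",
) -> ConsistencyCall:
    """Classify an observed MI element count against the two-species model.

    The count is tested for membership in the achievable sets of the pure
    scenario of the haplogroup's own taxon and, because mitochondria are
    maternally inherited and hybridization in this system runs through
    mothers of the ``maternal_hybrid_taxon`` lineage, in the F1 and BC1 sets
    when the haplogroup belongs to that lineage.  Ties resolve to the
    minimal-generation label; all matching scenarios are reported.
    """
    if observed_n <= 0:
        raise ValueError("observed_n must be positive")
    if model is None:
        spec_a, spec_b, _ = build_default_two_species_model()
    else:
        spec_a, spec_b = model
    taxa = dict(DEFAULT_HAPLOGROUP_TAXA if haplogroup_taxa is None else haplogroup_taxa)
    if haplogroup not in taxa:
        raise KeyError(f"unknown haplogroup {haplogroup!r}")
    role = taxa[haplogroup]
    own = spec_a if role == "A" else spec_b

    def support(label: str) -> set:
        return set(achievable_visible_counts(PedigreeScenario(label, spec_a, spec_b)))

    matches = []
    pure_label = "pure-A" if role == "A" else "pure-B"
    if observed_n in support(pure_label):
        matches.append(pure_label)
    if role == maternal_hybrid_taxon:
        if observed_n in support("F1"):
            matches.append("F1")
        if observed_n in support("BC1"):
            matches.append("BC1")

    if not matches:
        category = "inconsistent"
    elif matches[0].startswith("pure"):
        category = f"pure-{own.name}-consistent"
    elif matches[0] == "F1":
        category = "F1-consistent"
    else:
        category = "backcross-consistent"
    return ConsistencyCall(
        category=category,
        matching_scenarios=tuple(matches),
        observed_n=observed_n,
        haplogroup=haplogroup,
    )


# ---------------------------------------------------------------------------
# Export helpers


def scenario_table(scenarios: Sequence[PedigreeScenario]):
    """Tidy table of achievable counts: columns scenario, visible_count, probability."""
    import pandas as pd

    rows = []
    for sc in scenarios:
        for count, prob in achievable_visible_counts(sc).items():
            rows.append({"scenario": sc.label, "visible_count": count,
                         "probability": float(prob)})
    return pd.DataFrame(rows)


def write_model_json(path, *specs: SpeciesKaryotypeSpec) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_config() for s in specs], fh, indent=2)


def read_model_json(path) -> list:
    with open(path) as fh:
        return [SpeciesKaryotypeSpec.from_config(c) for c in json.load(fh)]
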