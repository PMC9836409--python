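# Methods

`agrodelim` implements an integrative species-delimitation workflow for a pair
of cryptic "anomalous blue" butterflies (*Polyommatus* subgenus *Agrodiaetus*)
that differ by Robertsonian chromosome fusions/fissions, mitochondrial COI
haplogroups and wing colouration, and that hybridize in a substrate contact
zone. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## The meiotic fusion/fission pairing model

A haploid karyotype is a partition of a fixed universe of ancestral
chromosome arms into chromosomes; `n` is the number of blocks. At metaphase I
every arm pairs with its homologue, so the pairing structure of a diploid is
the connected-component structure of the *homology graph*: one node per
chromosome of either haplotype, one edge per arm joining its two carriers. A
fusion homozygote gives a bivalent, a simple fusion heterozygote a trivalent,
chained heterozygous fusions quadrivalents and beyond. The number of *visible
elements* (bivalents + multivalents) is the component count — exactly what is
counted in an MI spread.

Assumptions, stated plainly:

* **Pairing is structural.** Chiasma formation or failure, univalence and
  pairing partner choice are not modelled; every homologous arm pair is
  assumed to synapse.
* **Balanced segregation only.** A multivalent's gametic products are the
  exact covers of its arms by its member chromosomes, weighted equally;
  aneuploid (unbalanced) products are excluded, since the downstream argument
  concerns viable hybrid offspring.
* **No recombination between fusion states**, no meiotic drive, no inversion
  polymorphism.

### The default two-species model

Printed haploid counts pin down the arm universe. With one fixed
fusion/fission difference and one distinct polymorphic fusion per species,
the unique disjoint-arm reconstruction (up to relabeling) uses **44 arms**:
38 shared singletons plus three two-arm pairs,

| pair | *P. orphicus* (species A) | *P. lurae* (species B) |
|------|---------------------------|------------------------|
| P    | polymorphic (fused freq. configurable) | fixed fused |
| F    | fixed fused               | fixed unfused (the fixed fission) |
| Q    | fixed fused               | polymorphic |

giving *orphicus* n ∈ {41, 42}, *lurae* n ∈ {42, 43}. Under this model every
F1 combination of parental variants shows **41** visible elements (the three
heterozygous pairs each collapse into a single multivalent-or-bivalent
element), whereas first-generation backcrosses to unfused *lurae* can show
41, 42 or **43** — so a 43-element specimen carrying an *orphicus*-lineage
haplogroup is explicable as a backcross but never as an F1.

The caption-level description of F1 variants admits quadrivalents only when
fusions share arms between taxa (chained fusions). The engine supports
chained configurations (and they are exercised in tests), but no chained
default is asserted because parental counts alone cannot pin one down.

### Consistency classification

`classify_karyotype_consistency(observed_n, haplogroup)` tests the observed
count against the achievable sets of the haplogroup's own pure scenario and
of the hybrid scenarios, resolving ties to the minimal generation (pure < F1
< BC1) and reporting all matches. Because mitochondria are maternal and every
discordant specimen in this system carries the *orphicus*-lineage haplogroup,
hybridization is modelled as directional (A-lineage mothers): hybrid
scenarios are only offered to A-lineage haplogroups. A *lurae*-haplogroup
specimen with n = 41 is therefore *inconsistent* rather than F1-consistent.
The direction is configurable (`maternal_hybrid_taxon`).

Two frequency regimes are used deliberately:

* `build_default_two_species_model()` defaults to fused-allele frequencies
  0.5/0.5 — the species-wide model in which both polymorphisms segregate and
  the pure supports are {41, 42} and {42, 43}.
* The generator and pipeline default to **0.0 / 0.5** — the sampled study
  population, where every pure A-lineage specimen shows n = 42 (the
  polymorphism being effectively fixed out locally) and the B taxon shows
  both homozygotes and the heterozygote. Under this regime a 41-count
  A-lineage specimen classifies F1-consistent instead of disappearing into
  the pure set.

## COI haplotypes

Site statistics, Hamming distances, haplotype collapsing and the
mutational-step network operate on an aligned FASTA. Policy decisions:

* **Ambiguity**: positions with `N`/gap in either member of a pair are
  excluded pairwise — barcodes trimmed to different lengths must not accrue
  steps. A column with fewer than two unambiguous states counts as constant.
* **Collapsing** under wildcards is not transitive; sequences merge greedily
  into the first zero-distance haplotype in input order and representatives
  are completed from members' unambiguous states.
* **Network**: minimum-spanning-network construction — pairs connected in
  order of increasing steps, with all tied alternative connections at a level
  retained (reticulations), and inferred "missing" intermediates inserted on
  multi-step edges in the expanded view. The statistical-parsimony 95%
  connection limit is not computed; the limit is a user-set integer
  (default ∞), which is what the downstream haplogroup step actually needs.
* **Haplogroups** are components after deleting edges longer than
  `max_within_steps` (default 5), labelled in decreasing total frequency.

The published alignment's exact counts (137 variable / 112
parsimony-informative sites over 60 sequences) depend on context sequences
that are not enumerated publicly; the suite therefore checks the statistics
structurally (against a brute-force column tally, at study scale 60 × 657)
rather than numerically.

## Wing-colour morphometrics

Three discs per wing are averaged to one RGB profile per specimen; HSV is
derived from the mean RGB by the standard hexcone formula (H in degrees,
grey → H = 0). The headline distance is Euclidean in RGB (HSV selectable);
the capture pipeline (lighting geometry, 20° tilt, disc blurring) is
upstream of this package.

* **NMDS**: non-metric MDS (isotonic regression of embedded on observed
  distances) via scikit-learn, one start from a classical (Torgerson) MDS
  configuration plus seeded random restarts (default 8), best Kruskal
  stress-1 kept, coordinates centred.
* **PERMANOVA** is implemented directly: with N points in k groups,
  SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g,
  pseudo-F = (SS_between/(k−1))/(SS_within/(N−k)), and the p-value is the
  add-one permutation estimator over label permutations (default 9999, seed
  required). On univariate Euclidean data the statistic reduces to the
  classical one-way ANOVA F (tested to 1e-9, and against scikit-bio).
  One factor at a time; species identity and substrate are tested in
  separate calls.

## The synthetic study generator

`SimulationConfig` defaults *are* the study conditions and are not tuned:

* **Scale**: 12 + 13 pure specimens + 2 hybrids = 27 colour-measured
  specimens; five haplogroups with one context sequence for each non-focal
  group.
* **Sequences**: a random 657-nt ancestor; each haplogroup centroid mutated
  at 8–16 disjoint sites; specimens receive Poisson(1) private mutations at
  fresh sites (infinite-sites approximation — no back-mutation; divergences
  are tens of steps over 657 sites). Disjoint site sets make between-group
  distances additive and ≥ 3× the within-group scatter, the regime in which
  exact haplogroup recovery is claimed.
* **Karyotypes**: Hardy–Weinberg draws within taxa (no mating-structure
  information exists to justify anything richer); hybrids drawn per the
  generation mix (default 100% BC1, matching the observed n = 43 animals);
  the reported count is the pairing engine's visible-element count.
* **Colour**: group means (120, 100, 84) for the paler reflective taxon and
  (96, 82, 70) for the dark ophiolite taxon, i.i.d. Gaussian channel noise
  SD 10, clamped to 0–255; hybrids at the parental midpoint. The planted
  species effect is ≈ 2.8 within-group SDs between centroids, at which
  PERMANOVA power at n = 27, α = 0.05 exceeds 0.8 (measured in the suite).
* **Geography**: pure specimens sit on their substrate-typical localities
  except a contact-zone fraction (default 0.25) sampled at a shared
  mixed-substrate locality; all hybrids are at the contact zone.

What the generator does *not* emulate: sequencing error, alignment error,
back-mutation/homoplasy, within-taxon population structure, unbalanced
(aneuploid) meiotic products, colour covariance between channels, and
observation noise on chromosome counts (e.g. fragmentation artefacts).
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to those real-data
complications.

## Integrative classification

Per specimen: concordant haplogroup × karyotype → species call; discordance
explainable by a hybrid scenario → putative hybrid with the minimal
generation class; a count no scenario explains → unresolved. Colour
intermediacy (nearer the inter-centroid midpoint than either centroid in
RGB) is recorded as supporting evidence and never suffices for a hybrid call,
because the species' colour ellipses overlap. Contact zones are localities
where haplogroups of both taxa co-occur; discordant specimens outside any
contact zone keep their hybrid call but are flagged `dispersive`. Specimens
lacking a karyotype are called from the haplogroup alone (unambiguous in
this system) rather than left unresolved.

## Numerical and degenerate-input choices

* Gamete and cross probabilities use exact `Fraction` arithmetic; sums are
  exactly 1.
* Exact covers are enumerated by brute-force subset filtering per element —
  elements in realistic karyotypes have ≤ 4–6 members, so this is never a
  bottleneck.
* A single-sequence alignment refuses site statistics; an all-zero distance
  matrix refuses NMDS; empty groups and < 99 permutations refuse PERMANOVA.
* The n = 44 MI plate reported alongside n = 43 in one dispersive specimen is
  treated as intraindividual observational noise (fragmentation), not
  modelled.
* Determinism: every stochastic step takes a seed; the pipeline report and
  the generator's files are byte-identical under a fixed seed and config.

## Known limitations

* The arm universe is inferred from counts, not from chromosome-level data;
  any disjoint-arm relabeling is observationally equivalent.
* The directional-hybridization assumption is an inference from the observed
  haplogroup composition of discordant specimens, not a biological law.
* The statistical-parsimony probability limit is not computed, so component
  structure at very large divergences depends on the user-set limit.
* Published PERMANOVA statistics depend on the original per-specimen
  measurement table and exact metric choices and are not reproduced here;
  the implementation is validated against closed-form ANOVA and an
  independent library instead.
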