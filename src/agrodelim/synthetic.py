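"""Synthetic study generator with planted truth.

Emulates the structure of an integrative delimitation study of a two-species
butterfly contact zone: aligned COI barcodes falling into divergent
haplogroups, MI chromosome counts drawn from fusion-polymorphism frequencies
under the meiotic pairing model, wing-colour disc measurements with
species-specific means, and a locality table with a contact zone where both
focal haplogroups co-occur.  Every planted label is recorded in a truth
bundle so downstream calls (haplogroup recovery, hybrid classification,
PERMANOVA power) can be scored exactly.

Mutations are placed uniformly at random without back-mutation (an
infinite-sites approximation, adequate for divergences of tens of steps over
a ~657-site barcode).  Genotypes within a taxon follow Hardy-Weinberg
proportions; hybrid colour means sit at the midpoint of the parental means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import AlignedSequenceSet
from .karyotype import (
    DiploidGenotype,
    HaploidKaryotype,
    SpeciesKaryotypeSpec,
    build_default_two_species_model,
    gamete_distribution,
    pair_meiosis,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_haplotypes",
    "simulate_karyotype_observations",
    "simulate_colours",
    "simulate_specimen_table",
    "write_study",
]

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the real study's scale: two focal taxa of about a dozen
    specimens each plus a few backcross hybrids, five haplogroups whose
    centroids sit 8-16 steps from the ancestor (pairwise divergence well
    above 3x the within-group scatter of about one step), fused-allele
    frequencies of 0.0 (*orphicus*, fixed at n = 42 in the sampled
    population) and 0.5 (*lurae*, both homozygotes observed), and dark-vs-pale brown wing
    colour means separated by roughly three within-group standard deviations.
    """

    seed: int = 0
    barcode_length: int = 657
    #: specimens per focal taxon (plus hybrids below)
    n_orphicus: int = 12
    n_lurae: int = 13
    n_hybrids: int = 2
    #: proportions of hybrid generations; the study's n=43 hybrids are BC1
    hybrid_generation_mix: dict = field(
        default_factory=lambda: {"F1": 0.0, "BC1": 1.0})
    #: mutational steps from the ancestral sequence to each haplogroup centroid
    haplogroup_steps: dict = field(default_factory=lambda: {
        "orph1": 8, "orph2": 10, "aroa1": 12, "aroa2": 14, "aroa3": 16})
    #: mean within-group mutations per specimen (Poisson)
    within_group_rate: float = 1.0
    #: haplogroups carried by the two focal taxa and by hybrids (maternal line)
    focal_haplogroups: dict = field(default_factory=lambda: {
        "orphicus": "orph2", "lurae": "aroa3", "hybrid": "orph2"})
    #: fused-allele frequency of each taxon's polymorphic fusion
    fused_freq_orphicus: float = 0.0
    fused_freq_lurae: float = 0.5
    #: wing-colour group means (RGB 0-255) and per-channel noise SD
    colour_means: dict = field(default_factory=lambda: {
        "orphicus": (120.0, 100.0, 84.0), "lurae": (96.0, 82.0, 70.0)})
    colour_sd: float = 10.0
    discs_per_specimen: int = 3
    #: fraction of each focal taxon sampled in the shared contact-zone locality
    contact_zone_fraction: float = 0.25

    def validate(self) -> None:
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if sum(self.hybrid_generation_mix.values()) and abs(
                sum(self.hybrid_generation_mix.values()) - 1) > 1e-9:
            raise ValueError("hybrid generation proportions must sum to 1")
        if sum(self.haplogroup_steps.values()) > self.barcode_length:
            raise ValueError("haplogroup divergence exceeds sequence length")


@dataclass
class SimulatedStudy:
    """Outputs plus the planted truth bundle."""

    sequences: AlignedSequenceSet
    specimen_table: pd.DataFrame
    colour_measurements: pd.DataFrame
    truth: dict


def _specimen_ids(config: SimulationConfig) -> dict:
    ids = {}
    ids["orphicus"] = [f"O{i + 1:03d}" for i in range(config.n_orphicus)]
    ids["lurae"] = [f"L{i + 1:03d}" for i in range(config.n_lurae)]
    ids["hybrid"] = [f"X{i + 1:03d}" for i in range(config.n_hybrids)]
    return ids


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for site in sites:
        current = out[site]
        options = NUCLEOTIDES[NUCLEOTIDES != current]
        out[site] = rng.choice(options)
    return out


def simulate_haplotypes(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[AlignedSequenceSet, pd.DataFrame]:
    """Simulate aligned barcodes for all specimens; returns (alignment, truth).

    An ancestral sequence is mutated at disjoint site sets to form each
    haplogroup centroid (so between-centroid distance is the sum of their
    step counts), then each specimen receives Poisson-distributed private
    mutations at so-far-untouched sites.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    length = config.barcode_length
    ancestor = rng.choice(NUCLEOTIDES, size=length)

    free_sites = rng.permutation(length)
    cursor = 0
    centroids = {}
    for group, steps in config.haplogroup_steps.items():
        sites = free_sites[cursor:cursor + steps]
        cursor += steps
        centroids[group] = _mutate(ancestor, sites, rng)

    ids_by_taxon = _specimen_ids(config)
    rows, ids, seqs = [], [], []
    for taxon, sids in ids_by_taxon.items():
        group = config.focal_haplogroups[taxon]
        for sid in sids:
            k = int(rng.poisson(config.within_group_rate))
            k = min(k, length - cursor)
            sites = free_sites[cursor:cursor + k]
            cursor += k
            seq = _mutate(centroids[group], sites, rng)
            ids.append(sid)
            seqs.append("".join(seq))
            rows.append({"specimen_id": sid, "taxon": taxon,
                         "haplogroup": group, "private_steps": k})
    # context specimens for the remaining haplogroups (one each) so the
    # network spans all planted groups
    for group in config.haplogroup_steps:
        if group in {config.focal_haplogroups[t] for t in ids_by_taxon}:
            continue
        sid = f"ctx_{group}"
        ids.append(sid)
        seqs.append("".join(centroids[group]))
        rows.append({"specimen_id": sid, "taxon": f"context_{group}",
                     "haplogroup": group, "private_steps": 0})
    alignment = AlignedSequenceSet(ids=tuple(ids), seqs=tuple(seqs))
    return alignment, pd.DataFrame(rows)


def _draw_haplotype(spec: SpeciesKaryotypeSpec, rng: np.random.Generator
                    ) -> HaploidKaryotype:
    states = {f: bool(rng.random() < q)
              for f, q in spec.polymorphic_fusions.items()}
    return spec.haplotype(states)


def _draw_gamete(genotype: DiploidGenotype, rng: np.random.Generator
                 ) -> HaploidKaryotype:
    dist = gamete_distribution(pair_meiosis(genotype))
    gametes = list(dist)
    probs = np.array([float(p) for p in dist.values()])
    return gametes[rng.choice(len(gametes), p=probs / probs.sum())]


def simulate_karyotype_observations(
    config: SimulationConfig,
    model: tuple[SpeciesKaryotypeSpec, SpeciesKaryotypeSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw genotypes per specimen and report MI visible-element counts.

    Pure-taxon genotypes are Hardy-Weinberg draws from the taxon's
    fused-allele frequencies; hybrids are F1 (one gamete from each species)
    or BC1 (balanced F1 gamete x *lurae* gamete) per the generation mix.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if model is None:
        model = build_default_two_species_model(
            config.fused_freq_orphicus, config.fused_freq_lurae)[:2]
    orphicus, lurae = model

    def pure_genotype(spec):
        return DiploidGenotype(_draw_haplotype(spec, rng), _draw_haplotype(spec, rng))

    gen_labels = list(config.hybrid_generation_mix)
    gen_probs = np.array([config.hybrid_generation_mix[g] for g in gen_labels],
                         dtype=float)

    rows = []
    for taxon, sids in _specimen_ids(config).items():
        for sid in sids:
            if taxon == "orphicus":
                genotype, generation = pure_genotype(orphicus), "pure"
            elif taxon == "lurae":
                genotype, generation = pure_genotype(lurae), "pure"
            else:
                generation = gen_labels[rng.choice(len(gen_labels),
                                                   p=gen_probs / gen_probs.sum())]
                f1 = DiploidGenotype(_draw_haplotype(orphicus, rng),
                                     _draw_haplotype(lurae, rng))
                if generation == "F1":
                    genotype = f1
                else:  # BC1: balanced F1 gamete against a lurae gamete
                    genotype = DiploidGenotype(_draw_gamete(f1, rng),
                                               _draw_haplotype(lurae, rng))
            rows.append({
                "specimen_id": sid,
                "taxon": taxon,
                "generation": generation,
                "visible_count": pair_meiosis(genotype).visible_count,
            })
    return pd.DataFrame(rows)


def simulate_colours(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Disc-level RGB measurements: taxon mean + Gaussian noise, clamped 0-255.

    Hybrid specimens draw from the midpoint of the two parental means.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    means = dict(config.colour_means)
    means["hybrid"] = tuple(
        (a + b) / 2 for a, b in zip(means["orphicus"], means["lurae"]))
    rows = []
    for taxon, sids in _specimen_ids(config).items():
        mu = np.array(means[taxon])
        for sid in sids:
            for disc in range(1, config.discs_per_specimen + 1):
                rgb = np.clip(rng.normal(mu, config.colour_sd), 0, 255)
                rows.append({"specimen_id": sid, "disc": disc,
                             "R": float(rgb[0]), "G": float(rgb[1]),
                             "B": float(rgb[2])})
    return pd.DataFrame(rows)


def simulate_specimen_table(config: SimulationConfig) -> SimulatedStudy:
    """Run all component simulators under one seed and join the study table.

    Localities: *orphicus* specimens sit on karst sites, *lurae* on ophiolite
    sites, except that a ``contact_zone_fraction`` of each taxon — and every
    hybrid — is sampled at the shared mixed-substrate contact locality.
    """
    config.validate()
    alignment, hap_truth = simulate_haplotypes(config)
    karyo = simulate_karyotype_observations(config)
    colours = simulate_colours(config)
    rng = np.random.default_rng(config.seed + 3)

    ids_by_taxon = _specimen_ids(config)
    locality, substrate = {}, {}
    for taxon, sids in ids_by_taxon.items():
        for sid in sids:
            if taxon == "hybrid":
                locality[sid], substrate[sid] = "contact_zone", "mixed"
            elif rng.random() < config.contact_zone_fraction:
                locality[sid], substrate[sid] = "contact_zone", "mixed"
            elif taxon == "orphicus":
                locality[sid], substrate[sid] = "karst_valley", "karst"
            else:
                locality[sid], substrate[sid] = "ophiolite_ridge", "ophiolite"

    karyo_map = karyo.set_index("specimen_id")
    rows = []
    for taxon, sids in ids_by_taxon.items():
        group = config.focal_haplogroups[taxon]
        for sid in sids:
            rows.append({
                "specimen_id": sid,
                "sex": "M" if rng.random() < 0.8 else "F",
                "locality": locality[sid],
                "substrate": substrate[sid],
                "haplogroup": group,
                "visible_count": int(karyo_map.loc[sid, "visible_count"]),
                "taxon_truth": taxon,
                "generation_truth": karyo_map.loc[sid, "generation"],
            })
    table = pd.DataFrame(rows)
    truth = {
        "config": dataclasses.asdict(config),
        "taxon": {r["specimen_id"]: r["taxon_truth"] for r in rows},
        "generation": {r["specimen_id"]: r["generation_truth"] for r in rows},
        "haplogroup": dict(zip(hap_truth["specimen_id"], hap_truth["haplogroup"])),
        "contact_zone_localities": ["contact_zone"] if any(
            v == "contact_zone" for v in locality.values()) else [],
    }
    return SimulatedStudy(sequences=alignment, specimen_table=table,
                          colour_measurements=colours, truth=truth)


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write FASTA, specimen TSV, disc CSV and truth JSON; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "barcodes.fasta"
    with open(fasta, "w") as fh:
        for sid, seq in zip(study.sequences.ids, study.sequences.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    specimen_tsv = outdir / "specimens.tsv"
    study.specimen_table.drop(
        columns=["taxon_truth", "generation_truth"]
    ).to_csv(specimen_tsv, sep="\t", index=False)
    colour_csv = outdir / "colour_discs.csv"
    study.colour_measurements.to_csv(colour_csv, index=False)
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
    return {"fasta": str(fasta), "specimens": str(specimen_tsv),
            "colours": str(colour_csv), "truth": str(truth_json)}
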