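"""COI barcode haplotype analysis: site statistics, haplotype collapsing,
mutational-step networks and haplogroup assignment.

Works on a pre-aligned set of mitochondrial barcode sequences (typically the
~658-bp COI fragment used for Lepidoptera barcoding).  Positions holding an
``N`` or a gap in either sequence of a pair are excluded pairwise from
distances and from per-site classification, so that barcodes of slightly
different length (end-trimmed) do not accrue spurious mutational steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AlignedSequenceSet",
    "SiteStats",
    "Haplotype",
    "HaplotypeNetwork",
    "read_aligned_fasta",
    "load_holotype_barcode",
    "site_statistics",
    "pairwise_difference_matrix",
    "collapse_haplotypes",
    "build_parsimony_network",
    "assign_haplogroups",
    "check_reading_frame",
]

VALID_STATES = frozenset("ACGT")
AMBIGUOUS = frozenset("N-")


@dataclass(frozen=True)
class AlignedSequenceSet:
    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("empty sequence set")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence IDs")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            offenders = [i for i, s in zip(self.ids, self.seqs)
                         if len(s) != len(self.seqs[0])]
            raise ValueError(f"ragged alignment; offending IDs: {offenders}")
        bad = set("".join(self.seqs)) - VALID_STATES - AMBIGUOUS
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def alignment_length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def to_matrix(self) -> np.ndarray:
        """(n_seqs, n_sites) array of single characters."""
        return np.array([list(s) for s in self.seqs])


@dataclass(frozen=True)
class SiteStats:
    total_sites: int
    constant_sites: int
    variable_sites: int
    parsimony_informative_sites: int


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str
    members: tuple[str, ...]

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    """Mutational-step network over collapsed haplotypes.

    ``graph`` holds one node per haplotype with edges weighted by mutational
    steps (ties retained, minimum-spanning-network style).  ``expanded()``
    inserts the inferred "missing" intermediate haplotypes so that every edge
    is a single step.  ``haplogroups`` is filled by :func:`assign_haplogroups`.
    """

    graph: nx.Graph
    haplotypes: tuple[Haplotype, ...]
    connection_limit: float
    haplogroups: dict | None = None

    def expanded(self) -> nx.Graph:
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, **data)
        counter = 0
        for u, v, data in self.graph.edges(data=True):
            steps = data["steps"]
            prev = u
            for k in range(1, steps):
                counter += 1
                mid = f"missing_{counter}"
                g.add_node(mid, missing=True, frequency=0)
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, v, steps=1)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [{"from": u, "to": v, "steps": d["steps"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["from", "to", "steps"])


def read_aligned_fasta(path) -> AlignedSequenceSet:
    """Read an aligned FASTA file; sequences are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return AlignedSequenceSet(
        ids=tuple(r.id for r in records),
        seqs=tuple(str(r.seq).upper() for r in records),
    )


def load_holotype_barcode() -> AlignedSequenceSet:
    """The 657-bp COI barcode of the *P. lurae* holotype, shipped as a fixture."""
    with resources.as_file(
        resources.files("agrodelim.data") / "holotype_coi.fasta"
    ) as path:
        return read_aligned_fasta(path)


def site_statistics(seqs: AlignedSequenceSet) -> SiteStats:
    """Classify alignment columns as constant / variable / parsimony-informative.

    Ambiguous states (N, gaps) are ignored within a column; a column with
    fewer than two unambiguous states is counted as constant.  A column is
    parsimony-informative when at least two states are each carried by at
    least two sequences.
    """
    if len(seqs) < 2:
        raise ValueError("site statistics require at least two sequences")
    mat = seqs.to_matrix()
    variable = informative = 0
    for col in mat.T:
        states, counts = np.unique(col[np.isin(col, list(VALID_STATES))],
                                   return_counts=True)
        if len(states) >= 2:
            variable += 1
            if np.sum(counts >= 2) >= 2:
                informative += 1
    total = seqs.alignment_length
    return SiteStats(
        total_sites=total,
        constant_sites=total - variable,
        variable_sites=variable,
        parsimony_informative_sites=informative,
    )


def pairwise_difference_matrix(seqs: AlignedSequenceSet) -> np.ndarray:
    """Hamming distances (mutational steps) over pairwise-unambiguous sites."""
    mat = seqs.to_matrix()
    ok = np.isin(mat, list(VALID_STATES))
    n = len(seqs)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        dist[i, i + 1:] = diff.sum(axis=1)
    return dist + dist.T


def collapse_haplotypes(seqs: AlignedSequenceSet) -> list[Haplotype]:
    """Merge sequences identical over their pairwise-unambiguous positions.

    Merging with wildcards is not transitive; sequences are assigned greedily
    to the first existing haplotype at distance zero (input order), and each
    representative sequence is completed with the unambiguous states of its
    members.  Frequencies are conserved: they sum to the input count.
    """
    dist = pairwise_difference_matrix(seqs)
    reps: list[list[str]] = []  # mutable representative sequences
    rep_index: list[int] = []
    members: list[list[str]] = []
    for i, (sid, seq) in enumerate(zip(seqs.ids, seqs.seqs)):
        for h, j in enumerate(rep_index):
            if dist[i, j] == 0:
                members[h].append(sid)
                rep = reps[h]
                for k, c in enumerate(seq):
                    if rep[k] not in VALID_STATES and c in VALID_STATES:
                        rep[k] = c
                break
        else:
            reps.append(list(seq))
            rep_index.append(i)
            members.append([sid])
    return [
        Haplotype(haplotype_id=f"H{h + 1}", sequence="".join(rep),
                  members=tuple(mem))
        for h, (rep, mem) in enumerate(zip(reps, members))
    ]


def build_parsimony_network(
    haplotypes: Iterable[Haplotype],
    connection_limit: float = np.inf,
) -> HaplotypeNetwork:
    """Minimum-spanning network over haplotypes with tied links retained.

    Haplotype pairs are connected in order of increasing mutational steps; at
    each step level, every pair joining components that were distinct before
    the level is added, so alternative equal-length connections survive as
    reticulations.  Pairs farther apart than ``connection_limit`` are never
    joined; disconnected components then correspond to groups beyond the
    parsimony connection limit.
    """
    haps = list(haplotypes)
    if not haps:
        raise ValueError("no haplotypes")
    seq_set = AlignedSequenceSet(
        ids=tuple(h.haplotype_id for h in haps),
        seqs=tuple(h.sequence for h in haps),
    )
    dist = pairwise_difference_matrix(seq_set)
    g = nx.Graph()
    for h in haps:
        g.add_node(h.haplotype_id, frequency=h.frequency,
                   members=",".join(h.members), missing=False)

    n = len(haps)
    pairs: dict[int, list] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dist[i, j])
            if d <= connection_limit:
                pairs.setdefault(d, []).append((i, j))

    comp = {i: i for i in range(n)}  # union-find

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for d in sorted(pairs):
        level_edges = [
            (i, j) for i, j in pairs[d] if find(i) != find(j)
        ]
        # evaluate membership against components as of the previous level,
        # then merge, so ties at the same level all survive
        for i, j in level_edges:
            g.add_edge(haps[i].haplotype_id, haps[j].haplotype_id, steps=d)
        for i, j in level_edges:
            comp[find(i)] = find(j)

    return HaplotypeNetwork(graph=g, haplotypes=tuple(haps),
                            connection_limit=connection_limit)


def assign_haplogroups(
    network: HaplotypeNetwork, max_within_steps: int
) -> HaplotypeNetwork:
    """Partition the network into haplogroups.

    Haplogroups are the connected components left after removing every edge
    longer than ``max_within_steps``.  Labels (``HG1``, ``HG2``, ...) are
    assigned in order of decreasing total frequency (ties broken by smallest
    haplotype id) so they are stable across runs.  The returned network's
    ``haplogroups`` maps haplotype id -> label; node attributes are updated
    in place, and a specimen-level map is available via
    :meth:`specimen_haplogroups`.
    """
    pruned = nx.Graph()
    pruned.add_nodes_from(network.graph.nodes)
    for u, v, d in network.graph.edges(data=True):
        if d["steps"] <= max_within_steps:
            pruned.add_edge(u, v)
    comps = sorted(
        nx.connected_components(pruned),
        key=lambda c: (-sum(network.graph.nodes[h]["frequency"] for h in c),
                       min(c)),
    )
    labels: dict = {}
    for k, compo in enumerate(comps, start=1):
        for h in compo:
            labels[h] = f"HG{k}"
            network.graph.nodes[h]["haplogroup"] = f"HG{k}"
    network.haplogroups = labels
    return network


def specimen_haplogroups(network: HaplotypeNetwork) -> pd.DataFrame:
    """Per-specimen haplogroup table (columns: specimen_id, haplotype, haplogroup)."""
    if network.haplogroups is None:
        raise ValueError("run assign_haplogroups first")
    rows = []
    for h in network.haplotypes:
        for sid in h.members:
            rows.append({"specimen_id": sid, "haplotype": h.haplotype_id,
                         "haplogroup": network.haplogroups[h.haplotype_id]})
    return pd.DataFrame(rows)


def check_reading_frame(sequence: str, table: int = 5) -> bool:
    """True if some reading frame of the barcode translates without internal
    stop codons under the given mitochondrial code (default: invertebrate)."""
    seq = sequence.upper().replace("-", "").replace("N", "A")
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if "*" not in str(Seq(sub).translate(table=table)):
            return True
    return False
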