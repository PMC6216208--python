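"""Network-based in silico drug-repurposing screen.

The screen expands a set of disease risk genes (typically GWAS hits) by
their direct protein-protein-interaction neighbors, intersects the combined
disease gene set with the targets of approved drugs, and reports candidate
drugs grouped into families.  The count cascade it emits — seeds, first
neighbors, disease genes, drug-targeted hit genes, candidate families —
mirrors how such screens are reported.

Gene identity is the uppercase-normalized symbol string; callers supply
pre-mapped symbol tables.  All operations are deterministic: candidate
ordering is lexicographic by drug id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "GeneSet",
    "PPINetwork",
    "DrugTargetRecord",
    "DrugTargetTable",
    "DrugCandidate",
    "ScreenReport",
    "normalize_symbol",
    "first_neighbors",
    "disease_gene_set",
    "map_drug_targets",
    "group_families",
    "annotate_literature",
    "screen_report",
]

logger = logging.getLogger(__name__)

APPROVED = "approved"


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped, uppercased, non-empty."""
    s = symbol.strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase-normalized gene symbols."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(normalize_symbol(s) for s in symbols))

    def __post_init__(self) -> None:
        norm = frozenset(normalize_symbol(g) for g in self.genes)
        object.__setattr__(self, "genes", norm)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


class PPINetwork:
    """Undirected gene-symbol interaction graph.

    Self-loops and duplicate/reversed edges are normalized away on
    construction; their counts are logged and kept as attributes.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self.graph = nx.Graph()
        self.n_self_loops_dropped = 0
        self.n_duplicates_dropped = 0
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            self.n_self_loops_dropped += 1
            return
        if self.graph.has_edge(a, b):
            self.n_duplicates_dropped += 1
            return
        self.graph.add_edge(a, b)

    def add_node(self, symbol: str) -> None:
        """Register an isolated node (a gene known to the network, no edges)."""
        self.graph.add_node(normalize_symbol(symbol))

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, symbol: str) -> frozenset[str]:
        s = normalize_symbol(symbol)
        if s not in self.graph:
            return frozenset()
        return frozenset(self.graph.neighbors(s))


@dataclass(frozen=True)
class DrugTargetRecord:
    """One drug-to-target-gene assertion."""

    drug_id: str
    drug_name: str
    target_gene: str
    approval_status: str = APPROVED
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_gene", normalize_symbol(self.target_gene))
        if not self.drug_id.strip():
            raise ValueError("empty drug_id")


class DrugTargetTable:
    """Collection of drug->target records, unique on (drug_id, target_gene).

    Duplicated pairs are dropped with a logged count; a drug carrying two
    different non-null family ids is rejected.
    """

    def __init__(self, records: Iterable[DrugTargetRecord] = ()):
        self._records: list[DrugTargetRecord] = []
        self._seen: set[tuple[str, str]] = set()
        self._family_of: dict[str, str] = {}
        self.n_duplicates_dropped = 0
        for r in records:
            self.add(r)

    def add(self, record: DrugTargetRecord) -> None:
        key = (record.drug_id, record.target_gene)
        if key in self._seen:
            self.n_duplicates_dropped += 1
            logger.debug("dropping duplicate drug-target pair %s", key)
            return
        if record.family_id is not None:
            prev = self._family_of.get(record.drug_id)
            if prev is not None and prev != record.family_id:
                raise ValueError(
                    f"conflicting family ids for drug {record.drug_id!r}: "
                    f"{prev!r} vs {record.family_id!r}"
                )
            self._family_of[record.drug_id] = record.family_id
        self._seen.add(key)
        self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def records(self, status_filter: Optional[set[str]] = None) -> list[DrugTargetRecord]:
        if status_filter is None:
            return list(self._records)
        return [r for r in self._records if r.approval_status in status_filter]

    def target_genes(self, status_filter: Optional[set[str]] = None) -> frozenset[str]:
        return frozenset(r.target_gene for r in self.records(status_filter))

    def family_id(self, drug_id: str) -> Optional[str]:
        return self._family_of.get(drug_id)


@dataclass(frozen=True)
class DrugCandidate:
    """A drug passing the approval filter with >= 1 target in the disease set."""

    drug_id: str
    drug_name: str
    family_id: str
    hit_genes: tuple[str, ...]  # sorted
    provenance: tuple[str, ...]  # 'seed' | 'neighbor', aligned with hit_genes


@dataclass(frozen=True)
class ScreenReport:
    """Count cascade and candidate table of one full screen run."""

    n_seed: int
    n_neighbor: int
    n_disease_genes: int
    n_drug_target_genes: int
    n_hit_genes: int
    n_candidate_drug_families: int
    candidates: tuple[DrugCandidate, ...] = ()
    missing_seeds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_disease_genes != self.n_seed + self.n_neighbor:
            raise ValueError(
                "count identity violated: n_disease_genes != n_seed + n_neighbor "
                f"({self.n_disease_genes} != {self.n_seed} + {self.n_neighbor})"
            )
        if self.n_hit_genes > self.n_disease_genes:
            raise ValueError("n_hit_genes cannot exceed n_disease_genes")

    def counts(self) -> dict[str, int]:
        return {
            "n_seed": self.n_seed,
            "n_neighbor": self.n_neighbor,
            "n_disease_genes": self.n_disease_genes,
            "n_drug_target_genes": self.n_drug_target_genes,
            "n_hit_genes": self.n_hit_genes,
            "n_candidate_drug_families": self.n_candidate_drug_families,
        }


def first_neighbors(network: PPINetwork, seeds: GeneSet) -> GeneSet:
    """Direct PPI neighbors of the seed genes, excluding the seeds themselves.

    The exclusion makes |seeds| + |neighbors| the size of the combined
    disease gene set.  Seeds absent from the network contribute nothing and
    are logged as a warning.
    """
    if len(seeds) == 0:
        raise ValueError("seed gene set is empty")
    missing = sorted(g for g in seeds.genes if g not in network)
    if missing:
        logger.warning("%d seed gene(s) absent from the PPI network: %s",
                       len(missing), ", ".join(missing))
    out: set[str] = set()
    for g in seeds.genes:
        out |= network.neighbors(g)
    return GeneSet(f"{seeds.name}:neighbors", frozenset(out - seeds.genes))


def disease_gene_set(seeds: GeneSet, neighbors: GeneSet) -> tuple[GeneSet, dict[str, str]]:
    """Union of seeds and neighbors with per-gene provenance tags.

    Returns the combined set and a mapping gene -> 'seed' | 'neighbor'.
    Overlap between the two inputs indicates the caller bypassed
    :func:`first_neighbors` and is rejected.
    """
    overlap = seeds.genes & neighbors.genes
    if overlap:
        raise ValueError(
            f"seeds and neighbors overlap ({sorted(overlap)}); "
            "neighbors must come from first_neighbors()"
        )
    provenance = {g: "seed" for g in seeds.genes}
    provenance.update({g: "neighbor" for g in neighbors.genes})
    return GeneSet(f"{seeds.name}:disease", seeds.genes | neighbors.genes), provenance


def map_drug_targets(
    disease: GeneSet,
    drugs: DrugTargetTable,
    status_filter: set[str] = frozenset({APPROVED}),
    provenance: Optional[Mapping[str, str]] = None,
) -> tuple[GeneSet, list[DrugCandidate]]:
    """Intersect the disease gene set with targets of filtered drugs.

    Returns the hit genes (disease genes targeted by at least one drug
    passing the status filter) and the candidate drugs, each carrying
    exactly its in-set targets.  Candidates are ordered by drug id.
    """
    if len(disease) == 0:
        raise ValueError("disease gene set is empty")
    status_filter = set(status_filter)
    if len(drugs) == 0:
        logger.warning("drug-target table is empty; screen yields no candidates")
    by_drug: dict[str, list[DrugTargetRecord]] = {}
    for r in drugs.records(status_filter):
        by_drug.setdefault(r.drug_id, []).append(r)
    hit: set[str] = set()
    candidates: list[DrugCandidate] = []
    for drug_id in sorted(by_drug):
        recs = by_drug[drug_id]
        in_set = sorted({r.target_gene for r in recs} & disease.genes)
        if not in_set:
            continue
        hit.update(in_set)
        fam = drugs.family_id(drug_id) or drug_id
        prov = tuple((provenance or {}).get(g, "unknown") for g in in_set)
        candidates.append(
            DrugCandidate(
                drug_id=drug_id,
                drug_name=recs[0].drug_name,
                family_id=fam,
                hit_genes=tuple(in_set),
                provenance=prov,
            )
        )
    return GeneSet(f"{disease.name}:hits", frozenset(hit)), candidates


def group_families(
    candidates: Sequence[DrugCandidate],
    family_map: Optional[Mapping[str, str]] = None,
) -> dict[str, list[DrugCandidate]]:
    """Group candidate drugs into families.

    A family id comes from the record (via the drug-target table), or from
    ``family_map`` (drug_id -> family_id); a drug with neither is its own
    family.  A conflict between the two sources is an error.  Returned dict
    is ordered by family id.
    """
    groups: dict[str, list[DrugCandidate]] = {}
    for c in candidates:
        fam = c.family_id
        if family_map and c.drug_id in family_map:
            mapped = family_map[c.drug_id]
            if fam != c.drug_id and fam != mapped:
                raise ValueError(
                    f"conflicting family for drug {c.drug_id!r}: record says {fam!r}, "
                    f"map says {mapped!r}"
                )
            fam = mapped
        groups.setdefault(fam, []).append(c)
    return {k: groups[k] for k in sorted(groups)}


def annotate_literature(
    families: Mapping[str, Sequence[DrugCandidate]] | Sequence[DrugCandidate],
    reported: Iterable[str],
) -> tuple[int, float]:
    """Count candidate families already reported in the literature.

    ``reported`` lists drug or family ids with prior evidence (an input
    curated outside this package).  Returns (n_reported, fraction of
    families).  A family counts if its id or any member drug id is listed.
    """
    if not isinstance(families, Mapping):
        families = group_families(families)
    n_fam = len(families)
    if n_fam == 0:
        raise ValueError("no candidate families: fraction undefined")
    reported_set = set(reported)
    n_hit = sum(
        1
        for fam, members in families.items()
        if fam in reported_set or any(c.drug_id in reported_set for c in members)
    )
    return n_hit, n_hit / n_fam


def screen_report(
    seeds: GeneSet,
    network: PPINetwork,
    drugs: DrugTargetTable,
    status_filter: set[str] = frozenset({APPROVED}),
    family_map: Optional[Mapping[str, str]] = None,
) -> ScreenReport:
    """Run the full screening cascade and assemble the report.

    Seeds are expanded by direct PPI neighbors, combined into the disease
    gene set, intersected with filtered drug targets, and the candidates
    grouped into families.  Deterministic: identical inputs yield identical
    reports.
    """
    neighbors = first_neighbors(network, seeds)
    disease, provenance = disease_gene_set(seeds, neighbors)
    hit_genes, candidates = map_drug_targets(disease, drugs, status_filter, provenance)
    if family_map:
        relabeled = []
        for c in candidates:
            fam = c.family_id
            if c.drug_id in family_map:
                if fam != c.drug_id and fam != family_map[c.drug_id]:
                    raise ValueError(
                        f"conflicting family for drug {c.drug_id!r}: record says {fam!r}, "
                        f"map says {family_map[c.drug_id]!r}"
                    )
                fam = family_map[c.drug_id]
            relabeled.append(
                DrugCandidate(c.drug_id, c.drug_name, fam, c.hit_genes, c.provenance)
            )
        candidates = relabeled
    families = group_families(candidates)
    missing = tuple(sorted(g for g in seeds.genes if g not in network))
    return ScreenReport(
        n_seed=len(seeds),
        n_neighbor=len(neighbors),
        n_disease_genes=len(seeds) + len(neighbors),
        n_drug_target_genes=len(drugs.target_genes(set(status_filter))),
        n_hit_genes=len(hit_genes),
        n_candidate_drug_families=len(families),
        candidates=tuple(candidates),
        missing_seeds=missing,
    )
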