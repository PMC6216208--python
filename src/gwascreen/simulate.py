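"""Synthetic case-control genotype data and planted screening instances.

Two generators make every pipeline stage testable without external data:

* ``simulate_genotype_counts`` draws case/control genotype-count triples
  under a multiplicative (per-allele) odds model: controls follow
  Hardy-Weinberg proportions at the population minor allele frequency,
  and case genotype probabilities are the control proportions tilted by
  OR^dose and renormalized.  Under this model the case minor-allele
  frequency has the closed form p*OR / (1 - p + p*OR).

* ``make_planted_screen`` builds a random PPI network, seed list and
  drug-target table whose screening cascade counts are known exactly by
  construction, providing a planted-truth oracle for the screen.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .assoc import GenotypeCounts
from .screen import (
    APPROVED,
    DrugTargetRecord,
    DrugTargetTable,
    GeneSet,
    PPINetwork,
    ScreenReport,
    screen_report,
)

__all__ = [
    "DiseaseModel",
    "PlantedScreenInstance",
    "simulate_genotype_counts",
    "case_genotype_probs",
    "expected_case_maf",
    "type1_error",
    "power_curve",
    "make_planted_screen",
]


@dataclass(frozen=True)
class DiseaseModel:
    """Design of one simulated case-control SNP study.

    ``maf_population`` is the control (population) minor allele frequency;
    ``or_per_allele`` the multiplicative odds ratio per copy of the minor
    allele (1.0 = null).
    """

    maf_population: float
    or_per_allele: float
    n_case: int
    n_control: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_population <= 0.5):
            raise ValueError(f"maf_population must be in (0, 0.5], got {self.maf_population}")
        if not (self.or_per_allele > 0 and math.isfinite(self.or_per_allele)):
            raise ValueError(f"or_per_allele must be positive and finite, got {self.or_per_allele}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be positive")


def _hwe_probs(maf: float) -> np.ndarray:
    p = maf
    q = 1.0 - p
    return np.array([p * p, 2 * p * q, q * q])  # (hom-minor, het, hom-major)


def case_genotype_probs(maf: float, or_per_allele: float) -> np.ndarray:
    """Case genotype probabilities: HWE proportions tilted by OR^dose."""
    base = _hwe_probs(maf)
    tilt = np.array([or_per_allele**2, or_per_allele, 1.0])
    w = base * tilt
    return w / w.sum()


def expected_case_maf(maf: float, or_per_allele: float) -> float:
    """Closed-form case minor-allele frequency under the per-allele odds model."""
    return maf * or_per_allele / (1 - maf + maf * or_per_allele)


def simulate_genotype_counts(
    model: DiseaseModel,
    snp_id: str = "sim1",
    chrom: str = "1",
    pos: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeCounts:
    """Draw one SNP's case/control genotype-count triples under the model."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    control = rng.multinomial(model.n_control, _hwe_probs(model.maf_population))
    case = rng.multinomial(
        model.n_case, case_genotype_probs(model.maf_population, model.or_per_allele)
    )
    return GenotypeCounts(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        minor_allele="A",
        major_allele="G",
        case_counts=tuple(int(x) for x in case),
        control_counts=tuple(int(x) for x in control),
    )


def _catt_pvals_vectorized(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Trend-test p-values for many 2x3 tables at once (weights 0,1,2).

    ``cases`` and ``controls`` are (n_sims, 3) count arrays ordered
    (hom-minor, het, hom-major).  Tables with zero trend variance get p = 1,
    matching :func:`gwascreen.assoc.catt_test`.
    """
    w = np.array([0.0, 1.0, 2.0])
    r = cases.sum(axis=1)
    s = controls.sum(axis=1)
    n = r + s
    col = cases + controls
    u = (s * (cases @ w) - r * (controls @ w)) / n
    var_u = (r * s / n**3) * (n * (col @ w**2) - (col @ w) ** 2)
    pvals = np.ones_like(u)
    ok = var_u > 0
    chi2 = np.zeros_like(u)
    chi2[ok] = u[ok] ** 2 / var_u[ok]
    pvals[ok] = stats.chi2.sf(chi2[ok], 1)
    return pvals


def _rejection_rate(model: DiseaseModel, n_sims: int, alpha: float,
                    rng: np.random.Generator) -> float:
    controls = rng.multinomial(model.n_control, _hwe_probs(model.maf_population), size=n_sims)
    cases = rng.multinomial(
        model.n_case,
        case_genotype_probs(model.maf_population, model.or_per_allele),
        size=n_sims,
    )
    pvals = _catt_pvals_vectorized(cases.astype(float), controls.astype(float))
    return float(np.mean(pvals < alpha))


def type1_error(model: DiseaseModel, n_sims: int = 10_000, alpha: float = 0.05) -> float:
    """Empirical type-I error of the trend test under the null (OR forced to 1)."""
    if n_sims < 100:
        raise ValueError(f"n_sims must be >= 100, got {n_sims}")
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    null_model = replace(model, or_per_allele=1.0)
    if alpha == 0:
        return 0.0
    if alpha == 1:
        return 1.0
    rng = np.random.default_rng(null_model.seed)
    return _rejection_rate(null_model, n_sims, alpha, rng)


def power_curve(
    model: DiseaseModel,
    or_grid: Sequence[float],
    n_sims: int = 2_000,
    alpha: float = 0.05,
) -> list[dict[str, float]]:
    """Trend-test rejection rate at each odds ratio on the grid.

    Rates are monotone non-decreasing in the odds ratio up to Monte-Carlo
    error.  Each grid point reuses the model's sample sizes and MAF; the
    random stream is seeded once so the whole curve is reproducible.
    """
    if len(or_grid) == 0:
        raise ValueError("or_grid is empty")
    rng = np.random.default_rng(model.seed)
    rows = []
    for orr in or_grid:
        m = replace(model, or_per_allele=float(orr))
        rows.append({"or_per_allele": float(orr), "alpha": alpha, "n_sims": n_sims,
                     "rejection_rate": _rejection_rate(m, n_sims, alpha, rng)})
    return rows


@dataclass(frozen=True)
class PlantedScreenInstance:
    """A screening problem whose cascade counts are known by construction."""

    network: PPINetwork
    seeds: GeneSet
    drugs: DrugTargetTable
    truth: ScreenReport

    def run(self) -> ScreenReport:
        return screen_report(self.seeds, self.network, self.drugs)


def make_planted_screen(
    n_genes: int,
    n_edges: int,
    n_seeds: int,
    n_neighbors_planted: int,
    n_drugs: int,
    n_hits_planted: int,
    seed: int = 0,
    n_families: Optional[int] = None,
) -> PlantedScreenInstance:
    """Build a random screening instance with exact planted cascade counts.

    Gene universe: ``n_seeds`` seed genes, ``n_neighbors_planted`` genes
    wired to at least one seed, and background genes up to ``n_genes``.
    Background edges (Erdos-Renyi style, ``n_edges`` of them) are drawn only
    from pairs that cannot create additional seed neighbors.  ``n_drugs``
    approved drugs are spread over ``n_families`` families (default: one
    family per drug) and target exactly ``n_hits_planted`` disease genes;
    decoy drugs (approved ones targeting background genes, and unapproved
    ones targeting disease genes) are added and must not affect any count.

    The ``truth`` report is populated from the construction, never by
    running the screen.
    """
    if n_families is None:
        n_families = n_drugs
    if n_seeds < 1:
        raise ValueError("need at least one seed gene")
    if n_genes < n_seeds + n_neighbors_planted:
        raise ValueError(
            f"n_genes={n_genes} cannot hold {n_seeds} seeds + "
            f"{n_neighbors_planted} planted neighbors"
        )
    if n_hits_planted > n_seeds + n_neighbors_planted:
        raise ValueError("cannot plant more hit genes than disease genes")
    if n_hits_planted > 0 and n_drugs < 1:
        raise ValueError("planting hit genes requires at least one drug")
    if not 0 <= n_families <= n_drugs:
        raise ValueError(f"n_families must be in [0, n_drugs], got {n_families}")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    seeds = genes[:n_seeds]
    neighbors = genes[n_seeds : n_seeds + n_neighbors_planted]
    background = genes[n_seeds + n_neighbors_planted :]

    net = PPINetwork()
    for s in seeds:
        net.add_node(s)
    # wire every planted neighbor to >= 1 random seed
    for g in neighbors:
        net.add_edge(g, seeds[int(rng.integers(n_seeds))])

    # background edges among pairs that cannot enlarge the neighbor set:
    # seed-seed, seed-neighbor, neighbor-neighbor, neighbor-background,
    # background-background.  Forbidden: seed-background.
    non_background = seeds + neighbors
    attempts = 0
    added = 0
    max_attempts = 20 * n_edges + 100
    while added < n_edges and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(n_genes, size=2)
        a, b = genes[int(i)], genes[int(j)]
        if a == b:
            continue
        a_seed = int(i) < n_seeds
        b_seed = int(j) < n_seeds
        a_bg = int(i) >= n_seeds + n_neighbors_planted
        b_bg = int(j) >= n_seeds + n_neighbors_planted
        if (a_seed and b_bg) or (b_seed and a_bg):
            continue
        if net.graph.has_edge(a, b):
            continue
        net.add_edge(a, b)
        added += 1

    disease = non_background
    hit_genes = list(rng.choice(np.array(disease), size=n_hits_planted, replace=False)) \
        if n_hits_planted else []

    records: list[DrugTargetRecord] = []
    n_cand_families = 0
    if n_hits_planted > 0:
        n_families = max(1, n_families)
        n_cand_families = n_families
        # each drug gets a family (surjective onto the n_families families)
        fam_of_drug = [f"F{k:04d}" for k in range(n_families)] + [
            f"F{int(rng.integers(n_families)):04d}" for _ in range(n_drugs - n_families)
        ]
        # each hit gene is covered by >= 1 drug; each drug targets >= 1 hit gene
        for k, g in enumerate(hit_genes):
            d = k % n_drugs
            records.append(
                DrugTargetRecord(f"D{d:04d}", f"drug{d}", g, APPROVED, fam_of_drug[d])
            )
        for d in range(n_drugs):
            g = hit_genes[int(rng.integers(n_hits_planted))]
            records.append(
                DrugTargetRecord(f"D{d:04d}", f"drug{d}", g, APPROVED, fam_of_drug[d])
            )

    # decoys: approved drugs on background genes; unapproved drugs on disease genes
    n_decoys = min(10, len(background))
    for k in range(n_decoys):
        records.append(
            DrugTargetRecord(f"X{k:04d}", f"decoy{k}", background[k], APPROVED, None)
        )
    for k in range(min(5, len(disease))):
        records.append(
            DrugTargetRecord(f"U{k:04d}", f"unapproved{k}", disease[k], "investigational", None)
        )
    drugs = DrugTargetTable(records)

    approved_targets = {r.target_gene for r in records if r.approval_status == APPROVED}
    truth = ScreenReport(
        n_seed=n_seeds,
        n_neighbor=n_neighbors_planted,
        n_disease_genes=n_seeds + n_neighbors_planted,
        n_drug_target_genes=len(approved_targets),
        n_hit_genes=n_hits_planted,
        n_candidate_drug_families=n_cand_families,
    )
    return PlantedScreenInstance(
        network=net,
        seeds=GeneSet.from_symbols("planted-seeds", seeds),
        drugs=drugs,
        truth=truth,
    )
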