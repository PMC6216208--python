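"""Single-SNP case-control association statistics.

Implements the statistics of a classical GWAS locus report: minor allele
frequency, genotyping call rate, the Cochran-Armitage trend test, the 2x3
genotypic chi-square test, the exact Hardy-Weinberg equilibrium test,
the allelic odds ratio with a Wald confidence interval, two-locus LD r^2
from phased haplotype counts, and inverse-variance fixed-effects
meta-analysis of per-study log odds ratios.

Genotype counts are always ordered (hom-minor, het, hom-major); the minor
allele dose is therefore (2, 1, 0) across the triple, and the trend test
uses additive weights (0, 1, 2) on the same ordering (the statistic is
invariant to this orientation choice).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "AssocResult",
    "HaplotypeCounts",
    "MetaStudy",
    "MetaResult",
    "TrendResult",
    "GenotypicResult",
    "OddsRatioResult",
    "compute_maf",
    "call_rate",
    "catt_test",
    "genotypic_chi2_test",
    "hwe_exact_test",
    "allelic_or",
    "ld_r2",
    "fixed_effects_meta",
    "assoc_table",
]

_Z975 = stats.norm.ppf(0.975)

Triple = Sequence[int]


def _check_triple(counts: Triple, name: str = "counts") -> tuple[int, int, int]:
    if len(counts) != 3:
        raise ValueError(f"{name} must have exactly 3 entries, got {len(counts)}")
    out = []
    for c in counts:
        if c != int(c) or c < 0:
            raise ValueError(f"{name} must be non-negative integers, got {counts!r}")
        out.append(int(c))
    if sum(out) < 1:
        raise ValueError(f"{name} must sum to at least 1, got {counts!r}")
    return tuple(out)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype-count triples for one SNP in a case-control cohort.

    Counts are ordered (hom-minor, het, hom-major).  ``case_missing`` and
    ``control_missing`` are samples attempted but not genotyped at this SNP
    and enter only the call-rate computation.
    """

    snp_id: str
    chrom: str
    pos: int
    minor_allele: str
    major_allele: str
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]
    case_missing: int = 0
    control_missing: int = 0
    build: str = "hg19"

    def __post_init__(self) -> None:
        object.__setattr__(self, "case_counts", _check_triple(self.case_counts, "case_counts"))
        object.__setattr__(
            self, "control_counts", _check_triple(self.control_counts, "control_counts")
        )
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.minor_allele == self.major_allele:
            raise ValueError(f"{self.snp_id}: minor and major allele are both {self.minor_allele!r}")
        for nm in ("case_missing", "control_missing"):
            v = getattr(self, nm)
            if v < 0 or v != int(v):
                raise ValueError(f"{nm} must be a non-negative integer, got {v!r}")

    @property
    def n_case(self) -> int:
        return sum(self.case_counts)

    @property
    def n_control(self) -> int:
        return sum(self.control_counts)


@dataclass(frozen=True)
class AssocResult:
    """Per-SNP association statistics (one locus-report row)."""

    snp_id: str
    maf_case: float
    maf_control: float
    trend_stat: float
    p_trend: float
    genotypic_stat: float
    genotypic_df: int
    p_genotypic: float
    p_hwe_case: float
    p_hwe_control: float
    or_allelic: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    call_rate_case: float
    call_rate_control: float


class TrendResult(NamedTuple):
    statistic: float
    p_value: float
    monomorphic: bool = False


class GenotypicResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    corrected: bool = False


def compute_maf(counts: Triple) -> float:
    """Minor allele frequency from a (hom-minor, het, hom-major) triple."""
    hom_min, het, hom_maj = _check_triple(counts)
    n = hom_min + het + hom_maj
    return (2 * hom_min + het) / (2 * n)


def call_rate(genotyped: int, total: int) -> float:
    """Fraction of attempted samples successfully genotyped."""
    if total < 1:
        raise ValueError(f"total must be >= 1, got {total}")
    if not 0 <= genotyped <= total:
        raise ValueError(f"need 0 <= genotyped <= total, got {genotyped}/{total}")
    return genotyped / total


def catt_test(
    case: Triple, control: Triple, weights: Sequence[float] = (0.0, 1.0, 2.0)
) -> TrendResult:
    """Cochran-Armitage trend test on a 2x3 case-control genotype table.

    One-degree-of-freedom chi-square for a linear trend in case proportion
    across the genotype classes, with no continuity correction.  Default
    weights (0, 1, 2) encode the additive (per-allele dose) model.  A pooled
    sample monomorphic under the weighting (zero trend variance) yields
    statistic 0 and p = 1 with a warning.
    """
    case_a = np.asarray(_check_triple(case, "case"), dtype=float)
    ctrl_a = np.asarray(_check_triple(control, "control"), dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError(f"weights must have length 3, got {weights!r}")
    r = case_a.sum()
    s = ctrl_a.sum()
    n = r + s
    col = case_a + ctrl_a
    u = float(np.sum(w * (s * case_a - r * ctrl_a))) / n
    var_u = (r * s / n**3) * (n * float(np.sum(w**2 * col)) - float(np.sum(w * col)) ** 2)
    if var_u <= 0:
        warnings.warn(
            "trend test undefined (zero variance: pooled sample monomorphic "
            "under the given weights); returning statistic 0, p 1",
            stacklevel=2,
        )
        return TrendResult(0.0, 1.0, monomorphic=True)
    chi2 = u * u / var_u
    return TrendResult(chi2, float(stats.chi2.sf(chi2, 1)))


def genotypic_chi2_test(case: Triple, control: Triple) -> GenotypicResult:
    """Pearson chi-square on the 2x3 case/control-by-genotype table.

    Genotype columns with zero pooled count are dropped and the degrees of
    freedom reduced accordingly (2 df for a full table).  No continuity
    correction.
    """
    case_a = np.asarray(_check_triple(case, "case"), dtype=float)
    ctrl_a = np.asarray(_check_triple(control, "control"), dtype=float)
    keep = (case_a + ctrl_a) > 0
    if keep.sum() < 2:
        raise ValueError("genotypic test undefined: fewer than 2 non-empty genotype columns")
    obs = np.vstack([case_a[keep], ctrl_a[keep]])
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return GenotypicResult(float(chi2), int(df), float(p))


def hwe_exact_test(counts: Triple) -> float:
    """Exact test of Hardy-Weinberg equilibrium for one genotype triple.

    Enumerates every heterozygote count consistent with the observed allele
    counts, computes each configuration's probability under the conditional
    (hypergeometric) HWE null, and returns the summed probability of all
    configurations no more probable than the observed one.  This is the
    standard exact p-value, not the mid-p variant.  Monomorphic samples
    return 1.0.
    """
    hom_min, het, hom_maj = _check_triple(counts)
    n = hom_min + het + hom_maj
    n_minor = 2 * hom_min + het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    # log P(het = h | allele counts) up to the constant normalizer:
    #   log n! - log hm! - log h! - log hM! + h log 2
    # with hm = (n_minor - h)/2 homozygotes of the rarer allele.
    hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hm = (n_minor - hs) // 2
    hmaj = n - hm - hs
    logp = (
        math.lgamma(n + 1)
        - np.vectorize(math.lgamma)(hm + 1.0)
        - np.vectorize(math.lgamma)(hs + 1.0)
        - np.vectorize(math.lgamma)(hmaj + 1.0)
        + hs * math.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == het][0]
    # small relative tolerance so ties are counted despite float rounding
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def allelic_or(case: Triple, control: Triple, level: float = 0.95) -> OddsRatioResult:
    """Allelic odds ratio (minor vs major) with a Wald CI on the log scale.

    Genotypes collapse to allele counts (minor = 2*hom_minor + het).  If any
    of the four allele cells is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) and the ``corrected`` flag is set.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    ca = _check_triple(case, "case")
    co = _check_triple(control, "control")
    a = 2 * ca[0] + ca[1]  # case minor
    b = 2 * ca[2] + ca[1]  # case major
    c = 2 * co[0] + co[1]  # control minor
    d = 2 * co[2] + co[1]  # control major
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    if (a == 0 and b == 0) or (c == 0 and d == 0):
        raise ValueError("odds ratio undefined: a group has no allele counts")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        math.exp(log_or),
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
        log_or,
        se,
        corrected,
    )


@dataclass(frozen=True)
class HaplotypeCounts:
    """Phased two-locus haplotype counts, in the order AB, Ab, aB, ab.

    Upper case marks one allele at each locus (A at the first, B at the
    second); the four fields are the counts of the four phased haplotypes.
    """

    AB: int
    Ab: int
    aB: int
    ab: int

    def __post_init__(self) -> None:
        for nm in ("AB", "Ab", "aB", "ab"):
            v = getattr(self, nm)
            if v < 0 or v != int(v):
                raise ValueError(f"haplotype count {nm} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("haplotype counts must sum to at least 1")

    @property
    def total(self) -> int:
        return self.AB + self.Ab + self.aB + self.ab


def ld_r2(h: HaplotypeCounts) -> float:
    """Squared allelic correlation r^2 between two loci from phased haplotypes.

    With haplotype frequencies p_AB etc., D = p_AB - p_A p_B and
    r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B)).  Requires both loci polymorphic.
    """
    n = h.total
    p_ab = h.AB / n
    p_a = (h.AB + h.Ab) / n
    p_b = (h.AB + h.aB) / n
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        raise ValueError("LD undefined: at least one locus is monomorphic")
    d = p_ab - p_a * p_b
    return min(1.0, d * d / denom)


@dataclass(frozen=True)
class MetaStudy:
    """One study's effect for meta-analysis: log odds ratio and its SE."""

    study_id: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError(f"{self.study_id}: log_or must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.study_id}: se must be a positive finite number")


@dataclass(frozen=True)
class MetaResult:
    pooled_log_or: float
    pooled_se: float
    or_pooled: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n_studies: int


def fixed_effects_meta(studies: Sequence[MetaStudy], level: float = 0.95) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-study log odds ratios."""
    if len(studies) == 0:
        raise ValueError("meta-analysis requires at least one study")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    x = np.array([s.log_or for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    pooled = float(np.sum(w * x) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(0.5 + level / 2)
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=se,
        or_pooled=math.exp(pooled),
        ci_low=math.exp(pooled - zq * se),
        ci_high=math.exp(pooled + zq * se),
        z=z,
        p=min(1.0, p) if p > 0 else float(np.nextafter(0, 1)),
        n_studies=len(studies),
    )


def assoc_table(rows: Sequence[GenotypeCounts]) -> list[AssocResult]:
    """Full per-SNP association statistics for a list of genotype-count rows.

    Input order is preserved; duplicate SNP ids are rejected.
    """
    if len(rows) == 0:
        raise ValueError("assoc_table requires a non-empty list of genotype counts")
    seen: set[str] = set()
    out: list[AssocResult] = []
    for gc in rows:
        if gc.snp_id in seen:
            raise ValueError(f"duplicate snp_id {gc.snp_id!r}")
        seen.add(gc.snp_id)
        trend = catt_test(gc.case_counts, gc.control_counts)
        geno = genotypic_chi2_test(gc.case_counts, gc.control_counts)
        orr = allelic_or(gc.case_counts, gc.control_counts)
        out.append(
            AssocResult(
                snp_id=gc.snp_id,
                maf_case=compute_maf(gc.case_counts),
                maf_control=compute_maf(gc.control_counts),
                trend_stat=trend.statistic,
                p_trend=trend.p_value,
                genotypic_stat=geno.statistic,
                genotypic_df=geno.df,
                p_genotypic=geno.p_value,
                p_hwe_case=hwe_exact_test(gc.case_counts),
                p_hwe_control=hwe_exact_test(gc.control_counts),
                or_allelic=orr.odds_ratio,
                ci_low=orr.ci_low,
                ci_high=orr.ci_high,
                log_or=orr.log_or,
                se_log_or=orr.se,
                call_rate_case=call_rate(gc.n_case, gc.n_case + gc.case_missing),
                call_rate_control=call_rate(gc.n_control, gc.n_control + gc.control_missing),
            )
        )
    return out
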