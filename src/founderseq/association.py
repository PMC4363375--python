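"""Kinship-corrected case-control association for related individuals.

Cases and controls drawn from one extended pedigree are not independent, so
a naive allelic chi-square test has inflated type I error.  The
quasi-likelihood score test implemented here corrects for relatedness
through the genotype correlation structure implied by the kinship matrix
and, in addition:

* distinguishes unaffected controls from controls of unknown phenotype by a
  prevalence-based phenotype transform (affected -> 1, unaffected ->
  -k/(1-k) with sex-specific prevalence k, unknown -> 0);
* can borrow phenotype information from relatives who were phenotyped but
  not genotyped, folding it into the genotyped individuals' weights via the
  kinship regression A = T_N + Phi_NN^{-1} Phi_NM T_M;
* estimates the allele frequency by the best linear unbiased estimator
  under the kinship covariance rather than the naive sample mean.

With genotypes coded as allele half-counts y in {0, 1/2, 1}, estimated
frequency p and correlation structure K (diag 1 + h_i, off-diagonal
2 phi_ij), the statistic is

    W = [A' (y - p 1)]^2 / { (p (1 - p) / 2) * [A' K A - (A' 1)^2 / (1' K^-1 1)] }

which is asymptotically chi-square with 1 degree of freedom under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats

from .pedigree import KinshipMatrix, Pedigree

logger = logging.getLogger(__name__)

_X_CHROM_NAMES = {"X", "chrX", "23", "x"}

#: condition-number guard for the kinship solves
_MAX_CONDITION = 1e12


class AssociationError(ValueError):
    """Raised for inconsistent inputs to the association machinery."""


@dataclass(frozen=True)
class PrevalenceModel:
    """Sex-specific disorder prevalences used in the phenotype transform."""

    k_male: float = 0.25
    k_female: float = 0.27

    def __post_init__(self) -> None:
        for name, k in (("k_male", self.k_male), ("k_female", self.k_female)):
            if not 0.0 < k < 1.0:
                raise AssociationError(f"{name} must lie strictly in (0, 1), got {k}")

    @property
    def k_default(self) -> float:
        """Prevalence applied when sex is unknown (mean of the two sexes)."""
        return 0.5 * (self.k_male + self.k_female)

    def for_sex(self, sex: str) -> float:
        if sex == "male":
            return self.k_male
        if sex == "female":
            return self.k_female
        return self.k_default


@dataclass
class GenotypeVector:
    """Allele half-counts for the genotyped individuals at one variant.

    ``y[i]`` is (count of variant alleles)/2, i.e. 0, 1/2 or 1; ``np.nan``
    marks a missing genotype.
    """

    ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != self.y.shape[0]:
            raise AssociationError("ids and y have different lengths")
        valid = self.y[~np.isnan(self.y)]
        if not np.all(np.isin(valid, [0.0, 0.5, 1.0])):
            raise AssociationError("genotype values must be 0, 1/2, 1 or missing")

    def nonmissing(self) -> tuple[list[str], np.ndarray]:
        mask = ~np.isnan(self.y)
        return [i for i, m in zip(self.ids, mask) if m], self.y[mask]


@dataclass
class AssociationResult:
    variant: str
    W: float
    df: int
    p: float
    n_genotyped: int
    allele_freq_estimate: float
    testable: bool = True
    note: str = ""


@dataclass
class CohortSummary:
    label: str
    n: int
    freq_hom_ref: float
    freq_het: float
    freq_hom_var: float
    allele_freq: float
    carrier_count: int
    defined: bool = True


@dataclass
class PenetranceSummary:
    penetrance: float | None
    phenocopy_rate: float | None
    n_carriers: int
    n_affected: int
    affected_carriers: int
    affected_noncarriers: int


@dataclass
class ScanResult:
    results: list[AssociationResult]
    n_variants: int
    bonferroni_threshold: float


# ---------------------------------------------------------------------------
# Phenotype transform and enrichment
# ---------------------------------------------------------------------------

def transform_phenotypes(
    pedigree: Pedigree, prevalence: PrevalenceModel
) -> dict[str, float]:
    """Per-individual phenotype weights: affected 1, unaffected -k/(1-k), unknown 0."""
    weights: dict[str, float] = {}
    for ind in pedigree.individuals:
        if ind.affection == "affected":
            weights[ind.id] = 1.0
        elif ind.affection == "unaffected":
            k = prevalence.for_sex(ind.sex)
            weights[ind.id] = -k / (1.0 - k)
        else:
            weights[ind.id] = 0.0
    return weights


def _checked_solve(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Symmetric PD solve with an explicit near-singularity guard."""
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise AssociationError(
            f"kinship submatrix is near-singular (condition number {cond:.3g})"
        )
    c, low = linalg.cho_factor(mat, check_finite=False)
    return linalg.cho_solve((c, low), rhs, check_finite=False)


def enrich_phenotypes(
    weights: Mapping[str, float],
    genotyped_ids: Sequence[str],
    ungenotyped_ids: Sequence[str],
    kinship: KinshipMatrix,
) -> np.ndarray:
    """Fold ungenotyped relatives' phenotypes into the genotyped set.

    Returns A = T_N + Phi_NN^{-1} Phi_NM T_M over the genotyped set N, where
    M are phenotyped-but-ungenotyped individuals.  With M empty this is just
    T_N.
    """
    t_n = np.array([weights[i] for i in genotyped_ids], dtype=float)
    if not ungenotyped_ids:
        return t_n
    t_m = np.array([weights[i] for i in ungenotyped_ids], dtype=float)
    phi_nn = kinship.submatrix(genotyped_ids)
    phi_nm = kinship.cross_matrix(genotyped_ids, ungenotyped_ids)
    return t_n + _checked_solve(phi_nn, phi_nm @ t_m)


# ---------------------------------------------------------------------------
# Allele frequency and the score statistic
# ---------------------------------------------------------------------------

def estimate_allele_freq_blue(y: np.ndarray, K: np.ndarray) -> float:
    """Best linear unbiased allele-frequency estimate under covariance K.

    p = (1' K^-1 y) / (1' K^-1 1); for unrelated individuals (K = I) this is
    the sample mean of the half-counts.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise AssociationError("no non-missing genotypes")
    ones = np.ones_like(y)
    k_inv_ones = _checked_solve(K, ones)
    return float(k_inv_ones @ y) / float(k_inv_ones @ ones)


def mqls_test(
    y: np.ndarray,
    A: np.ndarray,
    K: np.ndarray,
    variant: str = "",
) -> AssociationResult:
    """Quasi-likelihood score test of one variant against the phenotype weights.

    Monomorphic variants (estimated frequency 0 or 1) and degenerate
    phenotype contrasts (zero variance term) are flagged untestable with
    p = 1 by convention.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(A, dtype=float)
    n = y.shape[0]
    if A.shape[0] != n or K.shape != (n, n):
        raise AssociationError("y, A and K must be aligned on the same individuals")
    p_hat = estimate_allele_freq_blue(y, K)
    if p_hat <= 0.0 or p_hat >= 1.0:
        return AssociationResult(
            variant, 0.0, 1, 1.0, n, p_hat, testable=False, note="monomorphic"
        )
    ones = np.ones(n)
    k_inv_ones = _checked_solve(K, ones)
    denom_bracket = float(A @ K @ A) - float(A @ ones) ** 2 / float(k_inv_ones @ ones)
    variance = (p_hat * (1.0 - p_hat) / 2.0) * denom_bracket
    if variance <= 1e-12:
        return AssociationResult(
            variant, 0.0, 1, 1.0, n, p_hat, testable=False, note="no phenotype contrast"
        )
    score = float(A @ (y - p_hat * ones))
    W = score**2 / variance
    p = float(stats.chi2.sf(W, df=1))
    return AssociationResult(variant, W, 1, max(p, np.finfo(float).tiny), n, p_hat)


def mqls_test_many(
    Y: np.ndarray,
    A: np.ndarray,
    K: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized score test of many variants sharing one genotyped set.

    ``Y`` is (n_individuals, n_variants) of allele half-counts with no
    missingness; ``A`` and ``K`` are shared across variants, so the kinship
    factorization is done once.  Returns ``(W, p, p_hat, testable)`` arrays;
    untestable variants (monomorphic or zero variance) get W = 0, p = 1.
    Agrees with :func:`mqls_test` column by column.
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if Y.shape[0] != n or K.shape != (n, n):
        raise AssociationError("Y, A and K must be aligned on the same individuals")
    ones = np.ones(n)
    k_inv_ones = _checked_solve(K, ones)
    u = float(k_inv_ones @ ones)
    p_hat = (k_inv_ones @ Y) / u
    a_sum = float(A @ ones)
    score = A @ Y - a_sum * p_hat
    bracket = float(A @ K @ A) - a_sum**2 / u
    variance = (p_hat * (1.0 - p_hat) / 2.0) * bracket
    testable = (p_hat > 0.0) & (p_hat < 1.0) & (variance > 1e-12)
    W = np.zeros_like(p_hat)
    np.divide(score**2, variance, out=W, where=testable)
    p = np.where(testable, stats.chi2.sf(W, df=1), 1.0)
    return W, p, p_hat, testable


def _is_x_linked(variant: str) -> bool:
    chrom = str(variant).split(":", 1)[0]
    return chrom in _X_CHROM_NAMES


def association_scan(
    genotypes: Mapping[str, GenotypeVector],
    pedigree: Pedigree,
    prevalence: PrevalenceModel,
    phenotyped_ungenotyped: Sequence[str] = (),
    kinship: KinshipMatrix | None = None,
    include_x: bool = False,
    alpha: float = 0.05,
) -> ScanResult:
    """Run the score test per variant and report a Bonferroni threshold.

    ``genotypes`` maps a variant name (``chrom:pos`` or any label whose
    prefix before ``:`` is the chromosome) to the genotype vector of the
    genotyped individuals.  X-linked variants are skipped with a warning
    unless ``include_x`` is set, in which case the autosomal statistic is
    applied and flagged approximate.  No adjustment is applied to the
    statistics themselves; the threshold ``alpha / n_variants`` is reported
    alongside.
    """
    if not genotypes:
        raise AssociationError("no variants supplied")
    from .pedigree import kinship_matrix as _kinship_matrix

    if kinship is None:
        kinship = _kinship_matrix(pedigree)
    weights = transform_phenotypes(pedigree, prevalence)
    results: list[AssociationResult] = []
    for variant, gv in genotypes.items():
        note = ""
        if _is_x_linked(variant):
            if not include_x:
                logger.warning(
                    "skipping X-linked variant %s (autosomal statistic only)", variant
                )
                continue
            note = "X-linked: autosomal statistic, approximate"
        ids, y = gv.nonmissing()
        if not ids:
            raise AssociationError(f"variant {variant}: all genotypes missing")
        A = enrich_phenotypes(weights, ids, list(phenotyped_ungenotyped), kinship)
        K = kinship.correlation_structure(ids)
        res = mqls_test(y, A, K, variant=variant)
        if note:
            res.note = (res.note + "; " + note).strip("; ")
        results.append(res)
    n_tested = len(results)
    threshold = alpha / n_tested if n_tested else float("nan")
    return ScanResult(results=results, n_variants=n_tested, bonferroni_threshold=threshold)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def cohort_frequency_summary(
    genotype_counts: Mapping[str, int],
    subgroups: Mapping[str, Sequence[str]],
) -> list[CohortSummary]:
    """Genotype and allele frequencies per subgroup.

    ``genotype_counts`` maps individual id to variant-allele count (0, 1, 2).
    Empty subgroups are returned with ``defined=False``.
    """
    out: list[CohortSummary] = []
    for label, ids in subgroups.items():
        counts = [genotype_counts[i] for i in ids if i in genotype_counts]
        n = len(counts)
        if n == 0:
            out.append(CohortSummary(label, 0, np.nan, np.nan, np.nan, np.nan, 0, defined=False))
            continue
        n_het = sum(1 for c in counts if c == 1)
        n_hom_var = sum(1 for c in counts if c == 2)
        n_hom_ref = n - n_het - n_hom_var
        allele_freq = (n_het + 2 * n_hom_var) / (2 * n)
        out.append(
            CohortSummary(
                label=label,
                n=n,
                freq_hom_ref=n_hom_ref / n,
                freq_het=n_het / n,
                freq_hom_var=n_hom_var / n,
                allele_freq=allele_freq,
                carrier_count=n_het + n_hom_var,
            )
        )
    return out


def penetrance_phenocopy_summary(
    carrier_status: Mapping[str, bool],
    affection: Mapping[str, str],
) -> PenetranceSummary:
    """Observed penetrance and phenocopy rate among fully observed individuals.

    Penetrance = affected carriers / carriers; phenocopy rate = affected
    non-carriers / affected.  Only individuals with both a genotype and a
    known affection status are counted; an undefined ratio is returned as
    ``None``.
    """
    carriers = affected = affected_carriers = affected_noncarriers = 0
    for iid, is_carrier in carrier_status.items():
        status = affection.get(iid, "unknown")
        if status == "unknown":
            continue
        is_affected = status == "affected"
        carriers += is_carrier
        affected += is_affected
        affected_carriers += is_carrier and is_affected
        affected_noncarriers += (not is_carrier) and is_affected
    return PenetranceSummary(
        penetrance=affected_carriers / carriers if carriers else None,
        phenocopy_rate=affected_noncarriers / affected if affected else None,
        n_carriers=carriers,
        n_affected=affected,
        affected_carriers=affected_carriers,
        affected_noncarriers=affected_noncarriers,
    )
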