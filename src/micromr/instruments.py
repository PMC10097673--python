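"""Instrument selection and grading.

Covers p-value threshold selection, inverse-variance fixed-effects
meta-analysis across cohorts with the "meta-supported" rule, the lenient
threshold + cross-cohort directional-consistency filter, greedy LD clumping,
variance explained on the observed and liability scales, first-stage
F-statistics, and asymptotic power for a binary-outcome MR design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from micromr.sumstats import VariantAssociation

logger = logging.getLogger(__name__)

#: Genome-wide selection threshold used for single-SNP instruments.
GENOME_WIDE_THRESHOLD = 2.5e-8
#: Study-wide Bonferroni threshold.
STUDY_WIDE_THRESHOLD = 1.57e-10
#: Lenient threshold for multi-SNP sensitivity instruments.
LENIENT_THRESHOLD = 1e-5
#: Reverse-direction instrument selection threshold.
CONVENTIONAL_GWAS_THRESHOLD = 5e-8
#: Clumping defaults.
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 10_000_000

#: logistic -> probit scale factor (SD of the standard logistic distribution).
LOGISTIC_SCALE = math.pi / math.sqrt(3.0)


class InstrumentError(ValueError):
    pass


@dataclass(frozen=True)
class InstrumentSet:
    trait_id: str
    variant_ids: tuple[str, ...]
    selection_threshold: float
    selection_mode: str = "genome_wide"

    @property
    def k(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class InstrumentMetrics:
    variant_id: str
    r2: float
    f_stat: float
    scale: str = "observed"  # or "liability"


@dataclass(frozen=True)
class CohortAssociation:
    cohort_id: str
    association: VariantAssociation


@dataclass(frozen=True)
class PowerSpec:
    alpha: float
    r2: float
    odds_ratio: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InstrumentError("alpha must be in (0, 1)")
        if not (0 < self.r2 < 1):
            raise InstrumentError("r2 must be in (0, 1)")
        if not self.odds_ratio > 0:
            raise InstrumentError("odds_ratio must be > 0")


def _sort_key(a: VariantAssociation) -> tuple[float, str]:
    # deterministic: ascending p, ties broken lexicographically
    return (a.pvalue, a.variant_id)


def select_by_threshold(
    assocs: Sequence[VariantAssociation],
    threshold: float = GENOME_WIDE_THRESHOLD,
    *,
    selection_mode: str = "genome_wide",
) -> InstrumentSet:
    """Variants with p strictly below ``threshold``, sorted ascending by p."""
    trait_ids = {a.trait_id for a in assocs}
    trait_id = trait_ids.pop() if len(trait_ids) == 1 else ""
    hits = sorted((a for a in assocs if a.pvalue < threshold), key=_sort_key)
    return InstrumentSet(
        trait_id=trait_id,
        variant_ids=tuple(a.variant_id for a in hits),
        selection_threshold=threshold,
        selection_mode=selection_mode,
    )


def fixed_effects_meta(
    cohorts: Sequence[CohortAssociation],
    *,
    discovery_cohort: str = "discovery",
) -> tuple[VariantAssociation, bool]:
    """Inverse-variance fixed-effects meta-analysis across cohorts.

    Returns the pooled association and ``meta_supported``: whether the pooled
    p-value is smaller than the discovery cohort's own p-value (two-sided
    normal p from z = beta/se in both cases).
    """
    if len(cohorts) < 2:
        raise InstrumentError("meta-analysis requires >= 2 cohorts")
    first = cohorts[0].association
    for c in cohorts[1:]:
        a = c.association
        if a.variant_id != first.variant_id or a.trait_id != first.trait_id:
            raise InstrumentError("all cohorts must share variant and trait")
        if (a.effect_allele, a.other_allele) != (first.effect_allele, first.other_allele):
            raise InstrumentError("cohorts must be harmonized to a shared effect allele")

    weights = np.array([1.0 / c.association.se**2 for c in cohorts])
    betas = np.array([c.association.beta for c in cohorts])
    meta_beta = float(np.sum(weights * betas) / np.sum(weights))
    meta_se = float(1.0 / math.sqrt(np.sum(weights)))
    meta_p = _normal_p(meta_beta / meta_se)

    disc = next(
        (c.association for c in cohorts if c.cohort_id == discovery_cohort),
        cohorts[0].association,
    )
    disc_p = _normal_p(disc.beta / disc.se)

    n_total = sum(c.association.n for c in cohorts)
    meta = VariantAssociation(
        variant_id=first.variant_id,
        chromosome=first.chromosome,
        position=first.position,
        effect_allele=first.effect_allele,
        other_allele=first.other_allele,
        eaf=first.eaf,
        beta=meta_beta,
        se=meta_se,
        pvalue=max(meta_p, 5e-324),
        n=n_total,
        trait_id=first.trait_id,
        trait_type=first.trait_type,
    )
    return meta, bool(meta_p < disc_p)


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def directional_consistency_filter(
    per_cohort: Mapping[str, Sequence[CohortAssociation]],
    lenient_threshold: float = LENIENT_THRESHOLD,
    *,
    discovery_cohort: str = "discovery",
    trait_id: str = "",
) -> InstrumentSet:
    """Lenient multi-SNP instrument selection with cross-cohort sign agreement.

    ``per_cohort`` maps variant_id to that variant's associations in every
    cohort. A variant is kept iff its fixed-effects meta p-value is below the
    lenient threshold and the effect sign is identical in all cohorts.
    Variants with a missing cohort record are excluded with a log entry.
    """
    n_cohorts = max((len(v) for v in per_cohort.values()), default=0)
    kept: list[VariantAssociation] = []
    for vid in sorted(per_cohort):
        cohorts = per_cohort[vid]
        if len(cohorts) < n_cohorts or len(cohorts) < 2:
            logger.info("%s missing a cohort estimate, excluded", vid)
            continue
        signs = {math.copysign(1.0, c.association.beta) for c in cohorts}
        if len(signs) != 1:
            continue
        meta, _ = fixed_effects_meta(cohorts, discovery_cohort=discovery_cohort)
        if meta.pvalue < lenient_threshold:
            kept.append(meta)
    kept.sort(key=_sort_key)
    return InstrumentSet(
        trait_id=trait_id or (kept[0].trait_id if kept else ""),
        variant_ids=tuple(a.variant_id for a in kept),
        selection_threshold=lenient_threshold,
        selection_mode="lenient_consistent",
    )


def greedy_clump(
    assocs: Sequence[VariantAssociation],
    ld: np.ndarray,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> InstrumentSet:
    """Greedy p-value-ordered LD clumping.

    ``ld`` is the signed correlation matrix aligned to ``assocs`` order. A
    variant is retained iff its squared correlation with every already-kept
    variant within ``window_bp`` is at most ``r2_threshold``.
    """
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (len(assocs), len(assocs)):
        raise InstrumentError(
            f"LD matrix shape {ld.shape} does not match {len(assocs)} associations"
        )
    order = sorted(range(len(assocs)), key=lambda i: _sort_key(assocs[i]))
    kept_idx: list[int] = []
    for i in order:
        ok = True
        for j in kept_idx:
            if abs(assocs[i].position - assocs[j].position) <= window_bp:
                if ld[i, j] ** 2 > r2_threshold:
                    ok = False
                    break
        if ok:
            kept_idx.append(i)
    kept_idx.sort(key=lambda i: _sort_key(assocs[i]))
    trait_ids = {assocs[i].trait_id for i in kept_idx}
    return InstrumentSet(
        trait_id=trait_ids.pop() if len(trait_ids) == 1 else "",
        variant_ids=tuple(assocs[i].variant_id for i in kept_idx),
        selection_threshold=math.nan,
        selection_mode="clumped",
    )


def r2_continuous(beta: float, se: float, maf: float, n: int) -> float:
    """Variance explained by one variant in a continuous trait.

    R² = 2β²q / (2β²q + se²·2N·q) with q = MAF(1−MAF); the q factor cancels,
    so the value equals z²/(z² + N), but MAF is validated because the printed
    form requires it.
    """
    if not (0 < maf <= 0.5):
        raise InstrumentError(f"maf must be in (0, 0.5], got {maf}")
    if not se > 0:
        raise InstrumentError("se must be > 0")
    if n < 2:
        raise InstrumentError("n must be >= 2")
    q = maf * (1.0 - maf)
    num = 2.0 * beta**2 * q
    den = num + se**2 * 2.0 * n * q
    return num / den


def r2_liability_from_lor(log_odds_ratio: float, eaf: float, prevalence: float) -> float:
    """Variance explained on the liability scale for a binary trait.

    The per-allele log odds ratio is mapped to a liability-scale effect by the
    logistic-to-probit factor π/√3; the genotypic variance 2·eaf·(1−eaf)·β²
    is then expressed as a fraction of total liability variance (residual
    variance 1). ``prevalence`` is validated as part of the trait definition
    (it indexes the threshold model the approximation stands in for).
    """
    if not (0 < prevalence < 1):
        raise InstrumentError(f"prevalence must be in (0, 1), got {prevalence}")
    if not (0 < eaf < 1):
        raise InstrumentError(f"eaf must be in (0, 1), got {eaf}")
    beta_liab = log_odds_ratio / LOGISTIC_SCALE
    var_g = 2.0 * eaf * (1.0 - eaf) * beta_liab**2
    return var_g / (var_g + 1.0)


def lor_from_r2_liability(r2: float, eaf: float) -> float:
    """Inverse of :func:`r2_liability_from_lor` (positive branch)."""
    if not (0 <= r2 < 1):
        raise InstrumentError("r2 must be in [0, 1)")
    var_g = r2 / (1.0 - r2)
    beta_liab = math.sqrt(var_g / (2.0 * eaf * (1.0 - eaf)))
    return beta_liab * LOGISTIC_SCALE


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """First-stage F: R²(N−1−k) / ((1−R²)·k)."""
    if not (0 <= r2 < 1):
        raise InstrumentError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise InstrumentError("n must exceed k + 1")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def mr_power_binary(spec: PowerSpec) -> float:
    """Asymptotic power of a two-sample MR test with a binary outcome.

    power = Φ(|ln OR|·√(N·R²·K(1−K)) − z₁₋α/₂) with N the total sample size
    and K the case fraction.
    """
    n_total = spec.n_case + spec.n_control
    k_frac = spec.n_case / n_total
    ncp = abs(math.log(spec.odds_ratio)) * math.sqrt(
        n_total * spec.r2 * k_frac * (1.0 - k_frac)
    )
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))


def instrument_metrics(
    assoc: VariantAssociation,
    *,
    k: int = 1,
    prevalence: float | None = None,
) -> InstrumentMetrics:
    """R² and F for one instrument, liability scale for binary traits."""
    if assoc.trait_type == "binary":
        if prevalence is None:
            raise InstrumentError("binary traits need a prevalence for liability R2")
        if assoc.eaf is None:
            raise InstrumentError("binary traits need eaf for liability R2")
        r2 = r2_liability_from_lor(assoc.beta, assoc.eaf, prevalence)
        scale = "liability"
    else:
        if assoc.maf is None:
            raise InstrumentError("continuous traits need eaf/maf for R2")
        r2 = r2_continuous(assoc.beta, assoc.se, assoc.maf, assoc.n)
        scale = "observed"
    return InstrumentMetrics(
        variant_id=assoc.variant_id,
        r2=r2,
        f_stat=f_statistic(r2, assoc.n, k),
        scale=scale,
    )
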