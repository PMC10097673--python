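"""Approximate-Bayes-factor colocalisation of two traits in one region.

Per-variant Wakefield log approximate Bayes factors are combined into
posterior probabilities of five hypotheses: no association in the region
(H0), association with trait 1 only (H1), trait 2 only (H2), both traits via
different variants (H3), and both traits via one shared variant (H4). All
accumulation happens in log space so regions with very strong signals do not
overflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from micromr.sumstats import VariantAssociation, harmonize

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

#: Posterior probability of H4 at or above which a region is called colocalized.
COLOC_THRESHOLD = 0.80

DEFAULT_WINDOW_BP = 1_000_000


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class ColocConfig:
    """Priors for the enumeration. Effect-size prior SDs follow the usual
    defaults: 0.15·sd_y for a quantitative trait, 0.2 (log-OR) for
    case-control."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.p12 < self.p1 < 1 and self.p12 < self.p2 < 1):
            raise ColocError("priors must satisfy 0 < p12 < p1, p2 < 1")

    def prior_sd(self, trait_type: str, sd_y: float = 1.0) -> float:
        if trait_type == "cc":
            return self.prior_sd_cc
        return self.prior_sd_quant * sd_y


@dataclass(frozen=True)
class Region:
    """Variants present in both trait files, harmonized, in shared order."""

    lead_variant_id: str
    variant_ids: tuple[str, ...]
    positions: tuple[int, ...]
    beta1: tuple[float, ...]
    se1: tuple[float, ...]
    beta2: tuple[float, ...]
    se2: tuple[float, ...]
    trait1_type: str = "quant"
    trait2_type: str = "cc"
    sd_y: float = 1.0
    case_fraction: float | None = None
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        for name in ("positions", "beta1", "se1", "beta2", "se2"):
            if len(getattr(self, name)) != n:
                raise ColocError(f"{name} length does not match variant count")
        if n == 0:
            raise ColocError("region has no variants")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class ColocResult:
    pp: dict[str, float]
    n_variants: int
    config: ColocConfig

    @property
    def colocalized(self) -> bool:
        return self.pp["H4"] >= COLOC_THRESHOLD

    @property
    def best(self) -> str:
        return max(self.pp, key=lambda h: self.pp[h])


def extract_region(
    trait1: Sequence[VariantAssociation],
    trait2: Sequence[VariantAssociation],
    lead_variant_id: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    *,
    trait1_type: str = "quant",
    trait2_type: str = "cc",
    sd_y: float = 1.0,
    case_fraction: float | None = None,
) -> Region:
    """Intersect two full summary files around a lead variant.

    The window is inclusive at exactly ± ``window_bp`` of the lead position.
    Pairs are harmonized with the standard rules; dropped variants are logged
    and excluded.
    """
    by_id1 = {a.variant_id: a for a in trait1}
    if lead_variant_id not in by_id1:
        raise ColocError(f"lead variant {lead_variant_id} absent from trait-1 data")
    lead_pos = by_id1[lead_variant_id].position
    by_id2 = {a.variant_id: a for a in trait2}

    ids, poss, b1, s1, b2, s2 = [], [], [], [], [], []
    for a1 in trait1:
        if abs(a1.position - lead_pos) > window_bp:
            continue
        a2 = by_id2.get(a1.variant_id)
        if a2 is None:
            logger.info("%s present only in trait 1, excluded", a1.variant_id)
            continue
        pair = harmonize(a1, a2)
        if pair.dropped:
            logger.info("%s dropped during harmonization (%s)", a1.variant_id, pair.action)
            continue
        ids.append(pair.variant_id)
        poss.append(a1.position)
        b1.append(pair.exposure_beta)
        s1.append(pair.exposure_se)
        b2.append(pair.outcome_beta)
        s2.append(pair.outcome_se)
    if not ids:
        raise ColocError("no shared variants in the region")
    return Region(
        lead_variant_id=lead_variant_id,
        variant_ids=tuple(ids),
        positions=tuple(poss),
        beta1=tuple(b1),
        se1=tuple(s1),
        beta2=tuple(b2),
        se2=tuple(s2),
        trait1_type=trait1_type,
        trait2_type=trait2_type,
        sd_y=sd_y,
        case_fraction=case_fraction,
        window_bp=window_bp,
    )


def approximate_bayes_factor(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield-style log approximate Bayes factor for one association.

    With z = beta/se and r = prior_sd²/(prior_sd² + se²):
    log-ABF = ½·[log(1 − r) + r·z²].
    """
    if not se > 0:
        raise ColocError("se must be > 0")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (math.log1p(-r) + r * z * z)


def _log_abfs(betas, ses, prior_sd) -> np.ndarray:
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    z = b / s
    r = prior_sd**2 / (prior_sd**2 + s**2)
    return 0.5 * (np.log1p(-r) + r * z * z)


def coloc_abf(region: Region, config: ColocConfig | None = None) -> ColocResult:
    """Enumerate H0–H4 posterior probabilities for a region pair.

    All sums over variants run in log space. H3 is computed as
    S1·S2 − S4 via log-sum-exp with a clamp guard against negative round-off.
    """
    config = config or ColocConfig()
    l1 = _log_abfs(region.beta1, region.se1, config.prior_sd(region.trait1_type, region.sd_y))
    l2 = _log_abfs(region.beta2, region.se2, config.prior_sd(region.trait2_type))

    log_s1 = float(logsumexp(l1))
    log_s2 = float(logsumexp(l2))
    log_s4 = float(logsumexp(l1 + l2))
    # S3 = S1*S2 - S4 >= 0 (cross terms only); guard round-off
    log_prod = log_s1 + log_s2
    if log_s4 >= log_prod:
        if log_s4 > log_prod + 1e-9:
            logger.warning("H3 mass numerically negative; clamped to zero")
        log_s3 = -math.inf
    else:
        log_s3 = log_prod + math.log1p(-math.exp(log_s4 - log_prod))

    log_unnorm = np.array(
        [
            0.0,
            math.log(config.p1) + log_s1,
            math.log(config.p2) + log_s2,
            math.log(config.p1) + math.log(config.p2) + log_s3,
            math.log(config.p12) + log_s4,
        ]
    )
    denom = logsumexp(log_unnorm)
    pp = np.exp(log_unnorm - denom)
    return ColocResult(
        pp=dict(zip(HYPOTHESES, map(float, pp))),
        n_variants=region.n_variants,
        config=config,
    )


def regional_table(region: Region, result: ColocResult, path: str | Path) -> pd.DataFrame:
    """Plot-ready TSV: position, −log10 p per trait, lead flag."""
    z1 = np.array(region.beta1) / np.array(region.se1)
    z2 = np.array(region.beta2) / np.array(region.se2)
    df = pd.DataFrame(
        {
            "variant_id": region.variant_ids,
            "position": region.positions,
            "neglog10_p_trait1": -stats.norm.logsf(np.abs(z1)) / math.log(10) - math.log10(2),
            "neglog10_p_trait2": -stats.norm.logsf(np.abs(z2)) / math.log(10) - math.log10(2),
            "is_lead": [v == region.lead_variant_id for v in region.variant_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
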