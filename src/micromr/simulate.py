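"""Synthetic data generation with known ground truth.

Two backends are provided:

* an individual-level backend (``simulate_genotypes`` → trait → outcome →
  ``run_association_scan``) that exercises the exact scale conventions,
  allele frequencies and sample-size semantics of the I/O layer, and
* a fast closed-form summary backend (``summary_replicate``) that samples
  exposure/outcome effect estimates directly from their asymptotic sampling
  distributions for large replicate counts.

Regional datasets for colocalisation are generated at the summary level from
the standard multivariate-normal model of marginal z-scores given LD.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from micromr.instruments import lor_from_r2_liability
from micromr.screen import CatalogueEntry
from micromr.sumstats import VariantAssociation

SCENARIOS = (
    "null",
    "forward_causal",
    "pleiotropic",
    "reverse_causal",
    "shared_causal_region",
    "distinct_causal_region",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic dataset."""

    scenario: str
    seed: int
    n_individuals: int = 10_000
    n_cohorts: int = 3
    mafs: tuple[float, ...] = (0.3,)
    instrument_index: int = 0
    target_r2: float = 0.01
    true_or_per_sd: float = 1.0
    pleiotropy_beta: float = 0.0
    reverse_beta: float = 0.0
    measure: str = "AB"  # AB or PA
    prevalence: float = 0.6
    case_fraction: float = 0.46
    n_case: int = 5_500
    n_control: int = 6_500
    ld_block_size: int = 1
    ld_within_block_r: float = 0.0
    n_region_variants: int = 200

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        for p in (*self.mafs, self.prevalence, self.case_fraction):
            if not (0 < p < 1):
                raise SimulationError("probabilities must lie in (0, 1)")
        if self.measure not in ("AB", "PA"):
            raise SimulationError("measure must be AB or PA")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# --------------------------------------------------------------------------
# genotypes

def _latent_rho_for_genotype_r(target_r: float, maf: float) -> float:
    """Latent gaussian-copula correlation giving genotype correlation target_r.

    Alleles are thresholded latent gaussians; the genotype correlation equals
    the allele-indicator correlation, computed from the bivariate-normal
    orthant mass and inverted by bisection. Calibration assumes a shared MAF
    within the block (block members use the block's mean MAF).
    """
    if target_r == 0.0:
        return 0.0
    t = stats.norm.ppf(maf)
    pq = maf * (1.0 - maf)

    def realized(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([t, t], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        return (p11 - maf**2) / pq

    lo, hi = (0.0, 0.999999) if target_r > 0 else (-0.999999, 0.0)
    return float(optimize.brentq(lambda r: realized(r) - target_r, lo, hi, xtol=1e-6))


def simulate_genotypes(config: ScenarioConfig, cohort: int = 0) -> np.ndarray:
    """Hardy–Weinberg 0/1/2 genotypes with block-constant LD, one cohort.

    Each haplotype draws a latent gaussian per variant; within a block the
    latents share a calibrated equicorrelation so the realized genotype
    correlation matches ``ld_within_block_r`` (± sampling error).
    """
    rng = config.rng(stream=1000 + cohort)
    n = config.n_individuals
    m = len(config.mafs)
    mafs = np.asarray(config.mafs)
    geno = np.zeros((n, m), dtype=np.int8)
    block = max(1, config.ld_block_size)
    for start in range(0, m, block):
        idx = np.arange(start, min(start + block, m))
        rho = 0.0
        if len(idx) > 1 and config.ld_within_block_r != 0.0:
            rho = _latent_rho_for_genotype_r(
                config.ld_within_block_r, float(mafs[idx].mean())
            )
        thresh = stats.norm.ppf(mafs[idx])
        hap_sum = np.zeros((n, len(idx)), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            indep = rng.standard_normal((n, len(idx)))
            z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indep
            hap_sum += (z < thresh).astype(np.int8)
        geno[:, idx] = hap_sum
    return geno


# --------------------------------------------------------------------------
# traits and outcomes

def rank_normal(values: np.ndarray) -> np.ndarray:
    """Blom rank-normal transform: Φ⁻¹((rank − 3/8)/(n + 1/4)), stable ties."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    return stats.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


@dataclass(frozen=True)
class TraitData:
    """Phenotype as analysed: AB → rank-normalized abundance for everyone;
    PA → presence indicator, with zero-truncated rank-normalized abundance
    for carriers alongside."""

    measure: str
    values: np.ndarray  # AB: rank-normal abundance; PA: 0/1 presence
    abundance: np.ndarray | None = None  # PA only: NaN where absent


def _instrument_beta_continuous(target_r2: float, maf: float) -> float:
    # y = b·g + e, e ~ N(0,1): r² = b²·2pq / (b²·2pq + 1)
    var_g = 2.0 * maf * (1.0 - maf)
    return math.sqrt(target_r2 / (1.0 - target_r2) / var_g)


def simulate_microbial_trait(
    genotypes: np.ndarray, config: ScenarioConfig, cohort: int = 0
) -> TraitData:
    """Hurdle microbial trait driven by the designated instrument variant."""
    rng = config.rng(stream=2000 + cohort)
    g = genotypes[:, config.instrument_index].astype(float)
    maf = config.mafs[config.instrument_index]
    genetic = config.scenario not in ("null", "reverse_causal")
    n = len(g)

    if config.measure == "AB":
        b = _instrument_beta_continuous(config.target_r2, maf) if genetic else 0.0
        raw = b * g + rng.standard_normal(n)
        return TraitData(measure="AB", values=rank_normal(raw))

    lor = lor_from_r2_liability(config.target_r2, maf) if genetic else 0.0
    alpha = _solve_intercept(g, lor, config.prevalence)
    presence = (rng.random(n) < expit(alpha + lor * g)).astype(np.int8)
    abundance = np.full(n, np.nan)
    present = presence == 1
    if present.sum() > 2:
        b_ab = _instrument_beta_continuous(config.target_r2, maf) if genetic else 0.0
        raw = b_ab * g[present] + rng.standard_normal(int(present.sum()))
        abundance[present] = rank_normal(raw)
    return TraitData(measure="PA", values=presence.astype(float), abundance=abundance)


def _solve_intercept(g: np.ndarray, slope: float, target: float) -> float:
    if slope == 0.0:
        return float(logit(target))

    def mean_prob(alpha: float) -> float:
        return float(np.mean(expit(alpha + slope * g))) - target

    return float(optimize.brentq(mean_prob, -30.0, 30.0))


def simulate_outcome(
    genotypes: np.ndarray, trait: TraitData, config: ScenarioConfig, cohort: int = 0
) -> np.ndarray:
    """Case/control labels from a logistic model on the (standardized) trait.

    forward_causal adds ln(OR)·trait; pleiotropic additionally adds a direct
    genotype effect; reverse_causal generates the outcome independent of the
    trait (the trait shift is handled in trait generation / summary backend).
    """
    rng = config.rng(stream=3000 + cohort)
    t = trait.values
    t_std = (t - t.mean()) / t.std() if t.std() > 0 else t
    eta = np.zeros(len(t))
    if config.scenario in ("forward_causal", "pleiotropic"):
        eta += math.log(config.true_or_per_sd) * t_std
    if config.scenario == "pleiotropic":
        eta += config.pleiotropy_beta * genotypes[:, config.instrument_index]
    alpha = _solve_intercept(eta, 1.0, config.case_fraction) if eta.any() else float(
        logit(config.case_fraction)
    )
    return (rng.random(len(t)) < expit(alpha + eta)).astype(np.int8)


# --------------------------------------------------------------------------
# association scans

def run_association_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    *,
    trait_id: str = "trait",
    trait_type: str = "continuous",
    variant_ids: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
    chromosome: str = "1",
) -> list[VariantAssociation]:
    """Per-variant regression scan producing validated summary statistics.

    Continuous phenotypes use simple linear regression (closed form); binary
    phenotypes use per-variant logistic regression, returning log-OR betas.
    Monomorphic variants are skipped. Alleles are fixed A (effect) / G.
    """
    import statsmodels.api as sm

    n, m = genotypes.shape
    y = np.asarray(phenotype, dtype=float)
    variant_ids = variant_ids or [f"rs{i + 1}" for i in range(m)]
    positions = positions or [1_000_000 * (i + 1) for i in range(m)]
    out: list[VariantAssociation] = []
    for j in range(m):
        g = genotypes[:, j].astype(float)
        if g.std() == 0:
            continue
        eaf = float(g.mean() / 2.0)
        if trait_type == "continuous":
            beta, se = _linear_fit(g, y)
        else:
            try:
                model = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
            except Exception:  # separation etc.
                continue
            beta, se = float(model.params[1]), float(model.bse[1])
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
        out.append(
            VariantAssociation(
                variant_id=variant_ids[j],
                chromosome=chromosome,
                position=int(positions[j]),
                effect_allele="A",
                other_allele="G",
                eaf=eaf,
                beta=beta,
                se=se,
                pvalue=max(p, 5e-324),
                n=n,
                trait_id=trait_id,
                trait_type=trait_type,
            )
        )
    return out


def _linear_fit(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(g)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    s2 = float(resid @ resid) / (n - 2)
    return beta, math.sqrt(s2 / sxx)


def scan_cohorts(config: ScenarioConfig) -> list[list[VariantAssociation]]:
    """Individual-level simulation + scan for every cohort."""
    results = []
    for c in range(config.n_cohorts):
        geno = simulate_genotypes(config, cohort=c)
        trait = simulate_microbial_trait(geno, config, cohort=c)
        pheno = trait.values
        ttype = "binary" if config.measure == "PA" else "continuous"
        results.append(
            run_association_scan(
                geno, pheno, trait_id=f"trait_c{c}", trait_type=ttype
            )
        )
    return results


# --------------------------------------------------------------------------
# closed-form summary backend

@dataclass(frozen=True)
class SummaryReplicate:
    exposure: VariantAssociation
    outcome: VariantAssociation
    true_beta_xy: float


def summary_replicate(config: ScenarioConfig, rng: np.random.Generator) -> SummaryReplicate:
    """One exposure/outcome summary pair drawn from asymptotic distributions.

    Exposure: SD-unit beta with var-explained ``target_r2`` at the instrument
    MAF. Outcome: log-OR beta equal to ln(true OR per SD)·beta_x plus any
    direct pleiotropic effect, with the case-control GWAS standard error.
    """
    maf = config.mafs[config.instrument_index]
    pq2 = 2.0 * maf * (1.0 - maf)
    n_exp = config.n_individuals
    beta_x = math.sqrt(config.target_r2 / pq2)
    se_x = math.sqrt((1.0 - config.target_r2) / (pq2 * n_exp))

    n_out = config.n_case + config.n_control
    k = config.n_case / n_out
    se_y = 1.0 / math.sqrt(pq2 * n_out * k * (1.0 - k))
    true_bxy = math.log(config.true_or_per_sd) if config.scenario in (
        "forward_causal",
        "pleiotropic",
    ) else 0.0
    beta_y = true_bxy * beta_x + (
        config.pleiotropy_beta if config.scenario == "pleiotropic" else 0.0
    )

    bx_hat = float(rng.normal(beta_x, se_x))
    by_hat = float(rng.normal(beta_y, se_y))
    exposure = VariantAssociation(
        variant_id="rs1",
        chromosome="1",
        position=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=maf,
        beta=bx_hat,
        se=se_x,
        pvalue=max(float(2 * stats.norm.sf(abs(bx_hat / se_x))), 5e-324),
        n=n_exp,
        trait_id="trait",
        trait_type="continuous" if config.measure == "AB" else "binary",
    )
    outcome = VariantAssociation(
        variant_id="rs1",
        chromosome="1",
        position=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=maf,
        beta=by_hat,
        se=se_y,
        pvalue=max(float(2 * stats.norm.sf(abs(by_hat / se_y))), 5e-324),
        n=n_out,
        n_case=config.n_case,
        n_control=config.n_control,
        trait_id="outcome",
        trait_type="binary",
    )
    return SummaryReplicate(exposure=exposure, outcome=outcome, true_beta_xy=true_bxy)


def reverse_summary_replicate(
    config: ScenarioConfig,
    rng: np.random.Generator,
    n_snps: int = 20,
    instrument_z: float = 20.0,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Summary pairs for reverse MR: disease SNPs as exposure, trait as outcome.

    Disease instruments all have true association z-score ``instrument_z`` in
    the case-control GWAS (strong, as genome-wide hits from a large
    meta-analysis are); under ``reverse_causal`` the trait responds with
    slope ``reverse_beta`` per unit log-odds of disease liability.
    """
    maf = config.mafs[config.instrument_index]
    pq2 = 2.0 * maf * (1.0 - maf)
    n_out = config.n_case + config.n_control
    k = config.n_case / n_out
    se_d = 1.0 / math.sqrt(pq2 * n_out * k * (1.0 - k))
    beta_d = instrument_z * se_d

    n_tr = config.n_individuals
    se_t = 1.0 / math.sqrt(pq2 * n_tr)
    slope = config.reverse_beta if config.scenario == "reverse_causal" else 0.0

    exp_list, out_list = [], []
    for i in range(n_snps):
        bd = float(rng.normal(beta_d, se_d))
        bt = float(rng.normal(slope * beta_d, se_t))
        common = dict(
            variant_id=f"rs{i + 1}",
            chromosome="1",
            position=1_000_000 * (i + 1),
            effect_allele="A",
            other_allele="G",
            eaf=maf,
        )
        exp_list.append(
            VariantAssociation(
                beta=bd,
                se=se_d,
                pvalue=max(float(2 * stats.norm.sf(abs(bd / se_d))), 5e-324),
                n=n_out,
                n_case=config.n_case,
                n_control=config.n_control,
                trait_id="outcome",
                trait_type="binary",
                **common,
            )
        )
        out_list.append(
            VariantAssociation(
                beta=bt,
                se=se_t,
                pvalue=max(float(2 * stats.norm.sf(abs(bt / se_t))), 5e-324),
                n=n_tr,
                trait_id="trait",
                trait_type="continuous",
                **common,
            )
        )
    return exp_list, out_list


# --------------------------------------------------------------------------
# regional datasets for colocalisation

@dataclass(frozen=True)
class RegionalDataset:
    trait1: list[VariantAssociation]
    trait2: list[VariantAssociation]
    ld: np.ndarray
    truth: dict


def _block_ld(n_variants: int, block_size: int, rho: float) -> np.ndarray:
    ld = np.eye(n_variants)
    for start in range(0, n_variants, block_size):
        stop = min(start + block_size, n_variants)
        ld[start:stop, start:stop] = rho
    np.fill_diagonal(ld, 1.0)
    return ld


def make_regional_dataset(
    config: ScenarioConfig,
    *,
    causal_z: float = 8.0,
    ld_rho: float = 0.8,
    ld_block_size: int = 20,
) -> RegionalDataset:
    """Two regional summary files + LD under a named coloc scenario.

    Marginal z-scores follow z ~ MVN(R·λ, R) with λ the causal z-score
    vector. ``shared_causal_region`` plants the same causal variant in both
    traits; ``distinct_causal_region`` plants two causal variants in separate
    LD blocks; ``null`` plants none.
    """
    if config.scenario not in ("shared_causal_region", "distinct_causal_region", "null"):
        raise SimulationError("regional datasets need a regional scenario")
    rng = config.rng(stream=4000)
    m = config.n_region_variants
    ld = _block_ld(m, ld_block_size, ld_rho)
    chol = np.linalg.cholesky(ld + 1e-10 * np.eye(m))

    lam1 = np.zeros(m)
    lam2 = np.zeros(m)
    causal1 = m // 2
    if config.scenario == "shared_causal_region":
        lam1[causal1] = causal_z
        lam2[causal1] = causal_z
        causal2 = causal1
    elif config.scenario == "distinct_causal_region":
        causal2 = (causal1 + ld_block_size) % m
        lam1[causal1] = causal_z
        lam2[causal2] = causal_z
    else:
        causal1 = causal2 = -1

    z1 = ld @ lam1 + chol @ rng.standard_normal(m)
    z2 = ld @ lam2 + chol @ rng.standard_normal(m)

    maf = config.mafs[config.instrument_index]
    pq2 = 2.0 * maf * (1.0 - maf)
    n1 = config.n_individuals
    se1 = 1.0 / math.sqrt(pq2 * n1)
    n2 = config.n_case + config.n_control
    k = config.n_case / n2
    se2 = 1.0 / math.sqrt(pq2 * n2 * k * (1.0 - k))

    lead = f"rs{causal1 + 1}" if causal1 >= 0 else f"rs{m // 2 + 1}"
    center = 5_000_000
    positions = center + (np.arange(m) - m // 2) * 5_000

    def build(z, se, n, trait_id, ttype, extra) -> list[VariantAssociation]:
        out = []
        for i in range(m):
            beta = float(z[i] * se)
            out.append(
                VariantAssociation(
                    variant_id=f"rs{i + 1}",
                    chromosome="1",
                    position=int(positions[i]),
                    effect_allele="A",
                    other_allele="G",
                    eaf=maf,
                    beta=beta,
                    se=se,
                    pvalue=max(float(2 * stats.norm.sf(abs(z[i]))), 5e-324),
                    n=n,
                    trait_id=trait_id,
                    trait_type=ttype,
                    **extra,
                )
            )
        return out

    trait1 = build(z1, se1, n1, "microbial_trait", "continuous", {})
    trait2 = build(
        z2, se2, n2, "disease", "binary",
        {"n_case": config.n_case, "n_control": config.n_control},
    )
    truth = {
        "scenario": config.scenario,
        "lead_variant_id": lead,
        "causal1": f"rs{causal1 + 1}" if causal1 >= 0 else None,
        "causal2": f"rs{causal2 + 1}" if causal2 >= 0 else None,
    }
    return RegionalDataset(trait1=trait1, trait2=trait2, ld=ld, truth=truth)


# --------------------------------------------------------------------------
# LD matrix and fixture I/O

def write_ld_matrix(ld: np.ndarray, variant_ids: Sequence[str], path: str | Path) -> None:
    """Whitespace-delimited square matrix with a variant_id header row."""
    with open(path, "w") as fh:
        fh.write(" ".join(variant_ids) + "\n")
        for row in ld:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ld_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().split()
        ld = np.loadtxt(fh)
    ld = np.atleast_2d(ld)
    if ld.shape != (len(header), len(header)):
        raise SimulationError(f"{path}: LD matrix is not square against its header")
    return ld, header


def make_catalogue_fixture(
    class_counts: dict[str, int],
    *,
    variant_id: str = "rs1",
    seed: int = 0,
    threshold: float = 1e-4,
    sub_threshold: bool = True,
) -> list[CatalogueEntry]:
    """Deterministic catalogue with the requested per-class composition."""
    rng = np.random.default_rng(seed)
    entries = []
    for cls in sorted(class_counts):
        for i in range(class_counts[cls]):
            if sub_threshold:
                p = float(threshold * rng.uniform(1e-6, 0.999))
            else:
                p = float(rng.uniform(threshold, 1.0))
            entries.append(
                CatalogueEntry(
                    variant_id=variant_id,
                    trait_name=f"{cls}_{i + 1}",
                    trait_class=cls,
                    pvalue=max(p, 5e-324),
                    source="synthetic",
                )
            )
    return entries


def ground_truth_sidecar(config: ScenarioConfig, path: str | Path) -> None:
    """Write the scenario's ground truth as JSON next to generated files."""
    Path(path).write_text(json.dumps(asdict(config), indent=2, default=list))
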