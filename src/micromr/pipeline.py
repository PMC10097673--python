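"""Config-driven orchestration: forward MR, sensitivity battery, reverse MR.

An :class:`AnalysisPlan` names exposure and outcome summary-statistics files
plus sensitivity toggles; the runner functions read the files through
:mod:`micromr.sumstats`, apply the estimators and write tidy tables. Every
exposure × outcome combination appears in the output with a status — nothing
is silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from micromr import __version__, coloc, estimators, instruments, screen, sumstats

logger = logging.getLogger(__name__)

SITES = ("overall", "distal", "proximal", "colon", "rectal")

RESULT_COLUMNS = [
    "trait_id",
    "measure",
    "site",
    "method",
    "n_snps",
    "beta",
    "se",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "pvalue",
    "q_stat",
    "q_p",
    "egger_intercept_p",
    "status",
]


@dataclass(frozen=True)
class ExposureSpec:
    trait: sumstats.MicrobialTrait
    sumstats_path: str
    selection_threshold: float = instruments.GENOME_WIDE_THRESHOLD
    cohort_paths: tuple[str, ...] = ()  # per-cohort files for lenient selection


@dataclass(frozen=True)
class OutcomeSpec:
    site: str
    sumstats_path: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")


@dataclass(frozen=True)
class AnalysisPlan:
    exposures: tuple[ExposureSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    output_dir: str
    seed: int
    run_coloc: bool = False
    run_screen: bool = False
    run_lenient: bool = False
    run_reverse: bool = False
    catalogue_path: str | None = None
    regional_paths: tuple[tuple[str, str, str, str], ...] = ()  # (trait_id, t1, t2, lead)
    reverse_exposure_path: str | None = None
    reverse_ld_path: str | None = None
    reverse_threshold: float = instruments.CONVENTIONAL_GWAS_THRESHOLD
    reverse_clump_r2: float = instruments.CLUMP_R2
    flag_p: float = 0.05
    n_boot: int = 5000

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("plan needs >= 1 exposure and >= 1 outcome")


def _estimate_rows(
    pairs: list[sumstats.HarmonizedPair],
    trait: sumstats.MicrobialTrait,
    site: str,
    seed: int,
    n_boot: int,
) -> list[dict]:
    live = sumstats.surviving(pairs)
    if not live:
        return [
            _row(trait, site, None, status="no_instrument")
        ]
    if len(live) == 1:
        ests = [estimators.wald_ratio(live[0])]
    else:
        ests = estimators.all_estimators(live, n_boot=n_boot, seed=seed)
    rows = []
    for est in ests:
        if trait.measure == "PA":
            est = estimators.scale_binary_exposure(est, "binary")
        rows.append(_row(trait, site, est, status="ok"))
    return rows


def _row(trait, site, est, status: str) -> dict:
    base = {
        "trait_id": trait.trait_id,
        "measure": trait.measure,
        "site": site,
        "method": est.method if est else "",
        "n_snps": est.n_snps if est else 0,
        "status": status,
    }
    if est is not None:
        or_, lo, hi = estimators.to_odds_ratio(est)
        base.update(
            beta=est.beta_xy,
            se=est.se,
            odds_ratio=or_,
            ci_low=lo,
            ci_high=hi,
            pvalue=est.pvalue,
            q_stat=est.q_stat,
            q_p=est.q_p,
            egger_intercept_p=est.egger_intercept_p,
        )
    return base


def run_forward(plan: AnalysisPlan) -> pd.DataFrame:
    """Per exposure × site: harmonize, estimate, convert to odds ratios."""
    rows: list[dict] = []
    for exp in plan.exposures:
        ttype = "binary" if exp.trait.measure == "PA" else "continuous"
        exp_assocs = sumstats.read_sumstats(
            exp.sumstats_path, trait_id=exp.trait.trait_id, trait_type=ttype
        )
        selected = instruments.select_by_threshold(exp_assocs, exp.selection_threshold)
        chosen = [a for a in exp_assocs if a.variant_id in set(selected.variant_ids)]
        for out in plan.outcomes:
            out_assocs = sumstats.read_sumstats(
                out.sumstats_path, trait_id=out.site, trait_type="binary"
            )
            pairs = sumstats.harmonize_many(chosen, out_assocs)
            rows.extend(_estimate_rows(pairs, exp.trait, out.site, plan.seed, plan.n_boot))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def flagged_traits(plan: AnalysisPlan, forward: pd.DataFrame) -> list[str]:
    """Traits whose primary forward estimate passes the follow-up flag rule."""
    primary = forward[forward["method"].isin(["wald_ratio", "ivw"])]
    hits = primary[(primary["status"] == "ok") & (primary["pvalue"] < plan.flag_p)]
    return sorted(hits["trait_id"].unique())


def run_sensitivity(plan: AnalysisPlan, forward: pd.DataFrame) -> dict:
    """Coloc, pleiotropy screen and lenient multi-estimator table for flagged traits."""
    flagged = flagged_traits(plan, forward)
    bundle: dict = {"flagged": flagged, "coloc": [], "screen": [], "lenient": []}

    if plan.run_coloc:
        regional = {r[0]: r for r in plan.regional_paths}
        for trait_id in flagged:
            if trait_id not in regional:
                logger.warning("no regional data for %s; coloc skipped", trait_id)
                continue
            _, t1_path, t2_path, lead = regional[trait_id]
            t1 = sumstats.read_sumstats(t1_path)
            t2 = sumstats.read_sumstats(t2_path)
            region = coloc.extract_region(t1, t2, lead)
            res = coloc.coloc_abf(region)
            bundle["coloc"].append(
                {"trait_id": trait_id, "n_variants": res.n_variants,
                 "colocalized": res.colocalized, **res.pp}
            )

    if plan.run_screen and plan.catalogue_path:
        catalogue = screen.load_catalogue(plan.catalogue_path)
        exp_by_trait = {e.trait.trait_id: e for e in plan.exposures}
        for trait_id in flagged:
            exp = exp_by_trait.get(trait_id)
            if exp is None:
                continue
            assocs = sumstats.read_sumstats(exp.sumstats_path, trait_id=trait_id)
            selected = instruments.select_by_threshold(assocs, exp.selection_threshold)
            for vid in selected.variant_ids:
                rep = screen.screen_variant(vid, catalogue)
                bundle["screen"].append(
                    {"trait_id": trait_id, "variant_id": vid,
                     "total_hits": rep.total_hits, "verdict": rep.verdict,
                     **{f"n_{c}": rep.counts[c] for c in screen.TRAIT_CLASSES}}
                )

    if plan.run_lenient:
        for exp in plan.exposures:
            if exp.trait.trait_id not in flagged or not exp.cohort_paths:
                continue
            per_cohort = _collect_cohorts(exp)
            inst = instruments.directional_consistency_filter(
                per_cohort, trait_id=exp.trait.trait_id
            )
            bundle["lenient"].append(
                {"trait_id": exp.trait.trait_id, "n_snps": inst.k,
                 "variant_ids": list(inst.variant_ids)}
            )
    return bundle


def _collect_cohorts(exp: ExposureSpec) -> dict[str, list[instruments.CohortAssociation]]:
    per_cohort: dict[str, list[instruments.CohortAssociation]] = {}
    cohort_names = ["discovery"] + [f"replication_{i}" for i in range(1, len(exp.cohort_paths))]
    for name, path in zip(cohort_names, exp.cohort_paths):
        for a in sumstats.read_sumstats(path, trait_id=exp.trait.trait_id):
            per_cohort.setdefault(a.variant_id, []).append(
                instruments.CohortAssociation(cohort_id=name, association=a)
            )
    return per_cohort


def run_reverse(plan: AnalysisPlan) -> pd.DataFrame:
    """Disease as exposure: clump instruments, estimate effect on each trait."""
    if not plan.reverse_exposure_path:
        raise ValueError("plan has no reverse exposure summary statistics")
    disease = sumstats.read_sumstats(
        plan.reverse_exposure_path, trait_id="disease", trait_type="binary"
    )
    hits = [a for a in disease if a.pvalue < plan.reverse_threshold]
    hits.sort(key=lambda a: (a.pvalue, a.variant_id))
    if plan.reverse_ld_path:
        from micromr.simulate import read_ld_matrix

        ld, header = read_ld_matrix(plan.reverse_ld_path)
        index = {vid: i for i, vid in enumerate(header)}
        aligned = [a for a in hits if a.variant_id in index]
        sub = [index[a.variant_id] for a in aligned]
        clumped = instruments.greedy_clump(
            aligned, ld[sub][:, sub], r2_threshold=plan.reverse_clump_r2
        )
    else:
        clumped = instruments.select_by_threshold(hits, plan.reverse_threshold)
    keep = set(clumped.variant_ids)
    disease_inst = [a for a in hits if a.variant_id in keep]

    rows: list[dict] = []
    for exp in plan.exposures:
        trait_assocs = sumstats.read_sumstats(
            exp.sumstats_path, trait_id=exp.trait.trait_id
        )
        pairs = sumstats.harmonize_many(disease_inst, trait_assocs)
        live = sumstats.surviving(pairs)
        pseudo_trait = sumstats.MicrobialTrait(
            trait_id=exp.trait.trait_id,
            taxon_level=exp.trait.taxon_level,
            display_name=exp.trait.display_name,
            measure="AB",  # reverse estimates are per-unit disease liability
        )
        if not live:
            rows.append(_row(pseudo_trait, "overall", None, status="no_instrument"))
            continue
        ests = (
            [estimators.wald_ratio(live[0])]
            if len(live) == 1
            else estimators.all_estimators(live, n_boot=plan.n_boot, seed=plan.seed)
        )
        for est in ests:
            rows.append(_row(pseudo_trait, "overall", est, status="ok"))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.insert(0, "direction", "reverse")
    return df


def write_report(
    plan: AnalysisPlan,
    forward: pd.DataFrame,
    sensitivity: dict | None = None,
    reverse: pd.DataFrame | None = None,
) -> dict:
    """Write results.tsv, sensitivity tables and a JSON manifest."""
    outdir = Path(plan.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    forward.to_csv(outdir / "results.tsv", sep="\t", index=False)
    if sensitivity is not None:
        sensdir = outdir / "sensitivity"
        sensdir.mkdir(exist_ok=True)
        for key in ("coloc", "screen", "lenient"):
            pd.DataFrame(sensitivity.get(key, [])).to_csv(
                sensdir / f"{key}.tsv", sep="\t", index=False
            )
    if reverse is not None:
        reverse.to_csv(outdir / "reverse.tsv", sep="\t", index=False)

    digest = hashlib.sha256(
        json.dumps(_plan_fingerprint(plan), sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": plan.seed,
        "config_sha256": digest,
        "n_forward_rows": int(len(forward)),
        "n_reverse_rows": int(len(reverse)) if reverse is not None else 0,
        "flagged": sensitivity.get("flagged", []) if sensitivity else [],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _plan_fingerprint(plan: AnalysisPlan) -> dict:
    return {
        "exposures": [
            (e.trait.trait_id, e.sumstats_path, e.selection_threshold, list(e.cohort_paths))
            for e in plan.exposures
        ],
        "outcomes": [(o.site, o.sumstats_path) for o in plan.outcomes],
        "seed": plan.seed,
        "toggles": [plan.run_coloc, plan.run_screen, plan.run_lenient, plan.run_reverse],
    }
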