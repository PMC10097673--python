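"""GWAS summary-statistics I/O and exposure/outcome harmonization.

Summary statistics are exchanged as delimited text with a header row; column
names are mapped onto :class:`VariantAssociation` fields through an explicit
``column_map`` so files with bespoke layouts can be read without rewriting
them. Harmonization aligns an exposure and an outcome record for the same
variant to a shared effect allele, resolving strand flips and palindromic
(A/T, G/C) ambiguity from allele frequency where possible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Palindromic variants whose minor-allele frequency exceeds this limit in
#: either dataset cannot be oriented from frequency and are dropped.
PALINDROMIC_MAF_LIMIT = 0.42

# Harmonization actions
KEPT = "kept"
OUTCOME_SIGN_FLIPPED = "outcome_sign_flipped"
STRAND_FLIPPED = "strand_flipped"
PALINDROMIC_INFERRED = "palindromic_inferred"
DROPPED_PALINDROMIC_AMBIGUOUS = "dropped_palindromic_ambiguous"
DROPPED_ALLELE_MISMATCH = "dropped_allele_mismatch"

HARMONIZED_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "exposure_beta",
    "exposure_se",
    "exposure_eaf",
    "outcome_beta",
    "outcome_se",
    "outcome_eaf",
    "action",
]


class SumstatsError(ValueError):
    """Configuration or usage error in summary-statistics handling."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive per-effect-allele estimate: a log odds ratio for
    binary traits, SD units for rank-normalized continuous traits.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int
    chromosome: str = ""
    position: int = 0
    eaf: float | None = None
    n_case: int | None = None
    n_control: int | None = None
    trait_id: str = ""
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise SumstatsError(
                f"{self.variant_id}: alleles must be single bases, got {ea}/{oa}"
            )
        if ea == oa:
            raise SumstatsError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise SumstatsError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"{self.variant_id}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsError(f"{self.variant_id}: eaf outside [0, 1]")
        if self.n < 2:
            raise SumstatsError(f"{self.variant_id}: n must be >= 2")
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"{self.variant_id}: bad trait_type {self.trait_type}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome associations aligned to a shared effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    exposure_beta: float
    exposure_se: float
    exposure_eaf: float | None
    outcome_beta: float
    outcome_se: float
    outcome_eaf: float | None
    action: str

    @property
    def dropped(self) -> bool:
        return self.action.startswith("dropped")


@dataclass(frozen=True)
class MicrobialTrait:
    """A taxon-level trait, measured as abundance (AB) or presence (PA)."""

    trait_id: str
    taxon_level: str
    display_name: str
    measure: str  # "AB" or "PA"
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.taxon_level not in ("C", "F", "G", "O", "P"):
            raise SumstatsError(f"bad taxon level {self.taxon_level!r}")
        if self.measure not in ("AB", "PA"):
            raise SumstatsError(f"measure must be AB or PA, got {self.measure!r}")
        if self.measure == "PA":
            if self.prevalence is None or not (0 < self.prevalence < 1):
                raise SumstatsError("PA traits require prevalence in (0, 1)")
        elif self.prevalence is not None:
            raise SumstatsError("prevalence is only meaningful for PA traits")


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "n")
_OPTIONAL_INT_FIELDS = ("n_case", "n_control")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = "\t",
    trait_id: str = "",
    trait_type: str = "continuous",
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into validated records.

    ``column_map`` maps field names to file column names; fields absent from
    the map (or mapped to missing columns) other than the mandatory ones are
    left at their defaults. Malformed rows are skipped with a logged warning
    carrying the 1-based data row number.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for fname in MANDATORY_FIELDS:
        col = cmap.get(fname, fname)
        if col not in df.columns:
            raise SumstatsError(f"{path}: mandatory column {col!r} ({fname}) missing")

    records: list[VariantAssociation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        try:
            records.append(_row_to_association(raw, cmap, trait_id, trait_type))
        except (SumstatsError, ValueError, TypeError) as exc:
            logger.warning("%s row %d skipped: %s", path, i, exc)
    return records


def _row_to_association(
    raw: Mapping[str, str],
    cmap: Mapping[str, str],
    trait_id: str,
    trait_type: str,
) -> VariantAssociation:
    def get(fname: str) -> str | None:
        col = cmap.get(fname, fname)
        val = raw.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            return None
        return val

    kwargs: dict = {
        "variant_id": get("variant_id"),
        "effect_allele": get("effect_allele"),
        "other_allele": get("other_allele"),
        "beta": float(get("beta")),
        "se": float(get("se")),
        "pvalue": float(get("pvalue")),
        "n": int(float(get("n"))),
    }
    if get("chromosome") is not None:
        kwargs["chromosome"] = get("chromosome")
    if get("position") is not None:
        kwargs["position"] = int(float(get("position")))
    if get("eaf") is not None:
        kwargs["eaf"] = float(get("eaf"))
    for fname in _OPTIONAL_INT_FIELDS:
        if get(fname) is not None:
            kwargs[fname] = int(float(get(fname)))
    kwargs["trait_id"] = get("trait_id") or trait_id
    kwargs["trait_type"] = get("trait_type") or trait_type
    return VariantAssociation(**kwargs)


def write_sumstats(
    assocs: Iterable[VariantAssociation], path: str | Path, *, sep: str = "\t"
) -> None:
    """Write associations as a TSV readable by :func:`read_sumstats`."""
    rows = []
    for a in assocs:
        row = {f.name: getattr(a, f.name) for f in fields(a)}
        rows.append(row)
    cols = [f.name for f in fields(VariantAssociation)]
    # repr keeps doubles exact through a text round-trip
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep=sep, index=False, float_format=lambda v: repr(float(v))
    )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _maf(eaf: float | None) -> float | None:
    return None if eaf is None else min(eaf, 1.0 - eaf)


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindromic_maf_limit: float = PALINDROMIC_MAF_LIMIT,
) -> HarmonizedPair:
    """Align outcome to the exposure's effect allele.

    Matching rules, applied in order:

    1. identical alleles → ``kept``;
    2. swapped alleles → outcome beta negated, eaf complemented
       (``outcome_sign_flipped``);
    3. strand-complement match → outcome alleles relabelled
       (``strand_flipped``; complement + swap also negates the beta);
    4. palindromic pairs are oriented from allele frequency: dropped when the
       MAF exceeds ``palindromic_maf_limit`` in either dataset or an eaf is
       missing, otherwise the outcome is flipped iff the two eafs fall on
       opposite sides of 0.5 (``palindromic_inferred``);
    5. anything else → ``dropped_allele_mismatch``.
    """
    if exposure.variant_id != outcome.variant_id:
        raise SumstatsError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    def pair(outcome_beta: float, outcome_eaf: float | None, action: str) -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=exposure.variant_id,
            effect_allele=ea,
            other_allele=oa,
            exposure_beta=exposure.beta,
            exposure_se=exposure.se,
            exposure_eaf=exposure.eaf,
            outcome_beta=outcome_beta,
            outcome_se=outcome.se,
            outcome_eaf=outcome_eaf,
            action=action,
        )

    if is_palindromic(ea, oa):
        if is_palindromic(o_ea, o_oa) and {ea, oa} == {o_ea, o_oa}:
            return _harmonize_palindromic(exposure, outcome, palindromic_maf_limit, pair)
        return pair(outcome.beta, outcome.eaf, DROPPED_ALLELE_MISMATCH)

    if (o_ea, o_oa) == (ea, oa):
        return pair(outcome.beta, outcome.eaf, KEPT)
    if (o_ea, o_oa) == (oa, ea):
        return pair(-outcome.beta, _complement_eaf(outcome.eaf), OUTCOME_SIGN_FLIPPED)

    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (ea, oa):
        return pair(outcome.beta, outcome.eaf, STRAND_FLIPPED)
    if (c_ea, c_oa) == (oa, ea):
        return pair(-outcome.beta, _complement_eaf(outcome.eaf), STRAND_FLIPPED)

    return pair(outcome.beta, outcome.eaf, DROPPED_ALLELE_MISMATCH)


def _complement_eaf(eaf: float | None) -> float | None:
    return None if eaf is None else 1.0 - eaf


def _harmonize_palindromic(exposure, outcome, maf_limit, pair) -> HarmonizedPair:
    e_maf, o_maf = _maf(exposure.eaf), _maf(outcome.eaf)
    if e_maf is None or o_maf is None:
        # no frequency, no inference: conservative drop
        logger.info("%s: palindromic with missing eaf, dropped", exposure.variant_id)
        return pair(outcome.beta, outcome.eaf, DROPPED_PALINDROMIC_AMBIGUOUS)
    if e_maf > maf_limit or o_maf > maf_limit:
        return pair(outcome.beta, outcome.eaf, DROPPED_PALINDROMIC_AMBIGUOUS)
    concordant = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
    if concordant:
        return pair(outcome.beta, outcome.eaf, PALINDROMIC_INFERRED)
    return pair(-outcome.beta, 1.0 - outcome.eaf, PALINDROMIC_INFERRED)


def harmonize_pair_again(p: HarmonizedPair) -> HarmonizedPair:
    """Re-harmonize an already harmonized (non-dropped) pair; idempotence check."""
    if p.dropped:
        return p
    return replace(p, action=KEPT)


def harmonize_many(
    exposures: Sequence[VariantAssociation],
    outcomes: Sequence[VariantAssociation],
    palindromic_maf_limit: float = PALINDROMIC_MAF_LIMIT,
) -> list[HarmonizedPair]:
    """Harmonize by variant_id intersection; exposure order is preserved."""
    by_id = {o.variant_id: o for o in outcomes}
    out = []
    for e in exposures:
        o = by_id.get(e.variant_id)
        if o is None:
            logger.info("%s absent from outcome data, skipped", e.variant_id)
            continue
        out.append(harmonize(e, o, palindromic_maf_limit))
    return out


def write_harmonized(pairs: Iterable[HarmonizedPair], path: str | Path) -> None:
    """Write harmonized pairs (including dropped ones) as a fixed-layout TSV."""
    rows = [
        {c: getattr(p, c) for c in HARMONIZED_COLUMNS}
        for p in pairs
    ]
    pd.DataFrame(rows, columns=HARMONIZED_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=lambda v: repr(float(v))
    )


def read_harmonized(path: str | Path) -> list[HarmonizedPair]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    pairs = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        for k in ("exposure_eaf", "outcome_eaf"):
            if pd.isna(d.get(k)):
                d[k] = None
        pairs.append(HarmonizedPair(**{c: d[c] for c in HARMONIZED_COLUMNS}))
    return pairs


def surviving(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """Non-dropped pairs, ready for estimation."""
    return [p for p in pairs if not p.dropped]
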