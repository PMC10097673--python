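"""Offline pleiotropy screening against a local association catalogue.

Stands in for manual PhenoScanner / OpenGWAS-style lookups: a versioned TSV
catalogue of variant–trait associations is filtered at a lenient multiple
testing threshold and hits are grouped by trait class.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_CLASSES = ("complex_trait", "eQT", "metabolite", "mQT", "protein", "other")

#: Screening threshold: a 10% Bonferroni correction over 1000 catalogue rows.
DEFAULT_THRESHOLD = 1e-4
#: More complex-trait hits than this flags the instrument as high concern.
DEFAULT_CONCERN_CUTOFF = 10

CATALOGUE_COLUMNS = ["variant_id", "trait_name", "trait_class", "pvalue", "source"]


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogueEntry:
    variant_id: str
    trait_name: str
    trait_class: str
    pvalue: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ScreenError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if self.trait_class not in TRAIT_CLASSES:
            raise ScreenError(f"unknown trait_class {self.trait_class!r}")


@dataclass(frozen=True)
class ScreenReport:
    variant_id: str
    threshold: float
    counts: dict[str, int]
    flagged_traits: dict[str, tuple[str, ...]]
    concern_cutoff: int = DEFAULT_CONCERN_CUTOFF

    @property
    def total_hits(self) -> int:
        return sum(self.counts.values())

    @property
    def verdict(self) -> str:
        if self.counts.get("complex_trait", 0) > self.concern_cutoff:
            return "high_pleiotropy_concern"
        return "low_pleiotropy_concern"


def load_catalogue(path: str | Path, *, sep: str = "\t") -> list[CatalogueEntry]:
    """Read a catalogue TSV; malformed rows are skipped with a logged warning."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in CATALOGUE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ScreenError(f"{path}: missing columns {missing}")
    entries: list[CatalogueEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        src = d.get("source", "")
        if src is None or (isinstance(src, float) and pd.isna(src)):
            src = ""
        try:
            entries.append(
                CatalogueEntry(
                    variant_id=str(d["variant_id"]),
                    trait_name=str(d["trait_name"]),
                    trait_class=str(d["trait_class"]),
                    pvalue=float(d["pvalue"]),
                    source=str(src),
                )
            )
        except (ScreenError, ValueError, TypeError) as exc:
            logger.warning("%s row %d skipped: %s", path, i, exc)
    return entries


def write_catalogue(entries: Iterable[CatalogueEntry], path: str | Path) -> None:
    rows = [
        {
            "variant_id": e.variant_id,
            "trait_name": e.trait_name,
            "trait_class": e.trait_class,
            "pvalue": e.pvalue,
            "source": e.source,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=CATALOGUE_COLUMNS).to_csv(path, sep="\t", index=False)


def screen_variant(
    variant_id: str,
    catalogue: Sequence[CatalogueEntry],
    threshold: float = DEFAULT_THRESHOLD,
    concern_cutoff: int = DEFAULT_CONCERN_CUTOFF,
) -> ScreenReport:
    """Catalogue hits for one variant with p strictly below the threshold."""
    hits = [e for e in catalogue if e.variant_id == variant_id and e.pvalue < threshold]
    if not any(e.variant_id == variant_id for e in catalogue):
        logger.info("%s absent from catalogue; empty report", variant_id)
    counts = Counter(e.trait_class for e in hits)
    flagged = {
        cls: tuple(e.trait_name for e in hits if e.trait_class == cls)
        for cls in TRAIT_CLASSES
        if counts.get(cls)
    }
    return ScreenReport(
        variant_id=variant_id,
        threshold=threshold,
        counts={cls: counts.get(cls, 0) for cls in TRAIT_CLASSES},
        flagged_traits=flagged,
        concern_cutoff=concern_cutoff,
    )


def derive_threshold(n_results: int = 1000, fraction: float = 0.10) -> float:
    """Fractional Bonferroni threshold: ``fraction / n_results``."""
    if n_results < 1:
        raise ScreenError("n_results must be >= 1")
    return fraction / n_results


def write_report(report: ScreenReport, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    rows = [
        {
            "variant_id": report.variant_id,
            "trait_class": cls,
            "trait_name": name,
            "threshold": report.threshold,
        }
        for cls, names in report.flagged_traits.items()
        for name in names
    ]
    pd.DataFrame(
        rows, columns=["variant_id", "trait_class", "trait_name", "threshold"]
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "variant_id": report.variant_id,
            "threshold": report.threshold,
            "counts": report.counts,
            "total_hits": report.total_hits,
            "verdict": report.verdict,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
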