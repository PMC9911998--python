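"""RBC phenotype inference from JK diplotypes, and serotype concordance.

Two phenotype tables are supported side by side.  Under ``published`` every
allele keeps its ISBT category; under ``revised`` the serology-corrected
categories apply, in which the common synonymous changes c.588A>G and
c.810G>A do not attenuate or silence antigen expression (so e.g. the
c.810A-carrying JK2 allele expresses normal JK:2, and the JK*01N.20
constellation expresses normal JK:1), while truncations upstream of the
antigen-determining codon 280 remain null.

An allele contributes to exactly one antigen (JK1 when it lacks c.838A, JK2
when it carries it) at a level normal / weak / null / unknown; a diplotype's
per-antigen result is positive if any contributing allele is normal, unknown
if the best determinate contribution cannot override an unknown one, weak if
the best contribution is weak, and negative when every contribution is null
or the antigen has no contributing allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional

import pandas as pd

from .alleledb import Allele, AlleleDB
from .calling import Diplotype

__all__ = [
    "PhenotypePrediction",
    "SerotypeRecord",
    "ConcordanceReport",
    "allele_expression",
    "predict_phenotype",
    "concordance_report",
    "published_phenotype_label",
    "revised_serotype_label",
    "audit_validation_phenotypes",
]

_LEVELS = ("normal", "weak", "null", "unknown")


@dataclass(frozen=True)
class PhenotypePrediction:
    """Per-antigen RBC phenotype: positive / weak / negative / unknown."""

    jk1: str
    jk2: str
    table_version: str = "revised"

    @property
    def display(self) -> str:
        parts = []
        for antigen, value in (("1", self.jk1), ("2", self.jk2)):
            parts.append(
                {"positive": antigen, "weak": f"{antigen}weak",
                 "negative": f"-{antigen}", "unknown": f"?{antigen}"}[value]
            )
        return "JK:" + ",".join(parts)

    @property
    def predictable(self) -> bool:
        return "unknown" not in (self.jk1, self.jk2)


@dataclass(frozen=True)
class SerotypeRecord:
    """One serological determination: JK1/JK2 positivity and, when the
    secondary tube method was run, agglutination intensity on the 0-4 scale
    (4 strongest)."""

    sample_id: str
    jk1: str  # 'pos' | 'neg'
    jk2: str
    intensity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.jk1 not in ("pos", "neg") or self.jk2 not in ("pos", "neg"):
            raise ValueError("serotype values must be 'pos' or 'neg'")
        if self.intensity is not None and not 0 <= self.intensity <= 4:
            raise ValueError("agglutination intensity must be within 0-4")


def allele_expression(allele: Allele, version: str = "revised") -> tuple[str, str]:
    """(antigen, level) contributed by one allele under a table version.

    The antigen is fixed by the c.838 lineage; the level comes from the
    allele's stored category (``unknown`` for novel alleles the published
    table refuses to phenotype)."""
    if version not in ("published", "revised"):
        raise ValueError(f"unknown phenotype table version {version!r}")
    category = allele.phenotype_published if version == "published" else allele.phenotype_revised
    if category == "unknown":
        return allele.lineage, "unknown"
    lineage, _, level = category.partition("_")
    return lineage, level or "normal"


def _antigen_call(levels: list[str]) -> str:
    if "normal" in levels:
        return "positive"
    if "unknown" in levels:
        return "unknown"
    if "weak" in levels:
        return "weak"
    return "negative"


def predict_phenotype(
    dip: Diplotype, db: AlleleDB, version: str = "revised"
) -> Optional[PhenotypePrediction]:
    """Phenotype of a uniquely called (or novel-named) diplotype; ``None``
    ("not predictable") for ambiguous or no-call diplotypes.

    Novel alleles absent from the database contribute ``unknown`` on the
    lineage their variants imply."""
    if dip.status not in ("unique", "novel") or dip.alleles is None:
        return None
    levels: dict[str, list[str]] = {"JK1": [], "JK2": []}
    for name in dip.alleles:
        if name in db:
            antigen, level = allele_expression(db[name], version)
        else:
            variants = dip.novel_definitions.get(name, frozenset())
            antigen = "JK2" if any(v.position == (838, 0) for v in variants) else "JK1"
            level = "unknown"
        levels[antigen].append(level)
    return PhenotypePrediction(
        jk1=_antigen_call(levels["JK1"]),
        jk2=_antigen_call(levels["JK2"]),
        table_version=version,
    )


@dataclass(frozen=True)
class ConcordanceReport:
    table: pd.DataFrame  # sample, predicted, serotype, result
    concordant: int
    discordant: int
    not_evaluable: int

    @property
    def evaluated(self) -> int:
        return self.concordant + self.discordant

    @property
    def discrepancy_rate_pct(self) -> float:
        """100 x discordant / evaluated, two decimals (half-up)."""
        if not self.evaluated:
            return 0.0
        rate = Decimal(100 * self.discordant) / Decimal(self.evaluated)
        return float(rate.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


_PUBLISHED_LABELS = {
    "JK1": "JK:1", "JK1_weak": "JK:1weak", "JK1_null": "JK:Null",
    "JK2": "JK:2", "JK2_weak": "JK:2weak", "JK2_null": "JK:Null",
    "unknown": "Unknown",
}
_SEROTYPE_LABELS = {
    "JK1": "JK:1", "JK1_weak": "JK:1weak", "JK1_null": "JK:1-",
    "JK2": "JK:2", "JK2_weak": "JK:2weak", "JK2_null": "JK:2-",
}


def published_phenotype_label(allele: Allele) -> str:
    """The presumed-RBC-phenotype label implied by the ISBT category."""
    return _PUBLISHED_LABELS[allele.phenotype_published]


def revised_serotype_label(allele: Allele) -> Optional[str]:
    """The serotype label the revised category predicts for the allele's own
    antigen (None when the revision leaves the allele unphenotyped)."""
    return _SEROTYPE_LABELS.get(allele.phenotype_revised)


def audit_validation_phenotypes(db: AlleleDB) -> tuple[dict[str, bool], dict[str, bool]]:
    """Reproduce the validation table's phenotype columns from the database.

    Returns (published, revised) audits: per allele of the validation set,
    whether the ISBT category reproduces the recorded presumed phenotype and
    whether the revised category reproduces the recorded serotype (alleles
    without a serotype entry are skipped)."""
    published: dict[str, bool] = {}
    revised: dict[str, bool] = {}
    for allele in db.from_sources("table3"):
        name = str(allele.name)
        presumed = allele.metadata.get("presumed_phenotype", "")
        if presumed:
            published[name] = published_phenotype_label(allele) == presumed
        serotype = allele.metadata.get("serotype", "")
        if serotype and serotype != "-":
            revised[name] = revised_serotype_label(allele) == serotype
    return published, revised


def _positive(value: str) -> bool:
    return value in ("positive", "weak")


def concordance_report(
    predictions: Mapping[str, Optional[PhenotypePrediction]],
    serotypes: Iterable[SerotypeRecord],
) -> ConcordanceReport:
    """Compare predicted phenotypes with serotype records per sample.

    Weak expression counts as antigen-positive (intensity is reported but
    compared only qualitatively).  Samples without a prediction, with an
    unknown antigen, or without a matching serotype are not evaluable and
    leave the denominator."""
    rows = []
    concordant = discordant = not_evaluable = 0
    by_id = {s.sample_id: s for s in serotypes}
    for sample_id, pred in predictions.items():
        sero = by_id.get(sample_id)
        if sero is None or pred is None or not pred.predictable:
            not_evaluable += 1
            rows.append((sample_id, pred.display if pred else "-", "-", "not_evaluable"))
            continue
        match = (_positive(pred.jk1) == (sero.jk1 == "pos")) and (
            _positive(pred.jk2) == (sero.jk2 == "pos")
        )
        if match:
            concordant += 1
        else:
            discordant += 1
        rows.append(
            (
                sample_id,
                pred.display,
                f"JK:{'1' if sero.jk1 == 'pos' else '-1'},{'2' if sero.jk2 == 'pos' else '-2'}",
                "concordant" if match else "discordant",
            )
        )
    unmatched = set(by_id) - set(predictions)
    for sample_id in sorted(unmatched):
        not_evaluable += 1
        rows.append((sample_id, "-", "-", "not_evaluable"))
    table = pd.DataFrame(rows, columns=["sample", "predicted", "serotype", "result"])
    return ConcordanceReport(table, concordant, discordant, not_evaluable)
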