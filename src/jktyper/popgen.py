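"""Direct-count allele frequencies per donor panel, and cohort summaries.

Absolute allele frequencies are determined by direct counting: each
genotyped sample contributes two alleles (homozygotes count twice), no-calls
leave both numerator and denominator, and the percentage frequency of an
allele in a panel is 100 x count / (2 x genotyped samples), rounded half-up
to two decimals.  Lineage rollups (JK1 / JK2 totals) classify each allele by
presence of the antigen-determining c.838A change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alleledb import AlleleDB, data_path
from .calling import Diplotype

__all__ = [
    "PANEL_CODES",
    "PanelFrequencyTable",
    "CohortSummary",
    "round_pct",
    "count_alleles",
    "frequency_table_from_counts",
    "carrier_fraction",
    "summarize_cohort",
    "load_cohort_table",
    "load_table5_counts",
]

#: Donor panels by geographical area of the declared mother country.
PANEL_CODES = (
    "OTH", "TUR", "EEKCA", "SYR", "IRAN", "SAS", "NAF",
    "ARPE", "IRAQ", "SEEA", "CSAM", "SSAF", "WEUR",
)


def round_pct(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Half-up percentage rounding as used throughout the frequency tables."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PanelFrequencyTable:
    """Allele counts and percentages per donor panel.

    ``counts`` is a long-format frame (panel, allele, count, percent);
    ``genotyped_n`` maps panel -> genotyped samples.  Lineage rollups are
    stored under the pseudo-alleles ``JK1_total`` / ``JK2_total``.
    """

    counts: pd.DataFrame
    genotyped_n: Mapping[str, int]

    def count(self, panel: str, allele: str) -> int:
        sel = self.counts[(self.counts.panel == panel) & (self.counts.allele == allele)]
        return int(sel["count"].sum())

    def percent(self, panel: str, allele: str) -> float:
        return round_pct(self.count(panel, allele), 2 * self.genotyped_n.get(panel, 0))

    def wide(self) -> pd.DataFrame:
        """Table-5-shaped matrix: allele rows, panel columns, 'count (pct)'."""
        panels = [p for p in self.genotyped_n if self.genotyped_n[p] > 0]
        alleles = sorted(self.counts.allele.unique())
        rows = []
        for allele in alleles:
            row = {"allele": allele}
            for panel in panels:
                c = self.count(panel, allele)
                row[panel] = f"{c} ({self.percent(panel, allele):.2f})" if c else "-"
            rows.append(row)
        return pd.DataFrame(rows)

    def conservation_ok(self) -> bool:
        """Per panel, allele counts (without rollups) must sum to exactly
        twice the genotyped sample count."""
        plain = self.counts[~self.counts.allele.str.endswith("_total")]
        for panel, n in self.genotyped_n.items():
            if int(plain[plain.panel == panel]["count"].sum()) != 2 * n:
                return False
        return True


def _lineage(db: Optional[AlleleDB], dip: Diplotype, name: str) -> str:
    if db is not None and name in db:
        return db[name].lineage
    variants = dip.novel_definitions.get(name, frozenset())
    return "JK2" if any(v.position == (838, 0) for v in variants) else "JK1"


def count_alleles(
    samples: Iterable[tuple[str, str, Diplotype]],
    db: Optional[AlleleDB] = None,
) -> PanelFrequencyTable:
    """Direct counting of alleles over (sample_id, panel, diplotype) records.

    Only resolved diplotypes (unique or novel-named) enter the table;
    no-calls are excluded from numerator and denominator; unlabeled samples
    are assigned to the OTH panel with a warning."""
    counts: dict[tuple[str, str], int] = {}
    genotyped: dict[str, int] = {}
    for sample_id, panel, dip in samples:
        if not panel:
            warnings.warn(f"sample {sample_id} has no panel label; assigned OTH")
            panel = "OTH"
        if dip.status == "no_call" or dip.alleles is None:
            continue
        genotyped[panel] = genotyped.get(panel, 0) + 1
        for name in dip.alleles:
            counts[(panel, name)] = counts.get((panel, name), 0) + 1
            rollup = f"{_lineage(db, dip, name)}_total"
            counts[(panel, rollup)] = counts.get((panel, rollup), 0) + 1
    rows = []
    for (panel, allele), count in sorted(counts.items()):
        rows.append(
            {
                "panel": panel,
                "allele": allele,
                "count": count,
                "percent": round_pct(count, 2 * genotyped[panel]),
            }
        )
    frame = pd.DataFrame(rows, columns=["panel", "allele", "count", "percent"])
    return PanelFrequencyTable(frame, genotyped)


def frequency_table_from_counts(
    counts: pd.DataFrame, genotyped_n: Mapping[str, int]
) -> PanelFrequencyTable:
    """Build a frequency table from a printed-count matrix (allele rows,
    panel columns) and per-panel genotyped totals, recomputing percentages
    with the direct-count formula."""
    rows = []
    panel_cols = [c for c in counts.columns if c != "allele"]
    for _, r in counts.iterrows():
        for panel in panel_cols:
            n = genotyped_n.get(panel, 0)
            c = int(r[panel])
            if c == 0:
                continue
            rows.append(
                {
                    "panel": panel,
                    "allele": r["allele"],
                    "count": c,
                    "percent": round_pct(c, 2 * n),
                }
            )
    frame = pd.DataFrame(rows, columns=["panel", "allele", "count", "percent"])
    return PanelFrequencyTable(frame, dict(genotyped_n))


def carrier_fraction(
    samples: Iterable[tuple[str, str, Diplotype]],
    allele_names: Sequence[str],
    decimals: int = 1,
) -> tuple[int, int, float]:
    """Percent of genotyped samples carrying at least one listed allele.

    Counts samples, not alleles; returns (carriers, genotyped, percent)."""
    wanted = set(allele_names)
    carriers = genotyped = 0
    for _, _, dip in samples:
        if dip.status == "no_call" or dip.alleles is None:
            continue
        genotyped += 1
        if wanted & set(dip.alleles):
            carriers += 1
    return carriers, genotyped, round_pct(carriers, genotyped, decimals)


@dataclass(frozen=True)
class CohortSummary:
    validation_n: int
    prospective_n: int
    no_calls: int

    def __post_init__(self) -> None:
        if min(self.validation_n, self.prospective_n, self.no_calls) < 0:
            raise ValueError("cohort counts must be nonnegative")

    @property
    def total_n(self) -> int:
        return self.validation_n + self.prospective_n

    @property
    def genotyped(self) -> int:
        return self.total_n - self.no_calls

    @property
    def prospective_success_pct(self) -> float:
        """Successfully genotyped fraction of the prospective cohort (the
        validation set was fully genotyped; no-calls are prospective)."""
        return round_pct(self.prospective_n - self.no_calls, self.prospective_n, 1)

    @property
    def failure_rate_pct(self) -> float:
        """No-call rate across the entire sample set, two decimals."""
        return round_pct(self.no_calls, self.total_n, 2)


def summarize_cohort(
    validation_n: int, prospective_n: int, no_calls: int
) -> CohortSummary:
    """Cohort totals: genotyped = validation + prospective - no_calls."""
    return CohortSummary(validation_n, prospective_n, no_calls)


def load_cohort_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """The packaged per-panel cohort table (validation / prospective /
    no-call / genotyped counts, plus a Total row)."""
    return pd.read_csv(path or data_path("cohort.tsv"), sep="\t")


def load_table5_counts(path: Optional[str | Path] = None) -> pd.DataFrame:
    """The packaged panel-frequency count matrix (alleles seen at least five
    times plus all referenced alleles, counts per panel)."""
    return pd.read_csv(path or data_path("table5_counts.tsv"), sep="\t")
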