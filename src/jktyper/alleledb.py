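"""Allele database for the JK system.

The database holds every allele as its *absolute* variant set relative to the
JK*01 reference (an allele row names a background allele plus additional
changes; expansion is the union of the background's absolute set and the
row's changes).  Shipped fixtures transcribe the published allele tables:

* ``isbt.tsv``   — ISBT-referenced allele definitions (the backgrounds),
* ``table3.tsv`` — the 551-sample validation set (16 alleles, serotypes),
* ``table4.tsv`` — the prospective set (95 alleles, observation counts).

Each allele carries two phenotype categories: ``phenotype_published`` (the
ISBT assignment) and ``phenotype_revised`` (the serology-corrected
assignment, under which the synonymous changes c.588A>G and c.810G>A do not
alter antigen expression).  Categories are strings from
:data:`PHENOTYPE_CATEGORIES` (lineage JK1/JK2 plus expression level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    AlleleName,
    CoordinateError,
    ExonMap,
    JKError,
    ParseError,
    Variant,
    default_exon_map,
    format_hgvs_c,
    make_provisional_name,
    parse_allele_name,
    parse_hgvs_c,
)

__all__ = [
    "Allele",
    "AlleleDB",
    "AlleleDBError",
    "PHENOTYPE_CATEGORIES",
    "NOMENCLATURE_EXCEPTIONS",
    "load_allele_db",
    "default_db",
    "expand_variants",
    "data_path",
]

PHENOTYPE_CATEGORIES = frozenset(
    {"JK1", "JK1_weak", "JK1_null", "JK2", "JK2_weak", "JK2_null", "unknown"}
)

#: The c.838G>A (p.Asp280Asn) JK1/JK2-determining position.
JK2_POSITION = (838, 0)

#: Printed allele names that the nomenclature engine cannot regenerate from
#: the tabulated variants; maps printed name -> the engine-derived form.
#: ``279C_T`` swaps ref/alt relative to the printed change c.279T>C, and
#: ``E9-7T_G`` labels c.812-7T>C with the wrong exon anchor (exon 8 starts at
#: c.812) and alternate base.  Both printed forms are kept as database keys.
NOMENCLATURE_EXCEPTIONS: dict[str, str] = {
    "JK*01W.01.279C_T_588A_G": "JK*01W.01.279T_C_588A_G",
    "JK*01W.01.588A_G_E9-7T_G": "JK*01W.01.588A_G_E8-7T_C",
}


class AlleleDBError(JKError, ValueError):
    """Aggregated validation failure while loading an allele table."""


@dataclass(frozen=True)
class Allele:
    """A named JK haplotype: background allele plus additional variants,
    expanded to the full change set relative to JK*01."""

    name: AlleleName
    background: AlleleName
    variants: frozenset[Variant]
    phenotype_published: str = "unknown"
    phenotype_revised: str = "unknown"
    referenced: bool = False
    observations: int = 0
    sources: tuple[str, ...] = ()
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phenotype_published not in PHENOTYPE_CATEGORIES:
            raise AlleleDBError(f"{self.name}: bad category {self.phenotype_published!r}")
        if self.phenotype_revised not in PHENOTYPE_CATEGORIES:
            raise AlleleDBError(f"{self.name}: bad category {self.phenotype_revised!r}")
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise AlleleDBError(f"{self.name}: duplicate variant positions")

    @property
    def lineage(self) -> str:
        """JK2 if the allele carries c.838A, else JK1 (reference lineage)."""
        return "JK2" if any(v.position == JK2_POSITION for v in self.variants) else "JK1"

    @property
    def positions(self) -> frozenset[tuple[int, int]]:
        return frozenset(v.position for v in self.variants)

    def base_at(self, position: tuple[int, int], ref: str) -> str:
        for v in self.variants:
            if v.position == position:
                return v.alt_symbol
        return ref

    def extras_relative_to(self, other: "Allele") -> frozenset[Variant]:
        return self.variants - other.variants


def expand_variants(
    background: frozenset[Variant], extras: Iterable[Variant]
) -> frozenset[Variant]:
    """Union of a background's absolute variant set with additional changes.

    Idempotent (re-listing a background variant is tolerated); a different
    alternate at an already-variant position is a contradiction.
    """
    merged: dict[tuple[int, int, str], Variant] = {v.key: v for v in background}
    for v in extras:
        prev = merged.get(v.key)
        if prev is None:
            merged[v.key] = v
        elif prev.alt_symbol != v.alt_symbol:
            raise AlleleDBError(
                f"contradictory alternates at {format_hgvs_c(v)} vs {format_hgvs_c(prev)}"
            )
        elif v.aa_change and not prev.aa_change:
            merged[v.key] = v
    return frozenset(merged.values())


@dataclass
class AlleleDB:
    """Name-keyed collection of alleles plus the exon map."""

    alleles: dict[str, Allele]
    exon_map: ExonMap
    version: str = "isbt-v6.0+provisional"

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __getitem__(self, name: str) -> Allele:
        return self.alleles[name]

    def __iter__(self):
        return iter(self.alleles.values())

    def __len__(self) -> int:
        return len(self.alleles)

    # -- position bookkeeping ------------------------------------------------
    @property
    def positions(self) -> tuple[tuple[int, int], ...]:
        """All variant positions known to the database, sorted."""
        pos: set[tuple[int, int]] = set()
        for a in self:
            pos.update(a.positions)
        return tuple(sorted(pos))

    def ref_symbol(self, position: tuple[int, int]) -> str:
        """Reference base at a database position ('N' when the tables do not
        print one, e.g. at indel anchors)."""
        for a in self:
            for v in a.variants:
                if v.position == position and v.kind == "substitution":
                    return v.ref
        return "N"

    def variant_at(self, position: tuple[int, int], alt_symbol: str) -> Optional[Variant]:
        for a in self:
            for v in a.variants:
                if v.position == position and v.alt_symbol == alt_symbol:
                    return v
        return None

    def from_sources(self, source: str) -> list[Allele]:
        return [a for a in self if source in a.sources]

    # -- queries -------------------------------------------------------------
    def alleles_matching(
        self, observed: Mapping[tuple[int, int], str]
    ) -> list[Allele]:
        """Alleles whose variant pattern restricted to the queried positions
        equals the queried haplotype (a position -> base-symbol mapping)."""
        out = []
        for a in self:
            ok = True
            for pos, base in observed.items():
                if a.base_at(pos, self.ref_symbol(pos)) != base:
                    ok = False
                    break
            if ok:
                out.append(a)
        return out

    def haplotype_projection(self, name: str, positions: Sequence[tuple[int, int]]) -> tuple[str, ...]:
        a = self[name]
        return tuple(a.base_at(p, self.ref_symbol(p)) for p in positions)

    def audit_names(self) -> dict[str, bool]:
        """Regenerate each nonreferenced allele's provisional name from its
        background and extra variants; True where the engine reproduces the
        stored name.  Exceptions in :data:`NOMENCLATURE_EXCEPTIONS` are
        audited against their documented engine-derived form instead."""
        results: dict[str, bool] = {}
        for a in self:
            if a.referenced or a.name.is_base:
                continue
            bg = self[str(a.background)]
            extras = sorted(a.extras_relative_to(bg), key=lambda v: v.key)
            regenerated = str(make_provisional_name(a.background, extras, self.exon_map))
            expected = NOMENCLATURE_EXCEPTIONS.get(str(a.name), str(a.name))
            results[str(a.name)] = regenerated == expected
        return results


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_COLUMNS = ("name", "background", "additional_changes", "protein_changes")


def _parse_changes(changes: str, proteins: str, row_label: str) -> list[Variant]:
    if changes in ("", "-"):
        return []
    ctoks = changes.split(";")
    ptoks = proteins.split(";") if proteins not in ("", "-") else [""] * len(ctoks)
    if len(ptoks) != len(ctoks):
        raise AlleleDBError(f"{row_label}: {len(ctoks)} changes but {len(ptoks)} protein tokens")
    out = []
    for c, p in zip(ctoks, ptoks):
        try:
            out.append(parse_hgvs_c(c.strip(), p.strip() or None))
        except ParseError as exc:
            raise AlleleDBError(f"{row_label}: {exc}") from exc
    return out


def _reference_allele() -> Allele:
    return Allele(
        name=AlleleName("01"),
        background=AlleleName("01"),
        variants=frozenset(),
        phenotype_published="JK1",
        phenotype_revised="JK1",
        referenced=True,
        sources=("implicit",),
    )


def load_allele_db(
    path: str | Path,
    exon_map: Optional[ExonMap] = None,
    base: Optional[AlleleDB] = None,
    source: Optional[str] = None,
) -> AlleleDB:
    """Load an allele-table TSV into an :class:`AlleleDB`.

    Columns: name, background, additional_changes (semicolon-joined HGVS-like
    tokens), protein_changes (aligned amino-acid tokens, ``=`` synonymous,
    ``-`` intronic, ``fs``/``splice``/in-frame-del tokens), plus optional
    phenotype_published, phenotype_revised, referenced, observations, and
    free metadata columns (dbsnp, genbank, gnomad_maf, serotype, ...).

    Backgrounds must resolve within the file, the ``base`` database, or the
    implicit JK*01 reference.  Rows whose name already exists must agree with
    the existing variant set (their metadata is merged); validation problems
    are aggregated into one :class:`AlleleDBError` naming row numbers.
    """
    exon_map = exon_map or (base.exon_map if base else default_exon_map())
    source = source or Path(path).stem
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    for col in _COLUMNS:
        if col not in df.columns:
            if len(df.columns) == 0 and len(df) == 0:
                df = pd.DataFrame(columns=list(_COLUMNS))
                break
            raise AlleleDBError(f"{path}: missing column {col!r}")

    alleles: dict[str, Allele] = {}
    if base is not None:
        alleles.update(base.alleles)
    alleles.setdefault("JK*01", _reference_allele())

    errors: list[str] = []
    pending = list(df.itertuples())
    seen_in_file: set[str] = set()
    # multi-pass resolution: the background graph is acyclic, rows may be in
    # any order as long as every background is eventually resolvable
    progress = True
    while pending and progress:
        progress = False
        still = []
        for row in pending:
            label = f"{Path(path).name} row {row.Index + 2}"
            name = row.name.strip()
            bg_name = (row.background or "").strip()
            if bg_name in ("", "-"):
                bg_name = "JK*01"
            if name in seen_in_file:
                errors.append(f"{label}: duplicate name {name}")
                progress = True
                continue
            if bg_name not in alleles and bg_name != name:
                still.append(row)
                continue
            try:
                parsed_name = parse_allele_name(name)
                extras = _parse_changes(row.additional_changes, row.protein_changes, label)
                bg = alleles[bg_name] if bg_name != name else _reference_allele()
                variants = expand_variants(bg.variants, extras)
                for v in variants:
                    if not v.is_intronic and v.cds_pos > exon_map.cds_end:
                        raise AlleleDBError(
                            f"{label}: {format_hgvs_c(v)} outside modeled region"
                        )
                meta = {
                    c: getattr(row, c)
                    for c in df.columns
                    if c not in _COLUMNS
                    and c not in ("phenotype_published", "phenotype_revised", "referenced", "observations")
                    and getattr(row, c) != ""
                }
                allele = Allele(
                    name=parsed_name,
                    background=parse_allele_name(bg_name),
                    variants=variants,
                    phenotype_published=getattr(row, "phenotype_published", "") or "unknown",
                    phenotype_revised=getattr(row, "phenotype_revised", "") or "unknown",
                    referenced=str(getattr(row, "referenced", "0")) in ("1", "True", "true"),
                    observations=int(getattr(row, "observations", "0") or 0),
                    sources=(source,),
                    metadata=meta,
                )
            except (JKError, ValueError) as exc:
                errors.append(str(exc) if str(exc).startswith(label) else f"{label}: {exc}")
                progress = True
                seen_in_file.add(name)
                continue
            existing = alleles.get(name)
            if existing is not None and "implicit" not in existing.sources:
                if existing.variants != allele.variants:
                    errors.append(f"{label}: {name} redefined with a different variant set")
                else:
                    alleles[name] = replace(
                        existing,
                        observations=existing.observations + allele.observations,
                        sources=existing.sources + (source,),
                        metadata={**existing.metadata, **allele.metadata},
                    )
            else:
                alleles[name] = allele
            seen_in_file.add(name)
            progress = True
        pending = still
    for row in pending:
        errors.append(
            f"{Path(path).name} row {row.Index + 2}: unknown background {row.background!r}"
        )
    if errors:
        raise AlleleDBError("; ".join(errors))
    return AlleleDB(alleles, exon_map)


def data_path(filename: str) -> Path:
    """Path to a packaged data fixture."""
    return Path(resources.files("jktyper").joinpath("data", filename))  # type: ignore[arg-type]


def default_db(exon_map: Optional[ExonMap] = None) -> AlleleDB:
    """The full shipped database: ISBT definitions plus both allele tables."""
    exon_map = exon_map or default_exon_map()
    db = load_allele_db(data_path("isbt.tsv"), exon_map, source="isbt")
    db = load_allele_db(data_path("table4.tsv"), exon_map, base=db, source="table4")
    db = load_allele_db(data_path("table3.tsv"), exon_map, base=db, source="table3")
    return db
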