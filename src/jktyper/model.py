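"""Domain model for Kidd (JK) blood group genotyping.

The Kidd antigens JK1/Jk(a) and JK2/Jk(b) are carried by the urea transporter
encoded by *SLC14A1*; the two antithetical antigens differ by the single
coding change c.838G>A (p.Asp280Asn).  Everything in this package is anchored
on 1-based cDNA (HGVS ``c.``) coordinates of the JK*01 reference transcript,
with intronic positions expressed as an exon-boundary anchor plus a signed
offset (e.g. ``c.342-1``).  Genomic coordinates are never needed.

This module provides:

* :class:`Variant` — one cDNA-anchored sequence change,
* :func:`parse_hgvs_c` / :func:`format_hgvs_c` — the HGVS-like text round trip,
* :class:`ExonMap` — the exon 3-10 cDNA interval table and exon/intron lookup,
* :class:`AlleleName`, :func:`make_provisional_name`, :func:`parse_allele_name`
  — the provisional nomenclature for novel (non-ISBT-referenced) alleles:
  ``JK*<base>.<token>_<token>...`` where amino-acid tokens come first
  (one-letter code, nonsense written ``X``), then exonic nucleotide tokens
  (``588A_G``), then intron tokens (``E5-23G_A``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "JKError",
    "ParseError",
    "CoordinateError",
    "Variant",
    "ExonMap",
    "AlleleName",
    "parse_hgvs_c",
    "format_hgvs_c",
    "parse_position",
    "format_position",
    "make_provisional_name",
    "variant_token",
    "parse_allele_name",
    "default_exon_map",
    "load_exon_map",
]


class JKError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(JKError, ValueError):
    """Malformed variant or allele-name text; the message names the token."""


class CoordinateError(JKError, ValueError):
    """A cDNA coordinate that cannot be placed on the exon map."""


#: protein-effect vocabulary
PROTEIN_EFFECTS = frozenset(
    {
        "missense",
        "synonymous",
        "nonsense",
        "frameshift",
        "in-frame-del",
        "splice",
        "intronic",
    }
)

_AA_TOKEN_RE = re.compile(r"^[A-Z]\d+[A-Z*]$")


@dataclass(frozen=True, order=True)
class Variant:
    """One cDNA-anchored sequence change relative to the JK*01 reference.

    ``cds_pos`` is the 1-based cDNA coordinate (c.1 = A of the start codon);
    for intronic changes it is the exon-boundary anchor and ``intron_offset``
    the signed distance into the intron (never 0).  ``span_end`` is set for
    multi-base deletions such as c.27_50del.  ``aa_change`` carries the
    one-letter amino-acid token (e.g. ``Q21R``, ``Y37X``) when one is known.
    """

    cds_pos: int
    intron_offset: Optional[int] = None
    kind: str = "substitution"
    ref: str = ""
    alt: str = ""
    span_end: Optional[int] = None
    protein_effect: str = "synonymous"
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ParseError(f"cds_pos must be >= 1, got {self.cds_pos}")
        if self.intron_offset == 0:
            raise ParseError("intron_offset of 0 is not a valid intronic position")
        if self.span_end is not None and self.span_end < self.cds_pos:
            raise ParseError(
                f"span_end {self.span_end} precedes cds_pos {self.cds_pos}"
            )
        if self.kind == "substitution" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ParseError(
                f"substitution must have single-base ref/alt, got {self.ref!r}>{self.alt!r}"
            )
        if self.protein_effect not in PROTEIN_EFFECTS:
            raise ParseError(f"unknown protein_effect {self.protein_effect!r}")
        # intronic/splice annotations require an intron offset and vice versa;
        # near-boundary changes (|offset| <= 2) are recorded as splice-affecting.
        if self.protein_effect == "intronic" and self.intron_offset is None:
            raise ParseError("protein_effect 'intronic' requires an intron offset")
        if self.intron_offset is not None and self.protein_effect not in ("intronic", "splice"):
            raise ParseError("intron-offset variants must be annotated intronic or splice")

    # -- identity used for per-position bookkeeping -------------------------
    @property
    def position(self) -> tuple[int, int]:
        """(cds_pos, intron_offset-or-0) — the pileup coordinate of the change."""
        return (self.cds_pos, self.intron_offset or 0)

    @property
    def key(self) -> tuple[int, int, str]:
        """Uniqueness key within an allele: position plus kind."""
        return (self.cds_pos, self.intron_offset or 0, self.kind)

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset is not None

    @property
    def is_truncating(self) -> bool:
        """Nonsense or frameshift — stops translation at/near the change."""
        return self.protein_effect in ("nonsense", "frameshift")

    @property
    def alt_symbol(self) -> str:
        """Single-symbol alternate for pileup matching (D=del, I=ins, U=dup)."""
        if self.kind == "substitution":
            return self.alt
        return {"deletion": "D", "insertion": "I", "duplication": "U"}[self.kind]

    @property
    def codon(self) -> Optional[int]:
        """1-based codon number for exonic changes, None for intronic."""
        if self.is_intronic:
            return None
        return (self.cds_pos + 2) // 3

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_hgvs_c(self)


# ---------------------------------------------------------------------------
# HGVS-like cDNA text
# ---------------------------------------------------------------------------

_POS_RE = re.compile(
    r"^c\.(?P<pos>\d+)(?P<off>[+-]\d+)?"
    r"(?:_(?P<pos2>\d+)(?P<off2>[+-]\d+)?)?"
    r"(?P<rest>.*)$"
)
_SUB_RE = re.compile(r"^(?P<ref>[ACGT]+)>(?P<alt>[ACGT]+)$")
_DEL_RE = re.compile(r"^(?:(?P<ref>[ACGT]*)del(?![ACGT])|del(?P<ref2>[ACGT]*))$")
_INS_RE = re.compile(r"^ins(?P<alt>[ACGT]+)$")
_DUP_RE = re.compile(r"^dup(?P<alt>[ACGT]*)$")


def _infer_protein_effect(
    kind: str,
    intron_offset: Optional[int],
    span_len: int,
) -> str:
    """Default protein annotation when none is supplied alongside the text.

    Intron offsets within 2 nt of the boundary are splice-affecting; deeper
    offsets are plain intronic.  Exonic substitutions default to synonymous
    (a nucleotide-level record; missense/nonsense require an explicit
    amino-acid annotation, as in the allele tables).  Indels default to
    frameshift unless their length is a multiple of three.
    """
    if intron_offset is not None:
        return "splice" if abs(intron_offset) <= 2 else "intronic"
    if kind == "substitution":
        return "synonymous"
    if kind in ("deletion", "insertion", "duplication"):
        return "in-frame-del" if kind == "deletion" and span_len % 3 == 0 else "frameshift"
    raise ParseError(f"unknown variant kind {kind!r}")


def parse_hgvs_c(text: str, protein: Optional[str] = None) -> Variant:
    """Parse an HGVS-like cDNA string (``c.588A>G``, ``c.27_50del``,
    ``c.342-1G>A``, ``c.56insA``) into a :class:`Variant`.

    ``protein`` optionally supplies the amino-acid annotation from the allele
    tables: a one-letter change token (``Q21R``, ``Y37X``), ``=`` for
    synonymous, an in-frame deletion token (``V10_R17del``), ``fs`` for
    frameshift, or ``splice``.  Without it a sensible default is inferred
    (see :func:`_infer_protein_effect`).

    Raises :class:`ParseError` naming the offending token on malformed input.
    """
    text = text.replace(" ", "")
    if not text.startswith("c."):
        raise ParseError(f"variant text must start with 'c.': {text!r}")
    m = _POS_RE.match(text)
    if not m or (m.group("rest") == "" and m.group("pos2") is None):
        raise ParseError(f"malformed position in {text!r}")
    cds_pos = int(m.group("pos"))
    intron_offset = int(m.group("off")) if m.group("off") else None
    span_end = int(m.group("pos2")) if m.group("pos2") else None
    if m.group("off2"):
        raise ParseError(f"intron offset on span end not supported: {text!r}")
    rest = m.group("rest")
    if intron_offset == 0:
        raise ParseError(f"intron offset of 0 in {text!r}")

    kind: str
    ref = alt = ""
    if (sm := _SUB_RE.match(rest)) is not None:
        if span_end is not None:
            raise ParseError(f"substitution cannot carry a span: {text!r}")
        kind, ref, alt = "substitution", sm.group("ref"), sm.group("alt")
        if len(ref) != 1 or len(alt) != 1:
            raise ParseError(f"multi-base substitution not supported: {text!r}")
        if ref == alt:
            raise ParseError(f"ref equals alt in {text!r}")
    elif (dm := _DEL_RE.match(rest)) is not None:
        kind = "deletion"
        ref = dm.group("ref") or dm.group("ref2") or ""
    elif (im := _INS_RE.match(rest)) is not None:
        kind, alt = "insertion", im.group("alt")
    elif (um := _DUP_RE.match(rest)) is not None:
        kind, alt = "duplication", um.group("alt") or ""
    else:
        raise ParseError(f"unknown operator {rest!r} in {text!r}")

    span_len = (span_end - cds_pos + 1) if span_end is not None else 1
    aa_change: Optional[str] = None
    if protein in (None, "", "-", "intron"):
        effect = _infer_protein_effect(kind, intron_offset, span_len)
    elif protein in ("=", "syn", "synonymous", "Synonymous"):
        effect = "synonymous"
    elif protein in ("splice", "exon-skip"):
        effect = "splice"
    elif protein in ("fs", "frameshift"):
        effect = "frameshift"
    elif protein in ("ifdel", "in-frame-del") or protein.endswith("del"):
        effect = "in-frame-del"
    elif _AA_TOKEN_RE.match(protein):
        aa_change = protein.replace("*", "X")
        effect = "nonsense" if aa_change.endswith("X") else "missense"
    else:
        raise ParseError(f"unrecognised protein annotation {protein!r}")
    return Variant(
        cds_pos=cds_pos,
        intron_offset=intron_offset,
        kind=kind,
        ref=ref,
        alt=alt,
        span_end=span_end,
        protein_effect=effect,
        aa_change=aa_change,
    )


def format_hgvs_c(v: Variant) -> str:
    """Canonical HGVS-like text; inverse of :func:`parse_hgvs_c`."""
    pos = str(v.cds_pos)
    if v.intron_offset is not None:
        pos += f"{v.intron_offset:+d}"
    if v.span_end is not None:
        pos += f"_{v.span_end}"
    if v.kind == "substitution":
        return f"c.{pos}{v.ref}>{v.alt}"
    if v.kind == "deletion":
        return f"c.{pos}del{v.ref}"
    if v.kind == "insertion":
        return f"c.{pos}ins{v.alt}"
    return f"c.{pos}dup{v.alt}"


# -- pileup position text (e.g. "588", "342-23") ----------------------------

_PILEUP_POS_RE = re.compile(r"^(\d+)([+-]\d+)?$")


def format_position(position: tuple[int, int]) -> str:
    pos, off = position
    return f"{pos}{off:+d}" if off else str(pos)


def parse_position(text: str) -> tuple[int, int]:
    m = _PILEUP_POS_RE.match(text.strip())
    if not m:
        raise ParseError(f"malformed position {text!r}")
    return (int(m.group(1)), int(m.group(2)) if m.group(2) else 0)


# ---------------------------------------------------------------------------
# Exon map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonMap:
    """cDNA intervals of the *SLC14A1* coding exons 3-10.

    Boundaries anchored by the intron-offset variants in the allele tables
    (c.342-1, c.470+12, c.810 penultimate in exon 7, c.946+31, c.996+18) are
    fixed; the exon 3/4 and exon 6/7 junctions are configuration values and
    the shipped default tags them ``source_tag="synthetic"``.
    """

    intervals: tuple[tuple[int, int, int], ...]  # (exon, cds_start, cds_end)
    source_tag: str = "synthetic"

    def __post_init__(self) -> None:
        prev_exon, prev_end = None, 0
        for exon, start, end in self.intervals:
            if not (3 <= exon <= 10):
                raise CoordinateError(f"exon {exon} outside modeled range 3..10")
            if start > end or start <= prev_end:
                raise CoordinateError(f"exon {exon} interval [{start},{end}] not ascending/disjoint")
            if prev_exon is not None and exon != prev_exon + 1:
                raise CoordinateError(f"exon numbers not contiguous at {exon}")
            if prev_exon is not None and start != prev_end + 1:
                raise CoordinateError(f"cDNA gap before exon {exon}")
            prev_exon, prev_end = exon, end

    @property
    def starts(self) -> dict[int, int]:
        return {start: exon for exon, start, _ in self.intervals}

    @property
    def ends(self) -> dict[int, int]:
        return {end: exon for exon, _, end in self.intervals}

    @property
    def cds_end(self) -> int:
        return self.intervals[-1][2]

    def exon_containing(self, cds_pos: int) -> int:
        for exon, start, end in self.intervals:
            if start <= cds_pos <= end:
                return exon
        raise CoordinateError(f"c.{cds_pos} outside the modeled coding region")

    def exon_of(self, variant: Variant) -> str:
        """Printed-style exon/intron label, e.g. ``"exon 6"`` or ``"intron 4"``.

        Intron numbering: intron *n* separates exon *n* from exon *n+1*.  A
        positive offset anchors on the end of the preceding exon, a negative
        offset on the start of the following exon; any other anchor is a
        coordinate error.
        """
        if variant.intron_offset is None:
            return f"exon {self.exon_containing(variant.cds_pos)}"
        if variant.intron_offset > 0:
            exon = self.ends.get(variant.cds_pos)
            if exon is None:
                raise CoordinateError(
                    f"c.{variant.cds_pos}+{variant.intron_offset}: anchor is not an exon end"
                )
            return f"intron {exon}"
        exon = self.starts.get(variant.cds_pos)
        if exon is None:
            raise CoordinateError(
                f"c.{variant.cds_pos}{variant.intron_offset}: anchor is not an exon start"
            )
        return f"intron {exon - 1}"

    def amplicon_of(self, position: tuple[int, int]) -> int:
        """Exon-numbered amplicon owning a pileup position (one amplicon per
        coding exon; each amplicon also covers its flanking intron ends)."""
        pos, off = position
        if off == 0:
            return self.exon_containing(pos)
        if off > 0:
            exon = self.ends.get(pos)
            if exon is None:
                raise CoordinateError(f"{format_position(position)}: anchor not an exon end")
            return exon
        exon = self.starts.get(pos)
        if exon is None:
            raise CoordinateError(f"{format_position(position)}: anchor not an exon start")
        return exon


#: Default exon map.  Anchored boundaries (exon 4 end c.341, exon 5 = 342-470,
#: exon 7 end c.811, exon 8 end c.946, exon 9 = 947-996) come straight from the
#: intron-offset variants in the allele tables; the exon 3/4 (c.144|145) and
#: exon 6/7 (c.654|655) junctions are synthetic placeholders chosen inside the
#: windows the tables leave open, and the 3-10 coding span ends at c.1170
#: (389 codons + stop).
_DEFAULT_INTERVALS = (
    (3, 1, 144),
    (4, 145, 341),
    (5, 342, 470),
    (6, 471, 654),
    (7, 655, 811),
    (8, 812, 946),
    (9, 947, 996),
    (10, 997, 1170),
)


def default_exon_map() -> ExonMap:
    return ExonMap(_DEFAULT_INTERVALS, source_tag="synthetic")


def load_exon_map(path: str | Path) -> ExonMap:
    """Load an exon map TSV with columns exon, cds_start, cds_end, source_tag."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"exon", "cds_start", "cds_end", "source_tag"}
    if not required.issubset(df.columns):
        raise ParseError(f"exon map {path} missing columns {required - set(df.columns)}")
    intervals = tuple(
        (int(r.exon), int(r.cds_start), int(r.cds_end)) for r in df.itertuples()
    )
    return ExonMap(intervals, source_tag=str(df["source_tag"].iloc[0]))


# ---------------------------------------------------------------------------
# Allele names and provisional nomenclature
# ---------------------------------------------------------------------------

_BASE_LONG_RE = re.compile(r"^(\d{2}[WN]\.\d{2})(.*)$")
_BASE_SHORT_RE = re.compile(r"^(\d{2})(.*)$")
_TOKEN_AA_RE = re.compile(r"^[A-Z]\d+[A-Z]$")
_TOKEN_SYN_HEAD_RE = re.compile(r"^(\d+)([ACGT])$")
_TOKEN_INTRON_HEAD_RE = re.compile(r"^E(\d+)([+-])(\d+)([ACGT])$")
_TOKEN_DEL_RE = re.compile(r"^(\d+)del$")
_TOKEN_SPANDEL_HEAD_RE = re.compile(r"^(\d+)$")
_TOKEN_SPANDEL_TAIL_RE = re.compile(r"^(\d+)del$")
_TOKEN_INS_RE = re.compile(r"^(\d+)ins([ACGT]+)$")
_NUC_RE = re.compile(r"^[ACGT]$")


@dataclass(frozen=True)
class AlleleName:
    """An ISBT-style JK allele name: ``JK*<base>`` plus optional extra tokens.

    ``base`` is the ISBT token (``01``, ``02W.03``, ``01N.20``);
    ``extra_tokens`` the ordered provisional-nomenclature tokens.
    """

    base: str
    extra_tokens: tuple[str, ...] = ()
    system: str = "JK"

    def __str__(self) -> str:
        s = f"{self.system}*{self.base}"
        if self.extra_tokens:
            s += "." + "_".join(self.extra_tokens)
        return s

    @property
    def is_base(self) -> bool:
        return not self.extra_tokens

    @property
    def base_name(self) -> "AlleleName":
        return AlleleName(self.base)


def variant_token(v: Variant, exon_map: ExonMap) -> tuple[int, tuple[int, int], str]:
    """Provisional-nomenclature token for one extra variant.

    Returns ``(token_class, sort_key, text)`` where class 0 = amino-acid
    token, 1 = exonic nucleotide token, 2 = intron token; tokens are ordered
    by class then cDNA position, matching the printed convention (amino-acid
    changes first, intron tokens last).
    """
    key = (v.cds_pos, v.intron_offset or 0)
    if v.is_intronic:
        label = exon_map.exon_of(v)  # validates the anchor
        if v.intron_offset > 0:
            exon = exon_map.ends[v.cds_pos]
            sign = "+"
        else:
            exon = exon_map.starts[v.cds_pos]
            sign = "-"
        if v.kind != "substitution":
            raise CoordinateError(f"unsupported intronic {v.kind} at {format_hgvs_c(v)}")
        return (2, key, f"E{exon}{sign}{abs(v.intron_offset)}{v.ref}_{v.alt}")
    if v.cds_pos > exon_map.cds_end:
        raise CoordinateError(f"{format_hgvs_c(v)} outside the modeled coding region")
    if v.aa_change and v.protein_effect in ("missense", "nonsense"):
        return (0, key, v.aa_change)
    if v.kind == "substitution":
        return (1, key, f"{v.cds_pos}{v.ref}_{v.alt}")
    if v.kind == "deletion":
        text = f"{v.cds_pos}_{v.span_end}del" if v.span_end else f"{v.cds_pos}del"
        return (1, key, text)
    if v.kind == "insertion":
        return (1, key, f"{v.cds_pos}ins{v.alt}")
    if v.kind == "duplication":
        return (1, key, f"{v.cds_pos}dup{v.alt}")
    raise ParseError(f"cannot derive token for {v!r}")


def make_provisional_name(
    background: AlleleName,
    extras: Sequence[Variant],
    exon_map: ExonMap,
) -> AlleleName:
    """Name a novel allele as its background base plus ordered change tokens.

    Tokens are ordered amino-acid changes first (ascending cDNA position),
    then exonic nucleotide changes, then intron changes; deterministic for a
    given input.  ``extras`` must be nonempty.
    """
    if not extras:
        raise ParseError("a provisional name requires at least one extra variant")
    toks = sorted(variant_token(v, exon_map) for v in extras)
    return AlleleName(background.base, tuple(t for _, _, t in toks))


def parse_allele_name(name: str) -> AlleleName:
    """Parse ``JK*<base>[.<tokens>]`` back into an :class:`AlleleName`.

    Inverse of :func:`make_provisional_name` token-for-token.  Synonymous and
    intron tokens internally contain the ``_`` divider (``588A_G``), so the
    token string is re-grouped greedily after splitting.
    """
    if not name.startswith("JK*"):
        raise ParseError(f"allele name must start with 'JK*': {name!r}")
    rest = name[3:]
    m = _BASE_LONG_RE.match(rest) or _BASE_SHORT_RE.match(rest)
    if not m:
        raise ParseError(f"malformed ISBT base in {name!r}")
    base, tail = m.group(1), m.group(2)
    if not tail:
        return AlleleName(base)
    if not tail.startswith("."):
        raise ParseError(f"expected '.' divider after base in {name!r}")
    pieces = tail[1:].split("_")
    tokens: list[str] = []
    i = 0
    while i < len(pieces):
        p = pieces[i]
        if _TOKEN_AA_RE.match(p):
            tokens.append(p)
            i += 1
        elif _TOKEN_SYN_HEAD_RE.match(p) or _TOKEN_INTRON_HEAD_RE.match(p):
            if i + 1 >= len(pieces) or not _NUC_RE.match(pieces[i + 1]):
                raise ParseError(f"dangling nucleotide token {p!r} in {name!r}")
            tokens.append(f"{p}_{pieces[i + 1]}")
            i += 2
        elif _TOKEN_DEL_RE.match(p) or _TOKEN_INS_RE.match(p):
            tokens.append(p)
            i += 1
        elif _TOKEN_SPANDEL_HEAD_RE.match(p) and i + 1 < len(pieces) and _TOKEN_SPANDEL_TAIL_RE.match(pieces[i + 1]):
            tokens.append(f"{p}_{pieces[i + 1]}")
            i += 2
        else:
            raise ParseError(f"unknown token shape {p!r} in {name!r}")
    return AlleleName(base, tuple(tokens))
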