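"""Diplotype calling from per-amplicon pileups.

The pipeline mirrors the accredited analysis workflow the assay was validated
with: run-level QC, per-position diploid genotyping with an error-correction
noise floor, fragment acceptance rules (minimum coverage 80 for a homozygous
allele group, 30 per allele in a heterozygous group), exon-wise allele-group
intersection against the allele database, phase-constraint or double-ARMS
resolution of ambiguous calls, and provisional naming of novel alleles.

Pileups are diploid base counts per cDNA position over the symbol alphabet
``A C G T N D I`` (``N`` = unknown reference placeholder at indel anchors,
``D`` = deleted, ``I`` = insertion observed).  One amplicon covers each of
the eight coding exons (3-10) plus its flanking intron ends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .alleledb import Allele, AlleleDB
from .model import (
    AlleleName,
    CoordinateError,
    JKError,
    Variant,
    make_provisional_name,
)

__all__ = [
    "BASE_SYMBOLS",
    "RunMetrics",
    "CallingParams",
    "FragmentPileup",
    "PositionCall",
    "ObservedGenotype",
    "Diplotype",
    "ArmsResult",
    "PhaseRule",
    "DEFAULT_PHASE_RULES",
    "ARMS_POSITIONS",
    "InconsistencyError",
    "qc_run",
    "genotype_position",
    "call_sample",
    "intersect_allele_groups",
    "interpret_double_arms",
    "resolve_with_phase_constraints",
    "construct_novel_alleles",
    "call_diplotype",
]

BASE_SYMBOLS = ("A", "C", "G", "T", "N", "D", "I")

Position = tuple[int, int]
Haplotype3 = tuple[str, str, str]

#: the three double-ARMS SNV positions: c.588A>G, c.810G>A, c.838G>A
ARMS_POSITIONS: tuple[Position, ...] = ((588, 0), (810, 0), (838, 0))


class InconsistencyError(JKError, ValueError):
    """Evidence (ARMS bands, constraints) excludes every candidate."""


# ---------------------------------------------------------------------------
# Run QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunMetrics:
    """Sequencing-run quality metrics used as the run acceptance gate."""

    cluster_density: float  # k/mm^2
    pct_clusters_pf: float
    pct_q30: float

    def __post_init__(self) -> None:
        if min(self.cluster_density, self.pct_clusters_pf, self.pct_q30) < 0:
            raise ValueError("run metrics must be nonnegative")


def qc_run(metrics: RunMetrics) -> tuple[bool, list[str]]:
    """Run acceptance: cluster density within 800-1,300 k/mm^2, >70% of
    clusters passing filter, Q30 above 70%.  Returns (pass, reasons)."""
    reasons = []
    if not 800 <= metrics.cluster_density <= 1300:
        reasons.append(f"cluster density {metrics.cluster_density:g} outside 800-1300 k/mm^2")
    if not metrics.pct_clusters_pf > 70:
        reasons.append(f"clusters passing filter {metrics.pct_clusters_pf:g}% not above 70%")
    if not metrics.pct_q30 > 70:
        reasons.append(f"Q30 {metrics.pct_q30:g}% not above 70%")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# Position genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CallingParams:
    """Coverage acceptance rules and zygosity windows.

    Minimum fragment coverage is 80 reads for a homozygous allele group and
    30 reads per allele in a heterozygous group; the error floor removes
    low-fraction noise bases before zygosity classification, and the
    het/hom fraction windows encode the expected near-1:1 allele balance.
    """

    min_depth_hom: int = 80
    min_depth_het_per_allele: int = 30
    het_min_minor_fraction: float = 0.20
    hom_min_major_fraction: float = 0.80
    error_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.error_floor < self.het_min_minor_fraction <= 0.5:
            raise ValueError("require 0 < error_floor < het_min_minor_fraction <= 0.5")
        if not self.hom_min_major_fraction > 0.5:
            raise ValueError("hom_min_major_fraction must exceed 0.5")


@dataclass(frozen=True)
class PositionCall:
    bases: Optional[tuple[str, str]]  # sorted unordered pair, None if uninterpretable
    zygosity: Optional[str]  # 'hom' | 'het' | None
    qc_pass: bool
    reason: str = ""


def genotype_position(counts: Mapping[str, int], params: CallingParams = CallingParams()) -> PositionCall:
    """Classify one pileup position as hom/het after error correction.

    Bases below the noise floor are removed; a single surviving base at a
    fraction >= the hom window is homozygous (coverage rule: depth >= 80); two
    surviving bases each >= the het window are heterozygous (coverage rule:
    >= 30 reads per base).  Anything else is uninterpretable and fails the
    fragment.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative base count")
    total = sum(counts.values())
    if total == 0:
        return PositionCall(None, None, False, "no coverage")
    fracs = {b: c / total for b, c in counts.items() if c > 0}
    kept = {b: f for b, f in fracs.items() if f >= params.error_floor}
    if len(kept) == 1:
        (base, frac), = kept.items()
        if frac < params.hom_min_major_fraction:
            return PositionCall(None, None, False, "major allele fraction too low")
        ok = total >= params.min_depth_hom
        return PositionCall(
            (base, base), "hom", ok, "" if ok else f"homozygous depth {total} < {params.min_depth_hom}"
        )
    if len(kept) == 2:
        (b1, f1), (b2, f2) = sorted(kept.items())
        if min(f1, f2) < params.het_min_minor_fraction:
            return PositionCall(
                None, None, False,
                f"minor base fraction {min(f1, f2):.2f} below heterozygous window",
            )
        low = min(counts[b1], counts[b2])
        ok = low >= params.min_depth_het_per_allele
        return PositionCall(
            (b1, b2), "het", ok,
            "" if ok else f"allele depth {low} < {params.min_depth_het_per_allele}",
        )
    return PositionCall(None, None, False, f"{len(kept)} bases above noise floor")


# ---------------------------------------------------------------------------
# Sample-level genotype
# ---------------------------------------------------------------------------

CoRecord = tuple[Position, str, Position, str, int]


@dataclass(frozen=True)
class FragmentPileup:
    """Base counts for one amplicon of one sample.

    ``counts`` maps cDNA position -> symbol -> reads; ``refs`` optionally
    carries reference symbols for positions unknown to the allele database;
    ``cooccurrence`` optionally carries read-backed co-observation records
    ``(pos_a, base_a, pos_b, base_b, n_reads)`` used for within-amplicon
    phasing of novel variants.
    """

    amplicon_id: str
    counts: Mapping[Position, Mapping[str, int]]
    refs: Mapping[Position, str] = field(default_factory=dict)
    cooccurrence: tuple[CoRecord, ...] = ()

    @property
    def total_depth(self) -> int:
        return max((sum(c.values()) for c in self.counts.values()), default=0)


@dataclass(frozen=True)
class ObservedGenotype:
    """Per-position unordered base pairs for one sample, plus QC status."""

    sample_id: str
    status: str  # 'called' | 'no_call'
    genotypes: Mapping[Position, tuple[str, str]]
    refs: Mapping[Position, str]
    failing_fragments: tuple[tuple[str, str], ...] = ()  # (amplicon, reason)
    cooccurrence: tuple[CoRecord, ...] = ()

    @property
    def nonref_positions(self) -> tuple[Position, ...]:
        return tuple(
            sorted(
                p
                for p, (b1, b2) in self.genotypes.items()
                if (b1, b2) != (self.refs[p], self.refs[p])
            )
        )


def _required_amplicons(db: AlleleDB) -> dict[str, list[Position]]:
    groups: dict[str, list[Position]] = {f"exon{n}": [] for n in range(3, 11)}
    for pos in db.positions:
        groups[f"exon{db.exon_map.amplicon_of(pos)}"].append(pos)
    return groups


def call_sample(
    pileups: Iterable[FragmentPileup],
    db: AlleleDB,
    params: CallingParams = CallingParams(),
    sample_id: str = "sample",
) -> ObservedGenotype:
    """Genotype every pileup position; the sample is a no-call unless the
    entire set of fragments (all eight coding exons) passes the coverage
    acceptance rules."""
    by_amp = {p.amplicon_id: p for p in pileups}
    required = _required_amplicons(db)
    failing: list[tuple[str, str]] = []
    genotypes: dict[Position, tuple[str, str]] = {}
    refs: dict[Position, str] = {}
    co: list[CoRecord] = []
    for amp, db_positions in required.items():
        pile = by_amp.get(amp)
        if pile is None:
            failing.append((amp, "missing fragment"))
            continue
        missing = [p for p in db_positions if p not in pile.counts]
        if missing:
            failing.append((amp, f"{len(missing)} database positions without coverage"))
        for pos, counts in pile.counts.items():
            call = genotype_position(counts, params)
            refs[pos] = pile.refs.get(pos, db.ref_symbol(pos))
            if call.bases is not None:
                genotypes[pos] = call.bases
            if not call.qc_pass:
                label = f"{pos[0]}{pos[1]:+d}" if pos[1] else str(pos[0])
                failing.append((amp, f"c.{label}: {call.reason}"))
        co.extend(pile.cooccurrence)
    status = "no_call" if failing else "called"
    return ObservedGenotype(
        sample_id=sample_id,
        status=status,
        genotypes=genotypes,
        refs=refs,
        failing_fragments=tuple(failing),
        cooccurrence=tuple(co),
    )


# ---------------------------------------------------------------------------
# Diplotype and the intersection caller
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of allele identities for one sample."""

    alleles: Optional[tuple[str, str]]
    status: str  # unique | ambiguous | novel | ambiguous_novel | no_call
    phasing_evidence: str = "none"  # none | arms | population_constraint
    candidates: tuple[tuple[str, str], ...] = ()
    notes: tuple[str, ...] = ()
    novel_definitions: Mapping[str, frozenset[Variant]] = field(default_factory=dict)

    @property
    def pair(self) -> Optional[tuple[str, str]]:
        return self.alleles


class _PairIndex:
    """Per-database index of all unordered allele pairs, signatures grouped
    by exon amplicon, for fast allele-group intersection."""

    def __init__(self, db: AlleleDB):
        self.db = db
        self.positions = db.positions
        self.refs = {p: db.ref_symbol(p) for p in self.positions}
        self.names = sorted(db.alleles)
        vectors = {
            n: tuple(db[n].base_at(p, self.refs[p]) for p in self.positions)
            for n in self.names
        }
        self.pairs: list[tuple[str, str]] = [
            (a, b) for i, a in enumerate(self.names) for b in self.names[i:]
        ]
        groups: dict[int, list[int]] = {}
        for idx, pos in enumerate(self.positions):
            groups.setdefault(db.exon_map.amplicon_of(pos), []).append(idx)
        self.groups = groups
        self.group_index: dict[int, dict[tuple, set[int]]] = {}
        for exon, idxs in groups.items():
            table: dict[tuple, set[int]] = {}
            for k, (a, b) in enumerate(self.pairs):
                sig = tuple(
                    tuple(sorted((vectors[a][i], vectors[b][i]))) for i in idxs
                )
                table.setdefault(sig, set()).add(k)
            self.group_index[exon] = table

    def observed_signature(self, obs: ObservedGenotype, exon: int) -> tuple:
        out = []
        for i in self.groups[exon]:
            pos = self.positions[i]
            pair = obs.genotypes.get(pos)
            if pair is None:
                ref = self.refs[pos]
                pair = (ref, ref)
            out.append(tuple(sorted(pair)))
        return tuple(out)


def _pair_index(db: AlleleDB) -> _PairIndex:
    idx = getattr(db, "_pair_index", None)
    if idx is None or idx.db is not db or len(idx.names) != len(db):
        idx = _PairIndex(db)
        db.__dict__["_pair_index"] = idx
    return idx


def intersect_allele_groups(obs: ObservedGenotype, db: AlleleDB) -> Diplotype:
    """Call a diplotype by forming intersections of allele groups for all
    eight exons: per exon, the set of unordered allele pairs whose combined
    variant pattern matches the observed genotypes; the candidate set is the
    intersection across exons.  One survivor is a unique call, several an
    ambiguous call, none a novel constellation."""
    if obs.status != "called":
        return Diplotype(None, "no_call", notes=tuple(f"{a}: {r}" for a, r in obs.failing_fragments))
    index = _pair_index(db)
    known = set(index.positions)
    novel_obs = [
        p for p in obs.nonref_positions if p not in known
    ]
    candidates: Optional[set[int]] = None
    if not novel_obs:
        for exon in index.groups:
            table = index.group_index[exon]
            found = table.get(index.observed_signature(obs, exon), set())
            candidates = found if candidates is None else candidates & found
            if not candidates:
                break
    pairs = sorted(index.pairs[k] for k in (candidates or ()))
    if len(pairs) == 1:
        return Diplotype(pairs[0], "unique")
    if pairs:
        return Diplotype(None, "ambiguous", candidates=tuple(pairs))
    return Diplotype(None, "novel")


# ---------------------------------------------------------------------------
# Double-ARMS interpretation
# ---------------------------------------------------------------------------

_ALPHABET_588 = ("A", "G")
_ALPHABET_810 = ("G", "A")
_ALPHABET_838 = ("G", "A")


@dataclass(frozen=True)
class ArmsResult:
    """Band pattern of the two double-ARMS reactions.

    Reaction A amplifies c.588..c.810 with allele-specific primers at both
    ends (combos 588A/G x 810G/A); reaction B spans c.810..c.838.  A combo
    band appears only when one chromosome carries both primer-matched bases.
    """

    a_bands: frozenset  # of (base588, base810)
    b_bands: frozenset  # of (base810, base838)
    control_a: bool = True
    control_b: bool = True

    @classmethod
    def from_bools(
        cls,
        a_588A_810G: bool, a_588A_810A: bool, a_588G_810G: bool, a_588G_810A: bool,
        b_810G_838G: bool, b_810A_838G: bool, b_810G_838A: bool, b_810A_838A: bool,
        control_a: bool = True, control_b: bool = True,
    ) -> "ArmsResult":
        a = {("A", "G"): a_588A_810G, ("A", "A"): a_588A_810A,
             ("G", "G"): a_588G_810G, ("G", "A"): a_588G_810A}
        b = {("G", "G"): b_810G_838G, ("A", "G"): b_810A_838G,
             ("G", "A"): b_810G_838A, ("A", "A"): b_810A_838A}
        return cls(
            frozenset(k for k, v in a.items() if v),
            frozenset(k for k, v in b.items() if v),
            control_a, control_b,
        )


def predict_arms_bands(pair: tuple[Haplotype3, Haplotype3]) -> tuple[frozenset, frozenset]:
    """Band pattern predicted for an unordered pair of (588, 810, 838)
    haplotypes: a combo band is present iff some haplotype carries both
    primer-matched bases of that reaction."""
    a = frozenset((h[0], h[1]) for h in pair)
    b = frozenset((h[1], h[2]) for h in pair)
    return a, b


def interpret_double_arms(result: ArmsResult) -> tuple[tuple[Haplotype3, Haplotype3], ...]:
    """Return every unordered haplotype pair over (c.588, c.810, c.838) whose
    predicted band pattern equals the observed one.

    Works by splitting each reaction's band set into the one or two per-
    chromosome phase combos it implies and joining the reactions on their
    shared c.810 base.  Raises :class:`InconsistencyError` when a control
    band is absent or no pair explains the pattern (suggesting reaction
    failure)."""
    if not (result.control_a and result.control_b):
        raise InconsistencyError("amplification control band absent; reaction not interpretable")

    def assignments(bands: frozenset) -> list[tuple]:
        combos = sorted(bands)
        if len(combos) == 1:
            return [(combos[0], combos[0])]
        if len(combos) == 2:
            x, y = combos
            return [(x, y), (y, x)]
        return []

    pairs: set[tuple[Haplotype3, Haplotype3]] = set()
    for a1, a2 in assignments(result.a_bands):
        for b1, b2 in assignments(result.b_bands):
            if a1[1] != b1[0] or a2[1] != b2[0]:
                continue
            h1: Haplotype3 = (a1[0], a1[1], b1[1])
            h2: Haplotype3 = (a2[0], a2[1], b2[1])
            pair = tuple(sorted((h1, h2)))
            if predict_arms_bands(pair) == (result.a_bands, result.b_bands):
                pairs.add(pair)  # type: ignore[arg-type]
    if not pairs:
        raise InconsistencyError("no haplotype pair explains the observed band pattern")
    return tuple(sorted(pairs))


# ---------------------------------------------------------------------------
# Phase constraints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseRule:
    """A population haplotype-linkage rule over (c.588, c.810, c.838)."""

    name: str
    description: str

    def ok(self, hap: Haplotype3) -> bool:
        raise NotImplementedError


@dataclass(frozen=True)
class _Jk2Linked588G(PhaseRule):
    def ok(self, hap: Haplotype3) -> bool:
        return not (hap[2] == "A" and hap[0] == "A")


@dataclass(frozen=True)
class _810AOn588G838A(PhaseRule):
    def ok(self, hap: Haplotype3) -> bool:
        return hap[1] != "A" or (hap[0] == "G" and hap[2] == "A")


#: Linkage observed in the donor cohort: JK2 (c.838A) alleles carry c.588G,
#: and c.810A occurs exclusively in phase with c.588G and c.838A.
DEFAULT_PHASE_RULES: tuple[PhaseRule, ...] = (
    _Jk2Linked588G("jk2_linked_588G", "JK2 alleles (c.838A) carry c.588G"),
    _810AOn588G838A("810A_on_588G_838A", "c.810A occurs only in phase with c.588G and c.838A"),
)


def _projection(db: AlleleDB, name: str) -> Haplotype3:
    return tuple(db.haplotype_projection(name, ARMS_POSITIONS))  # type: ignore[return-value]


def resolve_with_phase_constraints(
    dip: Diplotype,
    db: AlleleDB,
    arms: Optional[ArmsResult] = None,
    rules: Sequence[PhaseRule] = DEFAULT_PHASE_RULES,
    frequency_tiebreak: bool = True,
) -> Diplotype:
    """Narrow an ambiguous diplotype with double-ARMS evidence and/or
    population phase rules.

    ARMS evidence keeps only candidate pairs whose (588, 810, 838)
    projections match an interpretation of the band pattern.  Constraint
    rules eliminate pairs containing a haplotype that violates them, and any
    remaining ambiguity is optionally resolved by haplotype-frequency
    phasing over the cohort's observed allele counts; both constraint-only
    resolutions are labeled ``population_constraint`` (lower confidence than
    read- or ARMS-backed phasing).  Ambiguity that survives is returned
    as-is; eliminating every pair raises :class:`InconsistencyError`."""
    if dip.status != "ambiguous":
        return dip
    pairs = list(dip.candidates)
    evidence = dip.phasing_evidence
    if arms is not None:
        interpretations = {p for p in interpret_double_arms(arms)}
        kept = [
            pr
            for pr in pairs
            if tuple(sorted((_projection(db, pr[0]), _projection(db, pr[1])))) in interpretations
        ]
        if not kept:
            raise InconsistencyError("ARMS band pattern excludes every candidate pair")
        if len(kept) < len(pairs):
            evidence = "arms"
        pairs = kept
    if len(pairs) > 1 and rules:
        kept = [
            pr
            for pr in pairs
            if all(rule.ok(_projection(db, n)) for n in pr for rule in rules)
        ]
        if not kept:
            raise InconsistencyError("phase constraints exclude every candidate pair")
        if len(kept) < len(pairs) and evidence != "arms":
            evidence = "population_constraint"
        pairs = kept
    if len(pairs) > 1 and frequency_tiebreak:
        best = _most_frequent_pair(pairs, db)
        if best is not None:
            return Diplotype(best, "unique", phasing_evidence="population_constraint")
    if len(pairs) == 1:
        return Diplotype(pairs[0], "unique", phasing_evidence=evidence)
    return replace(dip, candidates=tuple(pairs), phasing_evidence=evidence)


def _most_frequent_pair(
    pairs: Sequence[tuple[str, str]], db: AlleleDB
) -> Optional[tuple[str, str]]:
    """Haplotype-frequency phasing: rank candidate pairs by the product of
    their alleles' observed cohort frequencies (Hardy-Weinberg prior, factor
    2 for heterozygous pairs) and return a unique maximum, else None.
    Unobserved alleles get a 0.5 pseudo-count."""

    def weight(pair: tuple[str, str]) -> float:
        fa = db[pair[0]].observations or 0.5
        fb = db[pair[1]].observations or 0.5
        return (2.0 if pair[0] != pair[1] else 1.0) * fa * fb

    scored = sorted(((weight(p), p) for p in pairs), reverse=True)
    if scored[0][0] > scored[1][0]:
        return scored[0][1]
    return None


# ---------------------------------------------------------------------------
# Novel-allele construction
# ---------------------------------------------------------------------------


_SAME_BACKGROUND_NOTE = (
    "serotype comparison not possible: novel allele combined with a "
    "second allele of the same background"
)


def _variant_for(db: AlleleDB, pos: Position, sym: str, ref: str) -> Variant:
    known = db.variant_at(pos, sym)
    if known is not None:
        return known
    cds, off = pos
    if sym == "D":
        return Variant(cds, off or None, "deletion", ref if ref != "N" else "",
                       protein_effect="intronic" if off else "frameshift")
    if sym == "I":
        return Variant(cds, off or None, "insertion", "", "N",
                       protein_effect="intronic" if off else "frameshift")
    # unannotated substitution: named by its nucleotide token, flagged for
    # manual curation upstream
    effect = "intronic" if off and abs(off) > 2 else ("splice" if off else "synonymous")
    return Variant(cds, off or None, "substitution", ref, sym, protein_effect=effect)


def _pair_explanation(
    obs: ObservedGenotype,
    db: AlleleDB,
    a: Allele,
    b: Allele,
    positions: Sequence[Position],
    refs: Mapping[Position, str],
):
    """Residual variants needed for (a, b) to explain the observation.

    Returns (cost, residuals) where residuals is a list of
    (position, symbol, assignment) with assignment in {'both', 0, 1, 'free'};
    None when the pair cannot explain the observation at all."""
    residuals = []
    cost = 0
    for pos in positions:
        ref = refs[pos]
        bases = (a.base_at(pos, ref), b.base_at(pos, ref))
        observed = obs.genotypes.get(pos, (ref, ref))
        if tuple(sorted(bases)) == tuple(sorted(observed)):
            continue
        options = []
        for o1, o2 in (observed, observed[::-1]):
            adds = []
            ok = True
            for hap, (have, want) in enumerate(zip(bases, (o1, o2))):
                if have == want:
                    continue
                if have != ref:
                    ok = False
                    break
                adds.append((hap, want))
            if ok:
                options.append(adds)
        if not options:
            return None
        best = min(options, key=len)
        if len(best) == 2 and {h for h, _ in best} == {0, 1} and best[0][1] == best[1][1]:
            residuals.append((pos, best[0][1], "both"))
            cost += 1
        elif len(best) == 1:
            hap, sym = best[0]
            # free when both haplotypes sit on the reference base
            assignment = hap if bases[0] != bases[1] else "free"
            residuals.append((pos, sym, assignment))
            cost += 1
        else:  # two distinct new bases, one per haplotype (order open)
            syms = tuple(sym for _, sym in sorted(best))
            residuals.append((pos, syms, "split"))
            cost += 2
    return cost, residuals


def _name_novel(db: AlleleDB, bg: Allele, residuals: Sequence[Variant]) -> tuple[str, frozenset[Variant]]:
    base = db[f"JK*{bg.name.base}"]
    extras = sorted(
        (bg.variants - base.variants) | set(residuals), key=lambda v: v.key
    )
    variants = frozenset(bg.variants | set(residuals))
    if not extras:
        return str(bg.name), variants
    name = make_provisional_name(AlleleName(bg.name.base), extras, db.exon_map)
    return str(name), variants


def construct_novel_alleles(
    obs: ObservedGenotype,
    db: AlleleDB,
    rules: Sequence[PhaseRule] = DEFAULT_PHASE_RULES,
) -> Diplotype:
    """Explain a genotype no database pair matches, as a database pair plus a
    minimal set of residual (novel) variants, and name the resulting alleles
    provisionally.

    Homozygous residuals go to both haplotypes.  Heterozygous residuals are
    assigned by read-backed co-occurrence when records are available, then by
    population phase constraints; with neither, both arrangements are
    returned (``ambiguous_novel``), except that identical backgrounds make
    the arrangement immaterial (flagged: serotype comparison not possible
    when the novel allele pairs with a second allele of the same
    background)."""
    if obs.status != "called":
        return Diplotype(None, "no_call")
    index = _pair_index(db)
    positions = sorted(set(index.positions) | set(obs.genotypes))
    refs = {p: obs.refs.get(p, db.ref_symbol(p)) for p in positions}
    best_cost: Optional[int] = None
    best: list[tuple[Allele, Allele, list]] = []
    for a_name, b_name in index.pairs:
        a, b = db[a_name], db[b_name]
        expl = _pair_explanation(obs, db, a, b, positions, refs)
        if expl is None:
            continue
        cost, residuals = expl
        if best_cost is None or cost < best_cost:
            best_cost, best = cost, [(a, b, residuals)]
        elif cost == best_cost:
            best.append((a, b, residuals))
    if not best:
        raise InconsistencyError("no allele pair can explain the observed genotype")
    if best_cost == 0:
        # the intersection caller should have found this pair
        a, b, _ = best[0]
        return Diplotype(tuple(sorted((str(a.name), str(b.name)))), "unique")

    if len(best) > 1:
        best = _filter_novel_pairs(db, best, rules)

    outcomes: list[tuple[tuple[str, str], dict, tuple[str, ...], str]] = []
    for a, b, residuals in best:
        arrangements = _assign_residuals(obs, db, a, b, residuals, rules)
        outcomes.extend(arrangements)
    named = {o[0]: o for o in outcomes}
    pairs = sorted(named)
    if len(pairs) == 1:
        pair, defs, notes, evidence = named[pairs[0]]
        return Diplotype(pair, "novel", phasing_evidence=evidence,
                         notes=notes, novel_definitions=defs)
    notes = tuple(sorted({n for o in outcomes for n in o[2]}))
    defs: dict[str, frozenset[Variant]] = {}
    for _, d, _, _ in outcomes:
        defs.update(d)
    return Diplotype(None, "ambiguous_novel", candidates=tuple(pairs),
                     notes=notes, novel_definitions=defs)


def _filter_novel_pairs(db: AlleleDB, best: list, rules: Sequence[PhaseRule]) -> list:
    """Among equally minimal background pairs, drop pairs whose background
    haplotypes violate the phase rules, then prefer the most frequent pair
    (same evidence hierarchy as ambiguous-call resolution)."""
    kept = [
        (a, b, r)
        for a, b, r in best
        if all(
            rule.ok(_projection(db, str(bg.name)))
            for bg in (a, b)
            for rule in rules
        )
    ] or best
    if len(kept) > 1:
        pairs = [tuple(sorted((str(a.name), str(b.name)))) for a, b, _ in kept]
        winner = _most_frequent_pair(pairs, db)
        if winner is not None:
            kept = [
                (a, b, r)
                for a, b, r in kept
                if tuple(sorted((str(a.name), str(b.name)))) == winner
            ]
    return kept


def _assign_residuals(
    obs: ObservedGenotype,
    db: AlleleDB,
    a: Allele,
    b: Allele,
    residuals: Sequence[tuple],
    rules: Sequence[PhaseRule],
):
    """Enumerate haplotype assignments of residual variants, resolving free
    het residuals by co-occurrence, then phase rules."""
    refs = {p: obs.refs.get(p, db.ref_symbol(p)) for p, _, _ in residuals}
    fixed: list[tuple[Position, str, int | str]] = []
    free: list[tuple[Position, tuple[str, ...]]] = []  # (pos, syms per hap order)
    notes: list[str] = []
    evidence = "none"
    same_background = a.name == b.name
    for pos, sym, assignment in residuals:
        if assignment == "both":
            fixed.append((pos, sym, "both"))
        elif isinstance(assignment, int):
            fixed.append((pos, sym, assignment))
        elif assignment == "split":
            s1, s2 = sym
            hap = _phase_by_cooccurrence(obs, db, a, b, pos, s1)
            if same_background or hap == 0:
                fixed.append((pos, s1, 0))
                fixed.append((pos, s2, 1))
                if same_background:
                    notes.append(_SAME_BACKGROUND_NOTE)
            elif hap == 1:
                fixed.append((pos, s1, 1))
                fixed.append((pos, s2, 0))
            else:
                free.append((pos, (s1, s2)))
        elif same_background:
            fixed.append((pos, sym, 0))
            notes.append(_SAME_BACKGROUND_NOTE)
        else:
            hap = _phase_by_cooccurrence(obs, db, a, b, pos, sym)
            if hap is not None:
                fixed.append((pos, sym, hap))
            else:
                free.append((pos, (sym,)))

    def placements(combo: Sequence[int]) -> list[tuple[Position, str, int]]:
        """Resolve a free-entry flag vector into (pos, sym, hap) placements."""
        placed = []
        for (pos, syms), flag in zip(free, combo):
            if len(syms) == 1:
                placed.append((pos, syms[0], flag))
            else:
                placed.append((pos, syms[flag], 0))
                placed.append((pos, syms[1 - flag], 1))
        return placed

    def build(placed: Sequence[tuple[Position, str, int]]):
        per_hap: tuple[list, list] = ([], [])
        for pos, sym, assignment in fixed:
            v = _variant_for(db, pos, sym, refs.get(pos, db.ref_symbol(pos)))
            if assignment == "both":
                per_hap[0].append(v)
                per_hap[1].append(v)
            else:
                per_hap[assignment].append(v)
        for pos, sym, hap in placed:
            per_hap[hap].append(_variant_for(db, pos, sym, refs.get(pos, db.ref_symbol(pos))))
        n1, v1 = _name_novel(db, a, per_hap[0])
        n2, v2 = _name_novel(db, b, per_hap[1])
        pair = tuple(sorted((n1, n2)))
        return pair, {n1: v1, n2: v2}

    if not free:
        pair, defs = build(())
        return [(pair, defs, tuple(notes), evidence)]

    arrangements = []
    all_combos = list(itertools.product((0, 1), repeat=len(free)))
    for combo in all_combos:
        placed = placements(combo)
        ok = True
        for hap_idx, bg in ((0, a), (1, b)):
            proj = list(db.haplotype_projection(str(bg.name), ARMS_POSITIONS))
            for pos, sym, hap in placed:
                if hap == hap_idx and pos in ARMS_POSITIONS:
                    proj[ARMS_POSITIONS.index(pos)] = sym
            if not all(rule.ok(tuple(proj)) for rule in rules):
                ok = False
                break
        if ok:
            arrangements.append(combo)
    if len(arrangements) == 1:
        pair, defs = build(placements(arrangements[0]))
        return [(pair, defs, tuple(notes), "population_constraint")]
    out = []
    for combo in arrangements or all_combos:
        pair, defs = build(placements(combo))
        out.append((pair, defs, tuple(notes + ["unphased residual variant"]), "none"))
    return out


def _phase_by_cooccurrence(
    obs: ObservedGenotype, db: AlleleDB, a: Allele, b: Allele, pos: Position, sym: str
) -> Optional[int]:
    """Assign a residual het variant to the haplotype whose background base
    matches a read-backed co-observation at an informative position."""
    for p1, s1, p2, s2, n in obs.cooccurrence:
        if n <= 0:
            continue
        if (p1, s1) == (pos, sym):
            other_pos, other_sym = p2, s2
        elif (p2, s2) == (pos, sym):
            other_pos, other_sym = p1, s1
        else:
            continue
        ref = obs.refs.get(other_pos, db.ref_symbol(other_pos))
        ba, bb = a.base_at(other_pos, ref), b.base_at(other_pos, ref)
        if ba == bb:
            continue
        if other_sym == ba:
            return 0
        if other_sym == bb:
            return 1
    return None


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def call_diplotype(
    pileups: Iterable[FragmentPileup],
    db: AlleleDB,
    params: CallingParams = CallingParams(),
    arms: Optional[ArmsResult] = None,
    rules: Sequence[PhaseRule] = DEFAULT_PHASE_RULES,
    sample_id: str = "sample",
) -> tuple[ObservedGenotype, Diplotype]:
    """Pileups -> observed genotype -> diplotype, resolving ambiguity with
    ARMS evidence / phase constraints and constructing novel alleles."""
    obs = call_sample(pileups, db, params, sample_id)
    dip = intersect_allele_groups(obs, db)
    if dip.status == "ambiguous":
        dip = resolve_with_phase_constraints(dip, db, arms=arms, rules=rules)
    if dip.status == "novel":
        dip = construct_novel_alleles(obs, db, rules=rules)
    return obs, dip
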