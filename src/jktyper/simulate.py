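"""Synthetic-data generator for the JK genotyping pipeline.

Cohorts of diploid donors are drawn panel by panel from the observed
panel-specific allele frequencies (random mating, Hardy-Weinberg ratios);
each sample's per-amplicon pileups are simulated with a dispersed coverage
model (negative-binomial counts around the configured mean), an even 50:50
draw of reads from the two haplotypes, and uniform per-base sequencing
error.  A configurable fraction of samples is "degraded": their coverage is
scaled down so that fragments fail the acceptance rules and the sample
becomes a no-call, emulating poor-quality DNA.  Double-ARMS band patterns
and serotype records (with an adjustable sample mix-up rate) complete the
round trip through calling, phenotyping and frequency counting.

Randomness is reproducible: every sample derives its own generator from
(seed, sample index), so cohorts are stable under parallel generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .alleledb import AlleleDB, default_db
from .calling import (
    ARMS_POSITIONS,
    ArmsResult,
    CoRecord,
    FragmentPileup,
    predict_arms_bands,
)
from .phenotype import SerotypeRecord, allele_expression
from .popgen import PANEL_CODES, load_cohort_table, load_table5_counts

__all__ = [
    "SimConfig",
    "SimSample",
    "default_panel_frequencies",
    "simulate_cohort",
    "simulate_pileups",
    "simulate_arms",
    "simulate_serotypes",
]

_ERROR_TARGETS = ("A", "C", "G", "T")


def default_panel_frequencies() -> dict[str, dict[str, float]]:
    """Panel-specific allele frequencies, normalized from the shipped
    panel-count table (alleles observed at least five times plus all
    referenced alleles; the rare remainder is folded proportionally)."""
    counts = load_table5_counts()
    counts = counts[~counts["allele"].str.endswith("_total")]
    freqs: dict[str, dict[str, float]] = {}
    for panel in PANEL_CODES:
        col = counts[panel].astype(int)
        total = int(col.sum())
        if total == 0:
            continue
        freqs[panel] = {
            allele: c / total
            for allele, c in zip(counts["allele"], col)
            if c > 0
        }
    return freqs


def _default_panel_n() -> dict[str, int]:
    cohort = load_cohort_table()
    return {
        str(r.panel): int(r.genotyped)
        for r in cohort.itertuples()
        if r.panel != "Total"
    }


@dataclass
class SimConfig:
    """Study-condition defaults for the generator.

    Mean amplicon coverage 300x with negative-binomial dispersion 20 (about a
    23% coefficient of variation; wide enough to emulate the reported spread
    of per-amplicon means while keeping coverage failures a property of
    degraded samples, which is where the assay's no-calls came from),
    per-base error rate 0.5%, a degraded-sample fraction of 30/7,512 at a
    0.1 coverage scale (reproducing the observed no-call rate), and a
    serotype mix-up rate of 5/551 (the observed discrepancy rate).
    """

    seed: int = 0
    panel_frequencies: dict[str, dict[str, float]] = field(
        default_factory=default_panel_frequencies
    )
    n_per_panel: dict[str, int] = field(default_factory=_default_panel_n)
    mean_coverage: float = 300.0
    dispersion: float = 20.0
    error_rate: float = 0.005
    degraded_fraction: float = 30 / 7512
    degraded_scale: float = 0.1
    serotype_mixup_rate: float = 5 / 551

    def __post_init__(self) -> None:
        for panel, freqs in self.panel_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"panel {panel}: frequencies sum to {total!r}, not 1")
        for rate in (self.error_rate, self.degraded_fraction, self.degraded_scale,
                     self.serotype_mixup_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimSample:
    sample_id: str
    panel: str
    alleles: tuple[str, str]
    index: int
    degraded: bool = False


def _rng(config: SimConfig, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, index, stream])


def simulate_cohort(
    config: SimConfig,
    db: Optional[AlleleDB] = None,
    n_per_panel: Optional[Mapping[str, int]] = None,
) -> list[SimSample]:
    """Draw a labeled cohort: per panel, each sample draws two alleles
    independently from the panel's frequency vector (random mating)."""
    db = db or default_db()
    sizes = dict(n_per_panel if n_per_panel is not None else config.n_per_panel)
    samples: list[SimSample] = []
    index = 0
    for panel in sorted(sizes):
        freqs = config.panel_frequencies.get(panel)
        if freqs is None:
            raise ValueError(f"no allele frequencies for panel {panel}")
        for name in freqs:
            if name not in db:
                raise ValueError(f"unknown allele in frequency table: {name}")
        names = sorted(freqs)
        probs = np.array([freqs[n] for n in names])
        probs = probs / probs.sum()
        for _ in range(sizes[panel]):
            rng = _rng(config, index, 0)
            pair = tuple(sorted(str(n) for n in rng.choice(names, size=2, p=probs)))
            degraded = bool(rng.random() < config.degraded_fraction)
            samples.append(
                SimSample(f"S{index:06d}", panel, pair, index, degraded)
            )
            index += 1
    return samples


def simulate_pileups(
    sample: SimSample,
    db: AlleleDB,
    config: SimConfig,
) -> list[FragmentPileup]:
    """Per-amplicon pileups for one simulated sample.

    Depth per amplicon is negative-binomially dispersed around the mean
    (scaled down for degraded samples); each read derives from either
    haplotype with probability 0.5 and is mismapped to a uniformly chosen
    other base at the error rate.  Read-backed co-occurrence records are
    emitted for het-variant pairs within the same amplicon."""
    rng = _rng(config, sample.index, 1)
    a, b = (db[n] for n in sample.alleles)
    mean = config.mean_coverage * (config.degraded_scale if sample.degraded else 1.0)
    by_amp: dict[str, list[tuple[int, int]]] = {f"exon{n}": [] for n in range(3, 11)}
    for pos in db.positions:
        by_amp[f"exon{db.exon_map.amplicon_of(pos)}"].append(pos)
    k = config.dispersion
    pileups = []
    for amp, positions in by_amp.items():
        p_nb = k / (k + mean)
        depth = int(rng.negative_binomial(k, p_nb)) if mean > 0 else 0
        n1 = int(rng.binomial(depth, 0.5))
        counts: dict[tuple[int, int], dict[str, int]] = {}
        refs: dict[tuple[int, int], str] = {}
        het_sites: list[tuple[tuple[int, int], str, str]] = []
        for pos in positions:
            ref = db.ref_symbol(pos)
            refs[pos] = ref
            b1 = a.base_at(pos, ref)
            b2 = b.base_at(pos, ref)
            if b1 != b2:
                het_sites.append((pos, b1, b2))
            site: dict[str, int] = {}
            for true_base, n_src in ((b1, n1), (b2, depth - n1)):
                errs = int(rng.binomial(n_src, config.error_rate))
                site[true_base] = site.get(true_base, 0) + n_src - errs
                if errs:
                    targets = [t for t in _ERROR_TARGETS if t != true_base]
                    spread = rng.multinomial(errs, [1 / len(targets)] * len(targets))
                    for t, n_err in zip(targets, spread):
                        if n_err:
                            site[t] = site.get(t, 0) + int(n_err)
            counts[pos] = site
        co: list[CoRecord] = []
        for i, (p1, a1, b1_) in enumerate(het_sites):
            for p2, a2, b2_ in het_sites[i + 1:]:
                co.append((p1, a1, p2, a2, n1))
                co.append((p1, b1_, p2, b2_, depth - n1))
        pileups.append(FragmentPileup(amp, counts, refs, tuple(co)))
    return pileups


def simulate_arms(sample: SimSample, db: AlleleDB) -> ArmsResult:
    """Band pattern of the two double-ARMS reactions for a simulated
    diplotype: a combo band is present iff some haplotype carries both
    primer-matched bases; control bands always amplify."""
    haps = tuple(
        sorted(tuple(db.haplotype_projection(n, ARMS_POSITIONS)) for n in sample.alleles)
    )
    a_bands, b_bands = predict_arms_bands(haps)  # type: ignore[arg-type]
    return ArmsResult(a_bands, b_bands, True, True)


def simulate_serotypes(
    samples: Sequence[SimSample],
    db: AlleleDB,
    config: SimConfig,
) -> list[SerotypeRecord]:
    """Serotype records under the revised phenotype table, with sample
    mix-ups injected at the configured rate (each affected record swaps with
    a uniformly chosen other sample's record)."""
    records: list[SerotypeRecord] = []
    for sample in samples:
        pos = {"JK1": "neg", "JK2": "neg"}
        weak = False
        for name in sample.alleles:
            antigen, level = allele_expression(db[name], "revised")
            if level in ("normal", "weak"):
                pos[antigen] = "pos"
                weak = weak or (level == "weak" and pos[antigen] != "normal")
        intensity = 4 if "pos" in pos.values() else 0
        records.append(SerotypeRecord(sample.sample_id, pos["JK1"], pos["JK2"], intensity))
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 2])
    n = len(records)
    if n == 1 and config.serotype_mixup_rate > 0:
        import warnings

        warnings.warn("cannot inject serotype mix-ups with a single sample")
        return records
    for i in range(n):
        if rng.random() < config.serotype_mixup_rate:
            j = int(rng.integers(0, n - 1))
            j = j if j < i else j + 1
            ri, rj = records[i], records[j]
            records[i] = SerotypeRecord(ri.sample_id, rj.jk1, rj.jk2, rj.intensity)
            records[j] = SerotypeRecord(rj.sample_id, ri.jk1, ri.jk2, ri.intensity)
    return records
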