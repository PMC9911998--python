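"""Synthetic cohort, pileup, ARMS and serotype generation."""

import math

import numpy as np
import pytest

from jktyper.calling import call_diplotype, call_sample, interpret_double_arms
from jktyper.phenotype import concordance_report, predict_phenotype
from jktyper.simulate import (
    SimConfig,
    simulate_arms,
    simulate_cohort,
    simulate_pileups,
    simulate_serotypes,
)


def _config(seed=11, **kw):
    defaults = dict(seed=seed)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestCohortDraws:
    def test_same_seed_identical_cohort(self, db):
        cfg = _config()
        a = simulate_cohort(cfg, db, {"TUR": 50})
        b = simulate_cohort(cfg, db, {"TUR": 50})
        assert a == b

    def test_different_seed_differs(self, db):
        a = simulate_cohort(_config(seed=1), db, {"TUR": 50})
        b = simulate_cohort(_config(seed=2), db, {"TUR": 50})
        assert a != b

    def test_single_allele_frequency_one_gives_homozygotes(self, db):
        cfg = _config(panel_frequencies={"TUR": {"JK*01": 1.0}},
                      degraded_fraction=0.0)
        samples = simulate_cohort(cfg, db, {"TUR": 200})
        assert all(s.alleles == ("JK*01", "JK*01") for s in samples)

    def test_hardy_weinberg_proportions_within_3se(self, db):
        p = 0.5
        n = 4000
        cfg = _config(
            panel_frequencies={"TUR": {"JK*01": p, "JK*02W.03": 1 - p}},
            degraded_fraction=0.0,
        )
        samples = simulate_cohort(cfg, db, {"TUR": n})
        het = sum(1 for s in samples if s.alleles == ("JK*01", "JK*02W.03"))
        expected, se = 2 * p * (1 - p) * n, math.sqrt(n * 0.5 * 0.5)
        assert abs(het - expected) <= 3 * se

    def test_unknown_allele_in_frequency_table_rejected(self, db):
        cfg = _config(panel_frequencies={"TUR": {"JK*99": 1.0}})
        with pytest.raises(ValueError, match="unknown allele"):
            simulate_cohort(cfg, db, {"TUR": 1})

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            _config(panel_frequencies={"TUR": {"JK*01": 0.7}})


class TestPileups:
    def test_error_free_hom_sample_has_no_offtarget_bases(self, db):
        cfg = _config(error_rate=0.0, degraded_fraction=0.0)
        samples = simulate_cohort(
            _config(panel_frequencies={"TUR": {"JK*02W.03": 1.0}},
                    error_rate=0.0, degraded_fraction=0.0),
            db, {"TUR": 3},
        )
        for s in samples:
            for pile in simulate_pileups(s, db, cfg):
                for pos, counts in pile.counts.items():
                    ref = pile.refs[pos]
                    expected = db["JK*02W.03"].base_at(pos, ref)
                    assert set(b for b, c in counts.items() if c > 0) <= {expected}

    def test_het_minor_fraction_near_half(self, db):
        """At 300x error-free coverage, heterozygous sites show a minor-allele
        fraction within [0.4, 0.6] in at least 95% of deep amplicons."""
        cfg = _config(error_rate=0.0, degraded_fraction=0.0,
                      panel_frequencies={"TUR": {"JK*01": 0.5, "JK*02W.03": 0.5}})
        inside = outside = 0
        for s in simulate_cohort(cfg, db, {"TUR": 120}):
            if s.alleles != ("JK*01", "JK*02W.03"):
                continue
            for pile in simulate_pileups(s, db, cfg):
                for pos in ((588, 0), (838, 0)):
                    if pos not in pile.counts:
                        continue
                    counts = pile.counts[pos]
                    depth = sum(counts.values())
                    if depth < 100:
                        continue
                    minor = min(counts.values()) / depth
                    if 0.4 <= minor <= 0.6:
                        inside += 1
                    else:
                        outside += 1
        assert inside / (inside + outside) >= 0.95

    def test_degraded_sample_becomes_no_call(self, db):
        cfg = _config(degraded_fraction=1.0, degraded_scale=0.1)
        (s,) = simulate_cohort(cfg, db, {"TUR": 1})
        assert s.degraded
        obs = call_sample(simulate_pileups(s, db, cfg), db)
        assert obs.status == "no_call"

    def test_pileups_cover_every_database_position(self, db):
        cfg = _config(degraded_fraction=0.0)
        (s,) = simulate_cohort(cfg, db, {"TUR": 1})
        piles = simulate_pileups(s, db, cfg)
        covered = {p for pile in piles for p in pile.counts}
        assert covered == set(db.positions)
        assert {p.amplicon_id for p in piles} == {f"exon{n}" for n in range(3, 11)}


class TestArms:
    def test_reference_homozygote_band_pattern(self, db):
        cfg = _config(panel_frequencies={"TUR": {"JK*01": 1.0}},
                      degraded_fraction=0.0)
        (s,) = simulate_cohort(cfg, db, {"TUR": 1})
        arms = simulate_arms(s, db)
        assert arms.a_bands == frozenset({("A", "G")})
        assert arms.b_bands == frozenset({("G", "G")})

    def test_interpretation_contains_simulated_truth(self, db):
        cfg = _config(degraded_fraction=0.0)
        from jktyper.calling import ARMS_POSITIONS

        for s in simulate_cohort(cfg, db, {"SEEA": 40}):
            truth = tuple(sorted(
                tuple(db.haplotype_projection(n, ARMS_POSITIONS))
                for n in s.alleles
            ))
            assert truth in interpret_double_arms(simulate_arms(s, db))


class TestSerotypes:
    def test_zero_mixup_rate_gives_full_concordance(self, db):
        cfg = _config(serotype_mixup_rate=0.0, degraded_fraction=0.0)
        samples = simulate_cohort(cfg, db, {"TUR": 80})
        records = simulate_serotypes(samples, db, cfg)
        preds = {}
        from jktyper.calling import Diplotype

        for s in samples:
            preds[s.sample_id] = predict_phenotype(
                Diplotype(s.alleles, "unique"), db, "revised"
            )
        rep = concordance_report(preds, records)
        assert rep.discordant == 0

    def test_single_sample_cannot_mix_up(self, db):
        cfg = _config(serotype_mixup_rate=0.5, degraded_fraction=0.0)
        samples = simulate_cohort(cfg, db, {"TUR": 1})
        with pytest.warns(UserWarning, match="single sample"):
            records = simulate_serotypes(samples, db, cfg)
        assert len(records) == 1

    def test_mixup_rate_reproduces_discrepancy_scale(self, db):
        """With the observed mix-up rate (5/551) the mean discordance over
        replicates approaches 0.91% (a swap may pair phenotype-identical
        samples, so the realized rate is bounded above by the swap rate)."""
        n, reps = 551, 4
        rates = []
        from jktyper.calling import Diplotype

        for rep_i in range(reps):
            cfg = _config(seed=100 + rep_i, degraded_fraction=0.0)
            samples = simulate_cohort(cfg, db, {"TUR": n})
            records = simulate_serotypes(samples, db, cfg)
            preds = {
                s.sample_id: predict_phenotype(
                    Diplotype(s.alleles, "unique"), db, "revised"
                )
                for s in samples
            }
            rep = concordance_report(preds, records)
            rates.append(rep.discordant / max(rep.evaluated, 1))
        mean = sum(rates) / reps
        p = 5 / 551
        se = math.sqrt(p * (1 - p) / (n * reps))
        assert mean <= p + 3 * se
        assert mean >= 0.0


class TestEndToEndSmall:
    def test_pipeline_recovers_diplotypes(self, db):
        cfg = _config(degraded_fraction=0.0)
        samples = simulate_cohort(cfg, db, {"TUR": 30, "SSAF": 10})
        recovered = 0
        for s in samples:
            _, dip = call_diplotype(
                simulate_pileups(s, db, cfg), db, sample_id=s.sample_id
            )
            recovered += dip.status == "unique" and dip.alleles == s.alleles
        assert recovered >= 39  # at most one slip in 40 clean samples
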