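"""Pileup genotyping, the intersection caller, ARMS interpretation and
novel-allele construction."""

import itertools

import pytest

from jktyper.alleledb import AlleleDB, load_allele_db, data_path
from jktyper.calling import (
    ARMS_POSITIONS,
    ArmsResult,
    CallingParams,
    DEFAULT_PHASE_RULES,
    Diplotype,
    FragmentPileup,
    InconsistencyError,
    RunMetrics,
    call_sample,
    construct_novel_alleles,
    genotype_position,
    interpret_double_arms,
    intersect_allele_groups,
    predict_arms_bands,
    qc_run,
    resolve_with_phase_constraints,
)
from conftest import observed_from_pair


class TestRunQC:
    @pytest.mark.parametrize(
        "metrics,ok,keyword",
        [
            ((1000, 80, 85), True, ""),
            ((700, 80, 85), False, "density"),
            ((1000, 65, 85), False, "filter"),
            ((1000, 80, 60), False, "Q30"),
            ((800, 70.1, 70.1), True, ""),
            ((1300, 80, 85), True, ""),
        ],
    )
    def test_gate(self, metrics, ok, keyword):
        passed, reasons = qc_run(RunMetrics(*metrics))
        assert passed is ok
        if keyword:
            assert any(keyword in r for r in reasons)


class TestGenotypePosition:
    def test_balanced_het_passes(self):
        call = genotype_position({"G": 150, "A": 145, "C": 2})
        assert call.bases == ("A", "G") and call.zygosity == "het" and call.qc_pass

    def test_homozygous_below_80_fails(self):
        call = genotype_position({"G": 60})
        assert call.bases == ("G", "G") and call.zygosity == "hom"
        assert not call.qc_pass

    def test_het_minor_below_30_reads_fails(self):
        call = genotype_position({"G": 200, "A": 25})
        assert not call.qc_pass

    def test_three_bases_uninterpretable(self):
        call = genotype_position({"G": 100, "A": 100, "C": 100})
        assert call.bases is None and not call.qc_pass

    def test_zero_coverage_uninterpretable(self):
        call = genotype_position({"G": 0})
        assert call.bases is None and not call.qc_pass

    def test_error_floor_removes_noise(self):
        call = genotype_position({"G": 400, "A": 5, "T": 3})
        assert call.bases == ("G", "G") and call.qc_pass

    def test_het_at_exact_thresholds(self):
        call = genotype_position({"G": 30, "A": 30})
        assert call.zygosity == "het" and call.qc_pass


def _pileups_for(db, name1, name2, depth=300):
    """Noise-free pileups for an allele pair at every database position."""
    a, b = db[name1], db[name2]
    groups = {f"exon{n}": {} for n in range(3, 11)}
    refs = {f"exon{n}": {} for n in range(3, 11)}
    for pos in db.positions:
        amp = f"exon{db.exon_map.amplicon_of(pos)}"
        ref = db.ref_symbol(pos)
        counts = {}
        for base in (a.base_at(pos, ref), b.base_at(pos, ref)):
            counts[base] = counts.get(base, 0) + depth // 2
        groups[amp][pos] = counts
        refs[amp][pos] = ref
    return [FragmentPileup(amp, groups[amp], refs[amp]) for amp in groups]


class TestCallSample:
    def test_clean_reference_sample_called(self, db):
        obs = call_sample(_pileups_for(db, "JK*01", "JK*01"), db)
        assert obs.status == "called"
        assert obs.nonref_positions == ()

    def test_low_coverage_fragment_fails_whole_sample(self, db):
        piles = _pileups_for(db, "JK*01", "JK*01")
        weak = piles[0]
        low = {p: {b: 10 for b in c} for p, c in weak.counts.items()}
        piles[0] = FragmentPileup(weak.amplicon_id, low, weak.refs)
        obs = call_sample(piles, db)
        assert obs.status == "no_call"
        assert any(weak.amplicon_id == a for a, _ in obs.failing_fragments)

    def test_missing_amplicon_is_no_call(self, db):
        piles = _pileups_for(db, "JK*01", "JK*01")[1:]
        obs = call_sample(piles, db)
        assert obs.status == "no_call"
        assert any("missing fragment" in r for _, r in obs.failing_fragments)


def brute_force_pairs(obs, db):
    """Independent oracle: score every unordered allele pair directly
    against the observed genotype at every position."""
    names = sorted(db.alleles)
    refs = {p: db.ref_symbol(p) for p in db.positions}
    positions = sorted(set(refs) | set(obs.genotypes))
    out = []
    for i, n1 in enumerate(names):
        for n2 in names[i:]:
            a, b = db[n1], db[n2]
            ok = True
            for p in positions:
                ref = obs.refs.get(p, refs.get(p, "N"))
                want = obs.genotypes.get(p, (ref, ref))
                have = tuple(sorted((a.base_at(p, ref), b.base_at(p, ref))))
                if tuple(sorted(want)) != have:
                    ok = False
                    break
            if ok:
                out.append((n1, n2))
    return sorted(out)


class TestIntersection:
    def test_reference_genotype_calls_jk01_homozygote(self, db):
        dip = intersect_allele_groups(observed_from_pair(db, "JK*01", "JK*01"), db)
        assert dip.status == "unique" and dip.alleles == ("JK*01", "JK*01")

    def test_hom_588G_838A_is_jk02w03_homozygote(self, db):
        dip = intersect_allele_groups(
            observed_from_pair(db, "JK*02W.03", "JK*02W.03"), db
        )
        assert dip.status == "unique"
        assert dip.alleles == ("JK*02W.03", "JK*02W.03")

    def test_het_588_838_is_ambiguous_two_pairs(self, db):
        dip = intersect_allele_groups(observed_from_pair(db, "JK*01", "JK*02W.03"), db)
        assert dip.status == "ambiguous"
        assert set(dip.candidates) == {
            ("JK*01", "JK*02W.03"),
            ("JK*01W.06", "JK*02"),
        }

    def test_novel_when_no_pair_matches(self, db):
        obs = observed_from_pair(
            db, "JK*01", "JK*01", overrides={(700, 0): ("A", "G")}
        )
        dip = intersect_allele_groups(obs, db)
        assert dip.status == "novel"

    def test_no_call_passthrough(self, db):
        from jktyper.calling import ObservedGenotype

        obs = ObservedGenotype("s", "no_call", {}, {}, (("exon3", "low"),))
        assert intersect_allele_groups(obs, db).status == "no_call"

    @pytest.mark.parametrize(
        "pair",
        [
            ("JK*01", "JK*01N.20"),
            ("JK*01W.01.588A_G", "JK*02W.03"),
            ("JK*02N.17.588A_G", "JK*02W.03"),
            ("JK*01", "JK*02W.03.M167V"),
            ("JK*02W.03.1095T_C", "JK*02W.03.1095T_C"),
        ],
    )
    def test_matches_brute_force_oracle(self, db, pair):
        obs = observed_from_pair(db, *pair)
        dip = intersect_allele_groups(obs, db)
        expected = brute_force_pairs(obs, db)
        got = sorted(dip.candidates) if dip.status == "ambiguous" else (
            [dip.alleles] if dip.alleles else []
        )
        assert got == expected

    def test_unique_calls_reproduce_observation(self, db):
        """Soundness: the union of a unique pair's variant genotypes equals
        the observed genotype at every covered position."""
        obs = observed_from_pair(db, "JK*01N.20", "JK*02N.17.588A_G")
        dip = intersect_allele_groups(obs, db)
        assert dip.status == "unique"
        a, b = (db[n] for n in dip.alleles)
        for pos, want in obs.genotypes.items():
            ref = obs.refs[pos]
            assert tuple(sorted((a.base_at(pos, ref), b.base_at(pos, ref)))) == want


def arms_oracle(result):
    """36-pair brute-force oracle for double-ARMS interpretation."""
    haps = list(itertools.product("AG", "GA", "GA"))
    pairs = [
        tuple(sorted((h1, h2)))
        for i, h1 in enumerate(haps)
        for h2 in haps[i:]
    ]
    return tuple(
        sorted(
            {
                p
                for p in pairs
                if predict_arms_bands(p) == (result.a_bands, result.b_bands)
            }
        )
    )


class TestDoubleArms:
    def test_four_band_pattern_resolves_01_vs_02n17_588ag(self, db):
        res = ArmsResult.from_bools(
            a_588A_810G=True, a_588A_810A=False, a_588G_810G=False, a_588G_810A=True,
            b_810G_838G=True, b_810A_838G=False, b_810G_838A=False, b_810A_838A=True,
        )
        pairs = interpret_double_arms(res)
        assert pairs == ((("A", "G", "G"), ("G", "A", "A")),)
        # i.e. JK*01-type / JK*02N.17.588A_G-type haplotypes
        assert tuple(db.haplotype_projection("JK*01", ARMS_POSITIONS)) == ("A", "G", "G")
        assert tuple(
            db.haplotype_projection("JK*02N.17.588A_G", ARMS_POSITIONS)
        ) == ("G", "A", "A")

    def test_all_bands_present_is_impossible_for_a_diploid(self):
        """Two chromosomes project at most two combos per reaction, so a
        four-band reaction cannot be explained by any haplotype pair — the
        36-pair oracle agrees (suggests reaction failure)."""
        res = ArmsResult.from_bools(*([True] * 8))
        assert arms_oracle(res) == ()
        with pytest.raises(InconsistencyError):
            interpret_double_arms(res)

    def test_control_band_absent_is_error(self):
        res = ArmsResult.from_bools(*([True] * 8), control_a=False)
        with pytest.raises(InconsistencyError, match="control"):
            interpret_double_arms(res)

    def test_impossible_pattern_is_error(self):
        res = ArmsResult.from_bools(
            a_588A_810G=True, a_588A_810A=True, a_588G_810G=True, a_588G_810A=False,
            b_810G_838G=True, b_810A_838G=False, b_810G_838A=False, b_810A_838A=False,
        )
        with pytest.raises(InconsistencyError):
            interpret_double_arms(res)

    def test_interpreter_equals_oracle_on_sampled_patterns(self):
        combos_a = list(itertools.product("AG", "GA"))
        combos_b = list(itertools.product("GA", "GA"))
        for bits in range(0, 256, 7):  # every 7th of the 2^8 patterns
            a = frozenset(c for i, c in enumerate(combos_a) if bits & (1 << i))
            b = frozenset(c for i, c in enumerate(combos_b) if bits & (1 << (i + 4)))
            res = ArmsResult(a, b)
            expected = arms_oracle(res)
            if expected:
                assert interpret_double_arms(res) == expected
            else:
                with pytest.raises(InconsistencyError):
                    interpret_double_arms(res)


class TestPhaseResolution:
    def test_jk2_linkage_rule_resolves_588_838_ambiguity(self, db):
        dip = Diplotype(
            None, "ambiguous",
            candidates=(("JK*01", "JK*02W.03"), ("JK*01W.06", "JK*02")),
        )
        out = resolve_with_phase_constraints(dip, db, frequency_tiebreak=False)
        assert out.status == "unique"
        assert out.alleles == ("JK*01", "JK*02W.03")
        assert out.phasing_evidence == "population_constraint"

    def test_no_rules_no_arms_leaves_ambiguity(self, db):
        dip = Diplotype(
            None, "ambiguous",
            candidates=(("JK*01", "JK*02W.03"), ("JK*01W.06", "JK*02")),
        )
        out = resolve_with_phase_constraints(
            dip, db, rules=(), frequency_tiebreak=False
        )
        assert out.status == "ambiguous" and len(out.candidates) == 2

    def test_arms_with_het_810_resolves(self, db):
        dip = Diplotype(
            None, "ambiguous",
            candidates=(
                ("JK*01", "JK*02N.17.588A_G"),
                ("JK*01W.06", "JK*02N.17"),
            ),
        )
        res = ArmsResult.from_bools(
            a_588A_810G=True, a_588A_810A=False, a_588G_810G=False, a_588G_810A=True,
            b_810G_838G=True, b_810A_838G=False, b_810G_838A=False, b_810A_838A=True,
        )
        out = resolve_with_phase_constraints(dip, db, arms=res, rules=(),
                                             frequency_tiebreak=False)
        assert out.status == "unique"
        assert out.alleles == ("JK*01", "JK*02N.17.588A_G")
        assert out.phasing_evidence == "arms"

    def test_arms_excluding_everything_is_error(self, db):
        dip = Diplotype(None, "ambiguous", candidates=(("JK*01", "JK*01"),))
        res = ArmsResult.from_bools(
            a_588A_810G=False, a_588A_810A=False, a_588G_810G=True, a_588G_810A=False,
            b_810G_838G=True, b_810A_838G=False, b_810G_838A=False, b_810A_838A=False,
        )
        with pytest.raises(InconsistencyError):
            resolve_with_phase_constraints(dip, db, arms=res)

    def test_frequency_tiebreak_prefers_common_pair(self, db):
        dip = Diplotype(
            None, "ambiguous",
            candidates=(
                ("JK*01", "JK*02W.03.1095T_C"),
                ("JK*01.1095T_C", "JK*02W.03"),
            ),
        )
        out = resolve_with_phase_constraints(dip, db)
        assert out.status == "unique"
        assert out.alleles == ("JK*01", "JK*02W.03.1095T_C")
        assert out.phasing_evidence == "population_constraint"


@pytest.fixture(scope="module")
def isbt_db(exon_map):
    """Referenced alleles only — novel variants are genuinely novel here."""
    return load_allele_db(data_path("isbt.tsv"), exon_map, source="isbt")


class TestNovelConstruction:
    def test_het_residual_phased_by_cooccurrence(self, isbt_db):
        db = isbt_db
        obs = observed_from_pair(db, "JK*01", "JK*02W.03",
                                 overrides={(268, 0): ("C", "T")},
                                 ref_overrides={(268, 0): "C"})
        obs = type(obs)(
            obs.sample_id, obs.status, obs.genotypes, obs.refs,
            cooccurrence=(((268, 0), "T", (838, 0), "A", 140),),
        )
        dip = construct_novel_alleles(obs, db)
        assert dip.status == "novel"
        assert dip.alleles == ("JK*01", "JK*02W.03.268C_T")

    def test_hom_residual_assigned_to_both(self, isbt_db):
        db = isbt_db
        obs = observed_from_pair(db, "JK*02W.03", "JK*02W.03",
                                 overrides={(1095, 0): ("C", "C")},
                                 ref_overrides={(1095, 0): "T"})
        dip = construct_novel_alleles(obs, db)
        assert dip.status == "novel"
        assert dip.alleles == ("JK*02W.03.1095T_C", "JK*02W.03.1095T_C")

    def test_annotation_reuse_and_nucleotide_fallback(self, db, exon_map):
        """A residual matching a database-known variant reuses its amino-acid
        token (V175I, still known via another allele); a residual nobody else
        carries falls back to the nucleotide token (284C_T)."""
        smaller = AlleleDB(
            {n: a for n, a in db.alleles.items() if n != "JK*02W.03.T95I_V175I"},
            exon_map,
        )
        obs = observed_from_pair(
            smaller, "JK*01", "JK*02W.03",
            overrides={(284, 0): ("C", "T"), (523, 0): ("A", "G")},
            ref_overrides={(284, 0): "C"},
        )
        obs = type(obs)(
            obs.sample_id, obs.status, obs.genotypes, obs.refs,
            cooccurrence=(
                ((284, 0), "T", (838, 0), "A", 140),
                ((523, 0), "A", (838, 0), "A", 140),
            ),
        )
        dip = construct_novel_alleles(obs, smaller)
        assert dip.status == "novel"
        assert dip.alleles == ("JK*01", "JK*02W.03.V175I_284C_T")

    def test_same_background_partner_notes_serotype_limit(self, isbt_db):
        db = isbt_db
        obs = observed_from_pair(db, "JK*01", "JK*01",
                                 overrides={(442, 0): ("C", "T")},
                                 ref_overrides={(442, 0): "C"})
        dip = construct_novel_alleles(obs, db)
        assert dip.status == "novel"
        assert dip.alleles == ("JK*01", "JK*01.442C_T")
        assert any("same background" in n for n in dip.notes)

    def test_unphased_residual_returns_both_arrangements(self, isbt_db):
        db = isbt_db
        obs = observed_from_pair(db, "JK*01", "JK*02W.03",
                                 overrides={(1095, 0): ("C", "T")},
                                 ref_overrides={(1095, 0): "T"})
        dip = construct_novel_alleles(obs, db)
        assert dip.status == "ambiguous_novel"
        assert set(dip.candidates) == {
            ("JK*01", "JK*02W.03.1095T_C"),
            ("JK*01.1095T_C", "JK*02W.03"),
        }
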