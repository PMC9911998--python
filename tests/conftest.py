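import pytest

from jktyper import default_db, default_exon_map
from jktyper.calling import ObservedGenotype


@pytest.fixture(scope="session")
def exon_map():
    return default_exon_map()


@pytest.fixture(scope="session")
def db(exon_map):
    return default_db(exon_map)


def observed_from_pair(db, name1, name2, sample_id="truth", overrides=None,
                       ref_overrides=None):
    """Noise-free observed genotype of a known allele pair at every database
    position (plus explicit per-position overrides)."""
    refs = {p: db.ref_symbol(p) for p in db.positions}
    if ref_overrides:
        refs.update(ref_overrides)
    a, b = db[name1], db[name2]
    genotypes = {
        p: tuple(sorted((a.base_at(p, refs[p]), b.base_at(p, refs[p]))))
        for p in refs
    }
    if overrides:
        for pos, pair in overrides.items():
            genotypes[pos] = tuple(sorted(pair))
            refs.setdefault(pos, db.ref_symbol(pos))
    return ObservedGenotype(
        sample_id=sample_id,
        status="called",
        genotypes=genotypes,
        refs=refs,
    )


@pytest.fixture(scope="session")
def observed_pair(db):
    def _make(name1, name2, **kw):
        return observed_from_pair(db, name1, name2, **kw)

    return _make
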