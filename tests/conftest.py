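import pytest

from barcodedb.store import ReferenceDatabase, SequenceRecord
from barcodedb.taxonomy import Lineage


def make_lineage(family="FamA", genus=None, species=None, **kwargs):
    genus = genus or f"Gen{family}"
    defaults = dict(
        kingdom="K", phylum="P", class_="C", order=f"Ord{family}",
        family=family, genus=genus,
        species=species or f"{genus} sp1",
    )
    defaults.update(kwargs)
    return Lineage(**defaults)


def make_db(entries, log=None):
    """Build a ReferenceDatabase from (identifier, sequence, lineage) tuples."""
    records = [SequenceRecord(i, s) for i, s, _l in entries]
    taxonomy = {i: l for i, _s, l in entries}
    return ReferenceDatabase(records, taxonomy, log or [])


@pytest.fixture
def two_family_db(rng):
    """Two well-separated families of 4 records each, ~97% intra identity."""
    from tests.helpers import mutate, random_seq
    entries = []
    for fam in ("FamA", "FamB"):
        ancestor = random_seq(rng, 200)
        for i in range(4):
            ident = f"{fam}-{i}"
            entries.append((ident, mutate(rng, ancestor, 0.02),
                            make_lineage(fam, species=f"Gen{fam} sp{i}")))
    return make_db(entries)


@pytest.fixture
def rng():
    import numpy as np
    return np.random.default_rng(42)
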