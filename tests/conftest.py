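import pytest

from classfx import AssociationRecord, AssociationTable, Hierarchy


@pytest.fixture
def ae_hierarchy() -> Hierarchy:
    """Tiny AE ontology: root -> {digestive, neuro}; leaves under them."""
    edges = [
        ("AE:digestive", "AE:root"),
        ("AE:neuro", "AE:root"),
        ("AE:diarrhea", "AE:digestive"),
        ("AE:nausea", "AE:digestive"),
        ("AE:vomiting", "AE:digestive"),
        ("AE:headache", "AE:neuro"),
    ]
    return Hierarchy.from_edges(edges)


@pytest.fixture
def class_hierarchy() -> Hierarchy:
    """Two drug classes over four ingredients; i3 belongs to both."""
    edges = [
        ("CLS:glycosides", "CLS:root"),
        ("CLS:statins", "CLS:root"),
        ("ING:i1", "CLS:glycosides"),
        ("ING:i2", "CLS:glycosides"),
        ("ING:i3", "CLS:glycosides"),
        ("ING:i3", "CLS:statins"),
        ("ING:i4", "CLS:statins"),
    ]
    return Hierarchy.from_edges(edges)


@pytest.fixture
def small_table() -> AssociationTable:
    """Product-level records: i1/i2/i3 share diarrhea; i3 also headache."""
    recs = [
        AssociationRecord("P1", "diarrhea", ingredient_ids=("ING:i1",),
                          ae_id="AE:diarrhea"),
        AssociationRecord("P2", "diarrhea", ingredient_ids=("ING:i2",),
                          ae_id="AE:diarrhea"),
        AssociationRecord("P3", "diarrhea", ingredient_ids=("ING:i3",),
                          ae_id="AE:diarrhea"),
        AssociationRecord("P3", "headache", ingredient_ids=("ING:i3",),
                          ae_id="AE:headache"),
        AssociationRecord("P4", "nausea", ingredient_ids=("ING:i4",),
                          ae_id="AE:nausea"),
    ]
    return AssociationTable(records=recs)
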