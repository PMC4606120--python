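import pytest
from hypothesis import settings

from prdkit import (
    AnnotationTable,
    CompositionModel,
    PrDCall,
    PrDCallSet,
    ProteinRecord,
    ProteomeSet,
)
from prdkit.annotation import ProteinAnnotation

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def flat_model():
    """Uniform composition over the 20 standard residues."""
    return CompositionModel({a: 0.05 for a in "ACDEFGHIKLMNPQRSTVWY"})


@pytest.fixture
def nq_model():
    """Strongly N/Q-biased composition (negligible pseudocount)."""
    return CompositionModel({"N": 0.25, "Q": 0.25, "A": 0.25, "C": 0.25},
                            pseudocount=1e-12)


@pytest.fixture
def nq_background():
    return CompositionModel({"N": 0.05, "Q": 0.05, "A": 0.45, "C": 0.45},
                            pseudocount=1e-12)


@pytest.fixture
def tiny_proteome():
    return ProteomeSet([
        ProteinRecord("p1", "NNQQNNQQ", organism="orgA"),
        ProteinRecord("p2", "ACDEFGHIKL", organism="orgA"),
        ProteinRecord("p3", "MSTVWYACDE", organism="orgB", is_pathogen=True),
    ])


def make_call(accession, start, end, seq="N", organism=""):
    region = (seq * (end - start + 1))[: end - start + 1]
    return PrDCall(accession=accession, start=start, end=end,
                   score_bits=55.0, region_sequence=region,
                   organism=organism)


@pytest.fixture
def call_factory():
    return make_call


def make_callset(accessions, n_scanned=None, organism=""):
    calls = [make_call(acc, 1, 60, organism=organism) for acc in accessions]
    return PrDCallSet(calls=calls,
                      n_scanned=n_scanned if n_scanned else len(calls))


@pytest.fixture
def callset_factory():
    return make_callset


@pytest.fixture
def annotation_factory():
    def factory(entries):
        """entries: list of (accession, go_terms, pfam_domains)."""
        return AnnotationTable(
            ProteinAnnotation(accession=acc, go_terms=set(go),
                              pfam_domains=list(pfam))
            for acc, go, pfam in entries
        )
    return factory
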