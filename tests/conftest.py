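import pytest
from hypothesis import settings

settings.register_profile("suite", max_examples=50, derandomize=True)
settings.load_profile("suite")

from vernalnc import classification as cl
from vernalnc import expression_de as ed
from vernalnc import synthetic_data as sd
from vernalnc.annotation_io import AnnotationSet, GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def dataset() -> sd.SyntheticDataset:
    """The default synthetic dataset (fixed seed)."""
    return sd.generate()


@pytest.fixture(scope="session")
def sim_files(dataset, tmp_path_factory):
    return sd.write_dataset(dataset, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def classified(dataset, sim_files):
    coding = cl.load_coding_evidence(sim_files["hits_tsv"])
    return cl.classify_transcripts(dataset.assembled, dataset.reference, coding)


@pytest.fixture(scope="session")
def de_table(dataset):
    return ed.differential_expression(dataset.expression)


@pytest.fixture
def tiny_reference() -> AnnotationSet:
    """Two genes: GA (+, two exons 100-200/300-400) and GB (-, one exon)."""
    ga = TranscriptModel(
        "GA.t1",
        (
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
        ),
        "GA",
    )
    gb = TranscriptModel("GB.t1", (GenomicInterval("chr1", 10000, 10500, "-"),), "GB")
    return AnnotationSet.from_transcripts([ga, gb])
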