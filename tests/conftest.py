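import pytest

from rdprep.fastq import ReadRecord


def make_read(seq, scores=None, rid="r", qual=None):
    """ReadRecord helper; scores default to Phred 40 everywhere, qual is
    written on the Phred+33 scale unless given."""
    if scores is None:
        scores = [40] * len(seq)
    if qual is None:
        qual = "".join(chr(s + 33) for s in scores)
    return ReadRecord(rid, seq, qual, tuple(scores))


@pytest.fixture
def read_factory():
    return make_read
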