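import pytest

from codondegen import CodonAlignment, SequenceRecord, build_map, get_code


@pytest.fixture(scope="session")
def standard_code():
    return get_code(1)


@pytest.fixture(scope="session")
def principled_map_1(standard_code):
    return build_map(standard_code, "principled")


@pytest.fixture(scope="session")
def third_only_map_1(standard_code):
    return build_map(standard_code, "third_only")


@pytest.fixture
def make_alignment():
    def _make(*id_seq_pairs):
        return CodonAlignment(
            tuple(SequenceRecord(id=i, seq=s) for i, s in id_seq_pairs)
        )

    return _make
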