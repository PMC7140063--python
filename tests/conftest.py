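import pytest

from fishdose.regimens import builtin_regimens
from fishdose.safety import load_reference_table, reference_summaries


@pytest.fixture(scope="session")
def regimens():
    return builtin_regimens()


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def ref_summaries():
    return reference_summaries()
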