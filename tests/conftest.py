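import pytest

from adlcoach.simulate import builtin_routines, default_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


@pytest.fixture(scope="session")
def routines():
    return builtin_routines()
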