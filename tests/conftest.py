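import pytest

from bamtool import chem, fixtures


@pytest.fixture(scope="session")
def benchmark10():
    return fixtures.make_benchmark(10, seed=1)


@pytest.fixture(scope="session")
def benchmark10_table(benchmark10):
    return benchmark10.rule_table()


@pytest.fixture(scope="session")
def catalogue():
    return fixtures.scaffold_catalogue()


@pytest.fixture(scope="session")
def ethanol():
    return chem.canonicalize("CCO")


@pytest.fixture(scope="session")
def cyclohexanol():
    return chem.canonicalize("OC1CCCCC1")


@pytest.fixture(scope="session")
def cyclohexanone():
    return chem.canonicalize("O=C1CCCCC1")
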