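import numpy as np
import pytest

import pafkit as pk


@pytest.fixture
def table2():
    """The 10-person smoking / hearing-loss demonstration population."""
    return pk.table2_fixture()


@pytest.fixture
def table2_specs():
    return pk.worked_example_specs()


@pytest.fixture
def table2_csv(tmp_path, table2):
    path = tmp_path / "exposures.csv"
    lines = [",".join(table2.factor_names)]
    lines += [",".join(map(str, row)) for row in table2.values]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def spec_csv(tmp_path):
    path = tmp_path / "specs.csv"
    path.write_text(
        "name,rr,rr_low,rr_high,prevalence\n"
        "smoking,1.6,1.2,2.1,0.2\n"
        "hearing_loss,1.9,1.4,2.6,0.5\n"
    )
    return path


def random_exposure_matrix(rng, n=None, k=None):
    """A small random exposure matrix with no all-equal guarantee."""
    n = n or int(rng.integers(2, 40))
    k = k or int(rng.integers(1, 6))
    values = rng.integers(0, 2, size=(n, k))
    return pk.ExposureMatrix(values, tuple(f"f{j}" for j in range(k)))


def random_specs(rng, names):
    return [
        pk.RiskFactorSpec(name, rr=float(1.0 + rng.uniform(0.01, 3.0)))
        for name in names
    ]
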