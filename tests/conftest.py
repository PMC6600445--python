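import numpy as np
import pytest

import sedrisk as sr


@pytest.fixture(scope="session")
def reference():
    return sr.default_reference()


@pytest.fixture(scope="session")
def reference_map(reference):
    return sr.reference_by_element(reference)


@pytest.fixture(scope="session")
def default_study():
    """The default 32-site synthetic study, fixed seed."""
    return sr.generate_study(sr.SynthConfig(), seed=20260921 % 2**31)


@pytest.fixture()
def totals_csv(tmp_path):
    """Write a small well-formed totals CSV and return its path."""

    def _write(rows, name="totals.csv"):
        path = tmp_path / name
        lines = ["sample_id,river,site,element,concentration"]
        lines += [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture()
def fractions_csv(tmp_path):
    def _write(rows, name="fractions.csv"):
        path = tmp_path / name
        lines = ["sample_id,element,fraction,concentration"]
        lines += [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
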