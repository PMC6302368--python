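import numpy as np
import pytest

from mdsn import ExpressionMatrix, GroupDesign, simulate_cohort


@pytest.fixture
def tiny_expression(tmp_path):
    """3-feature x 4-sample TSV fixture on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "feature\ts1\ts2\ts3\ts4\n"
        "f1\t1.5\t2.25\t3\t4\n"
        "f2\t0\t1\t2\t3\n"
        "f3\t5\t5\t5\t5\n"
    )
    return path


@pytest.fixture
def small_matrices():
    rng = np.random.default_rng(7)
    mirna = ExpressionMatrix(
        ["m1", "m2"], ["s1", "s2", "s3"], rng.standard_normal((2, 3)), processed=True
    )
    mrna = ExpressionMatrix(
        ["g1", "g2"], ["s2", "s3", "s4"], rng.standard_normal((2, 3)), processed=True
    )
    design = GroupDesign(
        ["s1", "s2", "s3", "s4"],
        subtype_of={"s1": "a", "s2": "a", "s3": "b", "s4": "b"},
    )
    return mirna, mrna, design


@pytest.fixture(scope="session")
def planted_cohort():
    """Default 4-module cohort (rho=-0.8 in alpha, 0 in beta, n=60 each)."""
    return simulate_cohort(n_mirna=40, n_mrna=100, seed=11)
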