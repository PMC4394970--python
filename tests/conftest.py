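import numpy as np
import pandas as pd
import pytest

from renalmark import ExpressionMatrix, MirnaFamily

LET7_MATURE = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def let7() -> MirnaFamily:
    return MirnaFamily(name="let-7", mature=LET7_MATURE)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "n1": [1.0, 5.0, 2.0],
            "n2": [2.0, 6.0, 2.0],
            "t1": [8.0, 5.5, 2.0],
            "t2": [9.0, 6.5, 2.0],
        },
        index=["gA", "gB", "gC"],
    )
    groups = pd.Series(
        ["normal", "normal", "T1", "T1"], index=["n1", "n2", "t1", "t2"], name="group"
    )
    return ExpressionMatrix(values=values, groups=groups)


def random_families(n: int, seed: int, length: int = 22) -> list[MirnaFamily]:
    rng = np.random.default_rng(seed)
    return [
        MirnaFamily(name=f"fam{i:02d}", mature="".join(rng.choice(list("ACGU"), size=length)))
        for i in range(n)
    ]
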