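import numpy as np
import pandas as pd
import pytest

from plasmir.io import CtMatrix, RelativeExpressionMatrix, SampleTable


@pytest.fixture
def tiny_ct() -> CtMatrix:
    """3 assays x 4 samples, one undetected well, two cards."""
    values = pd.DataFrame(
        [[25.0, 26.0, 25.5, 24.5],
         [30.0, 31.0, 29.0, 42.0],
         [20.0, 20.1, 19.9, 20.0]],
        index=["mir-x", "mir-y", "mir-ref"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CtMatrix(
        values=values,
        card=pd.Series(["A", "B", "A"], index=values.index),
        is_internal_control=pd.Series(
            [False, False, True], index=values.index
        ),
    )


def make_samples(groups: dict[str, int], cohort: str = "discovery",
                 prefix: str = "s", **extra) -> SampleTable:
    rows = []
    i = 0
    for g, n in groups.items():
        for _ in range(n):
            i += 1
            rows.append({"sample_id": f"{prefix}{i}", "cohort": cohort,
                         "group": g, **{k: v for k, v in extra.items()}})
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def five_group_samples() -> SampleTable:
    return make_samples({"control": 4, "I": 4, "II": 4, "III": 4, "IV": 4})


def random_expression(
    rng: np.random.Generator, n_assays: int, sample_ids: list[str]
) -> RelativeExpressionMatrix:
    values = pd.DataFrame(
        rng.normal(0, 1, (n_assays, len(sample_ids))),
        index=[f"a{i}" for i in range(n_assays)],
        columns=sample_ids,
    )
    return RelativeExpressionMatrix(values, reference_assay="ref",
                                    baseline_group="control")
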