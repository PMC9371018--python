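import numpy as np
import pytest

from catimpute.data import Attribute, CategoricalSchema, DiscreteTable


@pytest.fixture
def lymph_schema() -> CategoricalSchema:
    """A small schema with a four-category attribute, UCI-style."""
    return CategoricalSchema(
        [
            Attribute(name="lymphatics", domain=("normal", "arched", "deformed", "displaced")),
            Attribute(name="block", domain=("no", "yes")),
            Attribute(name="class", domain=("metastases", "malign"), role="class"),
        ]
    )


@pytest.fixture
def lymph_table(lymph_schema) -> DiscreteTable:
    cols = [
        np.array([0, 1, 2, 3, 0, -1], dtype=np.int32),
        np.array([0, 1, -1, 1, 0, 1], dtype=np.int32),
        np.array([0, 0, 1, 1, 0, 1], dtype=np.int32),
    ]
    return DiscreteTable(lymph_schema, cols)
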