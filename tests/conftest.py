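import numpy as np
import pytest

from gliameta import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 2 samples, linear scale, with the target gene present."""
    return ExpressionDataset(
        dataset_id="T1",
        gene_symbols=["Oprm1", "P2ry12", "Gapdh"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 3.0], [7.0, 15.0], [0.0, 1.0]]),
        platform="rnaseq", species="mouse", tissue="cortex", group="cortex",
    )


def make_dataset(values, symbols=None, dataset_id="D", **kw) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    symbols = symbols or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_symbols=list(symbols),
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        **kw,
    )
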