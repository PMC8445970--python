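import numpy as np
import pytest

from qsarselect.descriptor_io import DescriptorTable, LabeledDataset


def make_table(values, ids=None, names=None) -> DescriptorTable:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return DescriptorTable(
        molecule_ids=ids or [f"M{i + 1}" for i in range(n)],
        feature_names=names or [f"f{j + 1}" for j in range(p)],
        values=values,
    )


def make_dataset(values, y, positive="pos", negative="neg", **kw) -> LabeledDataset:
    table = make_table(values, **kw)
    return LabeledDataset(
        table=table,
        labels=[positive if v else negative for v in y],
        positive_class_name=positive,
        negative_class_name=negative,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def separable_dataset(rng):
    """30 molecules, 4 features; f2 separates the classes perfectly."""
    n = 30
    y = np.array([1] * 10 + [0] * 20)
    X = rng.standard_normal((n, 4))
    X[:, 1] = np.where(y == 1, 1.0, -1.0) * (0.5 + rng.random(n))
    return make_dataset(X, y)
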