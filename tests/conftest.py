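import numpy as np
import pandas as pd
import pytest

from ldwcnn.clinical_io import CONTINUOUS, ClinicalTable, FeatureMeta


def table_from_arrays(X, y, n_classes=None, dataset_id="toy") -> ClinicalTable:
    """All-continuous ClinicalTable from a feature matrix and integer labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_classes = n_classes or int(y.max()) + 1
    meta = tuple(FeatureMeta(f"f{j}", CONTINUOUS) for j in range(X.shape[1]))
    data = pd.DataFrame({m.name: X[:, j] for j, m in enumerate(meta)})
    return ClinicalTable(data, meta, y, tuple(str(k) for k in range(n_classes)),
                         dataset_id)


@pytest.fixture
def random_table():
    def make(n=30, d=4, n_classes=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = rng.integers(0, n_classes, size=n)
        # guarantee every class occupied
        y[:n_classes] = np.arange(n_classes)
        return table_from_arrays(X, y, n_classes)

    return make


@pytest.fixture
def liver_table():
    from ldwcnn.synthdata import generate, make_schema_preset

    return generate(make_schema_preset("liver"), 120, effect_size=2.0,
                    missing_rate=0.05, seed=7)
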