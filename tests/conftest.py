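import numpy as np
import pytest

from fasf_tle.synth import PhantomSpec, make_phantom, make_slice_dataset

#: width-reduced network configuration used throughout the tests; the
#: published widths (64 filters, 128 LSTM units, 2048 FFN) are preserved
#: as estimator defaults
DESK_HAETN = dict(
    conv_filters=8,
    lstm_hidden=8,
    attn_heads=2,
    ffn_hidden=32,
    dense_units=16,
    epochs=15,
    batch_size=8,
    learning_rate=0.1,
    max_grad_norm=0.3,
)


@pytest.fixture(scope="session")
def blob_data():
    """40 slice sequences: class 1 carries a bright blob in quadrant (0, 0)."""
    X, y, quadrant = make_slice_dataset(n_per_class=20, blob_contrast=0.8, seed=7)
    return X, y, quadrant


@pytest.fixture(scope="session")
def trained_blob_model(blob_data):
    from fasf_tle.haetn import HAETNClassifier

    X, y, _ = blob_data
    return HAETNClassifier(**DESK_HAETN, random_state=0).fit(X, y)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(shape=(48, 48, 24), gaussian_sd=0.01, seed=3)
    return make_phantom(spec), spec


def quadrant_sums(heat2d: np.ndarray) -> list[float]:
    h, w = heat2d.shape
    return [
        float(heat2d[: h // 2, : w // 2].sum()),
        float(heat2d[: h // 2, w // 2 :].sum()),
        float(heat2d[h // 2 :, : w // 2].sum()),
        float(heat2d[h // 2 :, w // 2 :].sum()),
    ]
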