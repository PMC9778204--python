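import numpy as np
import pytest

from mfecg import SegmentFeaturizer, denoise, synthetic_ecg


@pytest.fixture(scope="session")
def ecg_cohort():
    """60 NSR-like + 60 CHF-like denoised 64-s segments and their features.

    Shared across tests: generation and featurization dominate runtime.
    """
    segs, labels = [], []
    for i in range(60):
        nsr = synthetic_ecg("ecg_nsr_like", fs=128, duration=64, seed=1000 + i)
        chf = synthetic_ecg("ecg_chf_like", fs=128, duration=64, seed=2000 + i)
        segs.append(denoise(nsr.values))
        labels.append("NSR")
        segs.append(denoise(chf.values))
        labels.append("CHF")
    labels = np.array(labels)
    with np.errstate(all="ignore"):
        X = SegmentFeaturizer().transform(segs)
    return segs, X, labels
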