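import numpy as np
import pytest

from botnet import SyntheticConfig, generate_corpus
from botnet.length_policy import LengthPolicy, Strategy
from botnet.train_eval import PipelineConfig


@pytest.fixture(scope="session")
def small_corpus():
    """200-pair start-motif corpus with short lncRNAs; fast to tokenize/train."""
    cfg = SyntheticConfig(n_pos=100, n_neg=100, lnc_len_range=(60, 200), seed=7)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_pipe():
    return PipelineConfig(
        lnc_policy=LengthPolicy(Strategy.START, X=20),
        partner_policy=LengthPolicy(Strategy.MAX_PAD),
        lnc_k=5,
        stride=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
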