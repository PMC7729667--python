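import numpy as np
import pytest

from promotif.background import BackgroundModel
from promotif.io_formats import SequenceSet
from promotif.promoters import PromoterRecord, PromoterUniverse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_bg():
    return BackgroundModel(
        order=0, transition={}, stationary=np.full(4, 0.25), pseudocount=1.0
    )


@pytest.fixture
def at_rich_bg():
    return BackgroundModel(
        order=0,
        transition={},
        stationary=np.array([0.31, 0.19, 0.19, 0.31]),
        pseudocount=1.0,
    )


def make_universe(seqs: dict[str, str]) -> PromoterUniverse:
    """Wrap raw promoter strings as a universe (forward strand, own contig)."""
    return PromoterUniverse(
        [
            PromoterRecord(tid, tid, tid, (0, len(s)), "+", s)
            for tid, s in seqs.items()
        ],
        [],
    )


@pytest.fixture
def random_pwm_factory(rng):
    from promotif.pwm import PWM

    def make(width: int, concentration: float = 1.0) -> PWM:
        mat = rng.dirichlet(np.full(4, concentration), size=width)
        return PWM(mat)

    return make
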