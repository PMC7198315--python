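import numpy as np
import pytest

from protcat.data_model import Category, ProteinFeatureSet

# the heme-sensor abstract used as the preprocessing pipeline's worked example
ABSTRACT = (
    "YddV from Escherichia coli (Ec) is a novel globin-coupled heme-based "
    "oxygen sensor protein displaying diguanylate cyclase activity in "
    "response to oxygen availability. In this study, we quantified the "
    "turnover numbers of the active [Fe(III), 0.066 min(-1); Fe(II)-O(2) "
    "and Fe(II)-CO, 0.022 min(-1)] [Fe(III), Fe(III)-protoporphyrin IX "
    "complex; Fe(II), Fe(II)-protoporphyrin IX complex] and inactive forms "
    "[Fe(II) and Fe(II)-NO, <0.01 min(-1)] of YddV for the first time."
)

EXPECTED_SENTENCE_1 = (
    "yddv escherichia coli ec novel globin coupl heme base oxygen sensor "
    "protein display diguanyl cyclas activ respons oxygen avail"
).split()

EXPECTED_SENTENCE_2 = (
    "studi quantifi turnov number activ fe iii _NUMBER_ min fe ii fe ii co "
    "_NUMBER_ min fe iii fe iii protoporphyrin ix complex fe ii fe ii "
    "protoporphyrin ix complex inact form fe ii fe ii _NUMBER_ min yddv "
    "first time"
).split()


@pytest.fixture
def abstract_text():
    return ABSTRACT


@pytest.fixture
def securin_features():
    """The securin (pituitary tumor-transforming gene 1 protein) entry."""
    return ProteinFeatureSet(
        accession="O95997",
        entry_name="PTTG1_HUMAN",
        names=[
            "Securin",
            "Esp1-associated protein",
            "Pituitary tumor-transforming gene 1 protein",
            "Tumor-transforming protein 1",
            "hPTTG",
        ],
        genes=["PTTG1", "EAP1", "PTTG", "TUTR1"],
    )


SECURIN_STRINGS = [
    "PTTG1_HUMAN",
    "Securin",
    "Esp1-associated protein",
    "Pituitary tumor-transforming gene 1 protein",
    "Tumor-transforming protein 1",
    "hPTTG",
    "PTTG1",
    "EAP1",
    "PTTG",
    "TUTR1",
]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_label_set(rng, max_size=3):
    n = int(rng.integers(1, max_size + 1))
    return frozenset(Category(int(i)) for i in rng.choice(11, size=n, replace=False))
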