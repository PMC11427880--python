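import numpy as np
import pandas as pd
import pytest

from questqual.examples import Q1, Q2
from questqual.textlex import default_lexicon_set


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicon_set()


@pytest.fixture(scope="session")
def q1_text():
    return Q1


@pytest.fixture(scope="session")
def q2_text():
    return Q2


@pytest.fixture()
def small_corpus():
    """Six hand-written question records covering both platforms."""
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(6)],
            "platform": ["webmd", "webmd", "webmd", "yahoo", "yahoo", "yahoo"],
            "title": [
                "What causes kidney stones?",
                "How long is dialysis?",
                "Worried about my blood test.",
                "Why do my legs swell at night?",
                "Kidney failure stage 3",
                "Need advice on treatment options",
            ],
            "body": [
                "My doctor found a stone on the scan. What should I do now?",
                "My father starts dialysis next week. How long does each session take?",
                "The lab results show high creatinine and I am scared.",
                "I am 55 with high blood pressure. When should I see a doctor?",
                "I was diagnosed last year. The condition stems from diabetes.",
                "My husband has chronic kidney disease and we hope for a transplant.",
            ],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
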