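import numpy as np
import pytest

from mafi.norming import default_lexicon
from mafi.phonfeatures import default_feature_table, tokenize_ipa
from mafi.saliency import default_viseme_inventory


@pytest.fixture(scope="session")
def table():
    return default_feature_table()


@pytest.fixture(scope="session")
def inv():
    return default_viseme_inventory()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def tok(table):
    def _tok(ipa):
        return tokenize_ipa(ipa, table)

    return _tok


@pytest.fixture(scope="session")
def bat(tok):
    return tok("bæt")


@pytest.fixture(scope="session")
def pat(tok):
    return tok("pæt")


@pytest.fixture(scope="session")
def cat(tok):
    return tok("kæt")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_transcriptions(table):
    """A pool of random segment sequences (length 0-6) over the full table."""
    rng = np.random.default_rng(7)
    symbols = sorted(table.segments)
    pool = []
    for _ in range(60):
        n = int(rng.integers(0, 7))
        segs = tuple(table.segments[symbols[i]] for i in rng.integers(len(symbols), size=n))
        from mafi.phonfeatures import Transcription

        pool.append(Transcription(word="", segments=segs))
    return pool
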