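import numpy as np
import pytest

from prmkit.chem import LabeledPeptide


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def nontryptic_peptide():
    """The nontryptic SIL peptide used throughout the worked examples."""
    return LabeledPeptide.parse("DLQPETTDL[+7]Y")
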