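import numpy as np
import pytest

from promevol.events import PromoterAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_alignment():
    """Tiny hand-checkable alignment: 1 substitution, 1 deletion, 1 insertion.

    Reference spans offsets -5..+5 (TSS at column 7 => ref base index 5).
    other1: substitution at offset -3; 2-base deletion at offsets 0,+1;
            2-base insertion anchored at offset -1 (columns 5-6).
    other2: identical to the reference.
    """
    rows = {
        "ref":    "ACGTA--CGTACG",
        "other1": "ACTTAGG--TACG",
        "other2": "ACGTA--CGTACG",
    }
    return PromoterAlignment(gene="toy", ref_species="ref", rows=rows, tss_column=7)
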