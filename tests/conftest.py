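import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def reference_window():
    """A 300 bp random reference exon window (fixed seed)."""
    r = np.random.default_rng(12345)
    return "".join(r.choice(list("ACGT"), 300))


@pytest.fixture(scope="session")
def small_panel():
    from panelvar.panel import default_panel

    return default_panel(n_filler_genes=2, exons_per_gene=5)
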