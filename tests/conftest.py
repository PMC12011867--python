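from pathlib import Path

import pandas as pd
import pytest

from pvsignal.cohort import MeddraMap

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def meddra() -> MeddraMap:
    return MeddraMap.bundled()


@pytest.fixture(scope="session")
def reference_rows() -> pd.DataFrame:
    """Published disproportionality statistics for the 30 most frequent
    pembrolizumab/cervical-cancer adverse-event signals (reference values
    used for self-consistency and reconstruction checks)."""
    return pd.read_csv(DATA_DIR / "reference_signal_rows.tsv", sep="\t")
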