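import numpy as np
import pytest

from phagoquant.plate_model import AnalysisParams


@pytest.fixture
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160915)


@pytest.fixture
def layout_csv(tmp_path):
    """Minimal valid 3-well layout file."""
    path = tmp_path / "layout.csv"
    path.write_text(
        "well,treatment,concentration,unit,role,cells,meal\n"
        "B07,vehicle,0,ug/ml,vehicle,50000,E. coli\n"
        "B08,cytochalasin,10,uM,treated,50000,E. coli\n"
        "B09,cytochalasin,2,uM,treated,50000,E. coli\n"
    )
    return path
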