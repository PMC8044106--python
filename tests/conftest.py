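import numpy as np
import pandas as pd
import pytest

from sporetrace.barcode_io import SampleSheet
from sporetrace.synth import (
    AmpliconDesign,
    BarcodeLibrary,
    build_strain_panel,
    default_samplesheet_frame,
)


@pytest.fixture(scope="session")
def panel79():
    return build_strain_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_library():
    # fixed, mutually distant 12-mers mapped to three strains
    return BarcodeLibrary(
        {
            "AAAACCCCGGGG": "WT",
            "TTTTGGGGAAAA": "A",
            "CCCCAAAATTTT": "B",
        }
    )


@pytest.fixture
def design():
    return AmpliconDesign()


@pytest.fixture
def sheet24():
    return SampleSheet(default_samplesheet_frame())


def make_sheet(rows):
    return SampleSheet(pd.DataFrame(rows))
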