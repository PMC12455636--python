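import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sortscreen import fixtures, parts


@pytest.fixture(scope="session")
def registry():
    return fixtures.make_registry()


@pytest.fixture(scope="session")
def barcodes():
    return fixtures.make_barcodes()


@pytest.fixture(scope="session")
def elp2_designs(registry):
    return parts.enumerate_design_space(
        registry.by_role("promoter"),
        registry.by_role("sp_flag"),
        registry["ELP2"],
        registry["CBM"],
        registry["cassette_display"],
    )


@pytest.fixture(scope="session")
def slot_parts(registry):
    """One representative part per grammar slot, in order."""
    return [
        registry["pYTK010"],
        registry["MF"],
        registry["ELP2"],
        registry["CBM"],
        registry["cassette_display"],
    ]
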