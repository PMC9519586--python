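import logging

import pytest

from dsdscreen.panel import load_panel
from dsdscreen.simulate import LabelMixture

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def enriched_mixture():
    """Pathogenic-rich label mixture for tier-recovery tests (the realistic
    default mixture yields almost no P/LP at reduced variant counts)."""
    return LabelMixture(
        intervar={"P": 0.05, "LP": 0.05, "VUS": 0.7, "LB": 0.05, "B": 0.15},
        clinvar={
            "P": 0.1,
            "LP": 0.05,
            "VUS": 0.1,
            "LB": 0.02,
            "B": 0.03,
            "conflicting": 0.05,
            "absent": 0.65,
        },
        hgmd={"DM": 0.1, "other": 0.05, "absent": 0.85},
    )
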