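import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from boolmerge import LogicalModel


@pytest.fixture
def mutual_activation() -> LogicalModel:
    """Two-node mutual activation: A <-> B (positive feedback)."""
    return LogicalModel.from_rules({"A": "B", "B": "A"}, model_id="mutual")


@pytest.fixture
def negative_loop() -> LogicalModel:
    """Two-node negative feedback loop: A = !B, B = A."""
    return LogicalModel.from_rules({"A": "!B", "B": "A"}, model_id="negloop")


@pytest.fixture
def toy_regulon() -> LogicalModel:
    """Four-node toy: an input driving a small cascade with repression."""
    return LogicalModel.from_rules(
        {"IN": None, "X": "IN", "Y": "X & !Z", "Z": "Y | Z"},
        model_id="toy",
    )
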