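import numpy as np
import pytest

from salmoquant import datasets
from salmoquant.calibration import CalibrationPoint


@pytest.fixture(scope="session")
def assays():
    return {a.species_label: a for a in datasets.load_assays()}


@pytest.fixture(scope="session")
def templates():
    return {rec.id: rec for rec in datasets.synthetic_templates()}


@pytest.fixture(scope="session")
def published_calibration_points():
    """Calibration points from the bundled replicate-mean concentrations."""
    tab = datasets.calibration_table()
    return [
        CalibrationPoint(
            trout_mass_fraction_pct=row.trout_mass_fraction_pct,
            q_o=row.q_o_mean_copies_per_ul,
            q_s=row.q_s_mean_copies_per_ul,
        )
        for row in tab.itertuples()
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20231129)
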