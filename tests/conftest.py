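"""Shared fixtures: the packaged worked example and its frozen expected
intermediate results (Boolean matrices, per-condition Shapley tables,
ADSV columns, reference resampling p-values)."""

import numpy as np
import pytest

from microgame import table1_fixture


def _parse(text: str) -> np.ndarray:
    return np.array(
        [[float(v) for v in line.split()] for line in text.strip().splitlines()]
    )


GENES = tuple(f"gene{i}" for i in range(1, 10))
CONTROL_SAMPLES = tuple(f"C{i}" for i in range(1, 6))
EXPERIMENTAL_SAMPLES = tuple(f"E{i}" for i in range(1, 6))

# over-expression indicator of the worked example (all 10 samples)
BOOL_OVER = _parse("""
0 0 0 0 0 0 1 0 0 1
0 0 0 0 0 0 0 0 0 0
0 0 0 1 0 0 0 0 0 0
0 0 0 1 0 0 0 0 0 0
0 0 0 1 0 0 0 0 0 1
0 0 0 0 1 0 0 0 0 1
1 0 0 0 0 0 0 0 0 0
0 0 0 1 0 0 0 0 0 0
0 0 0 0 1 0 0 0 0 0
""")

# under-expression indicator of the worked example
BOOL_UNDER = _parse("""
1 0 0 0 0 1 0 0 1 0
0 0 0 0 1 0 0 1 0 0
0 1 0 0 0 0 1 0 1 0
1 0 0 0 0 0 0 0 0 0
0 0 0 0 0 1 0 0 1 0
0 0 0 0 0 1 0 0 1 0
0 0 0 0 0 0 0 1 1 1
0 0 0 0 0 1 1 0 1 0
1 0 0 0 0 0 0 0 0 0
""")

# per-sample marginal contributions (Sh columns) and mean Shapley value
# of the four condition-restricted games, at the displayed 3 decimals
SH_EXPERIMENTAL_OVER = _parse("""
0 1 0 0 0.333
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0.333
0 0 0 0 0.333
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0
""")
MEANSH_EXPERIMENTAL_OVER = np.array([0.267, 0, 0, 0, 0.067, 0.067, 0, 0, 0])

SH_EXPERIMENTAL_UNDER = _parse("""
0.25 0 0 0.167 0
0 0 0.5 0 0
0 0.5 0 0.167 0
0 0 0 0 0
0.25 0 0 0.167 0
0.25 0 0 0.167 0
0 0 0.5 0.167 1
0.25 0.5 0 0.167 0
0 0 0 0 0
""")
MEANSH_EXPERIMENTAL_UNDER = np.array(
    [0.083, 0.1, 0.133, 0, 0.083, 0.083, 0.333, 0.183, 0]
)

SH_CONTROL_OVER = _parse("""
0 0 0 0 0
0 0 0 0 0
0 0 0 0.25 0
0 0 0 0.25 0
0 0 0 0.25 0
0 0 0 0 0.5
1 0 0 0 0
0 0 0 0.25 0
0 0 0 0 0.5
""")
MEANSH_CONTROL_OVER = np.array([0, 0, 0.05, 0.05, 0.05, 0.1, 0.2, 0.05, 0.1])

SH_CONTROL_UNDER = _parse("""
0.333 0 0 0 0
0 0 0 0 1
0 1 0 0 0
0.333 0 0 0 0
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0
0.333 0 0 0 0
""")
MEANSH_CONTROL_UNDER = np.array([0.067, 0.2, 0.2, 0.067, 0, 0, 0, 0, 0.067])

# reference ADSV columns and selection thresholds
ADSV_OVER = np.array([0.267, 0, 0.05, 0.05, 0.017, 0.033, 0.2, 0.05, 0.1])
ADSV_UNDER = np.array([0.017, 0.1, 0.067, 0.067, 0.083, 0.083, 0.333, 0.183, 0.067])
THRESHOLD_OVER = 0.130
THRESHOLD_UNDER = 0.181

# reference CASh p-values (uncorrected, B = 1000)
REFERENCE_P_OVER = np.array([0.1, 1, 0.34, 0.34, 0.7, 0.84, 0.37, 0.34, 0.22])
REFERENCE_P_UNDER = np.array([0.78, 0.55, 0.67, 0.41, 0.04, 0.04, 0.04, 0.02, 0.41])


@pytest.fixture(scope="session")
def table1():
    """(ExpressionMatrix, GroupLabels) of the packaged worked example."""
    return table1_fixture()


@pytest.fixture(scope="session")
def expected_shapley():
    """(Sh matrix, meanSh) per (group, direction), at 3 displayed decimals."""
    return {
        ("experimental", "over"): (SH_EXPERIMENTAL_OVER, MEANSH_EXPERIMENTAL_OVER),
        ("experimental", "under"): (SH_EXPERIMENTAL_UNDER, MEANSH_EXPERIMENTAL_UNDER),
        ("control", "over"): (SH_CONTROL_OVER, MEANSH_CONTROL_OVER),
        ("control", "under"): (SH_CONTROL_UNDER, MEANSH_CONTROL_UNDER),
    }
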