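import numpy as np
import pandas as pd
import pytest

import weightstates as ws
from weightstates import reference


@pytest.fixture(scope="session")
def q_all():
    """Reference all-children intensity matrix (1/year)."""
    return reference.REFERENCE_INTENSITIES["all"]


@pytest.fixture(scope="session")
def q_girls():
    return reference.REFERENCE_INTENSITIES["girls"]


@pytest.fixture(scope="session")
def q_boys():
    return reference.REFERENCE_INTENSITIES["boys"]


@pytest.fixture(scope="session")
def fixture_cutoffs():
    """Tiny custom cutoff table: (c_ow, c_ob) = (17, 19) at ages [5, 12)."""
    return ws.CutoffTable(
        pd.DataFrame(
            [
                {"sex": s, "age_lo": 5.0, "age_hi": 12.0, "c_ow": 17.0, "c_ob": 19.0}
                for s in ("girl", "boy")
            ]
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-child simulated cohort with its generating truth."""
    cfg = ws.SimulationConfig(n_children=300, seed=11)
    return ws.generate_cohort(cfg)


@pytest.fixture(scope="session")
def full_cohort():
    """A full-size cohort at the emulated study scale (2,334 x 6 waves)."""
    cfg = ws.SimulationConfig(seed=20)
    return ws.generate_cohort(cfg)


def panel_frame(children: dict[str, list[tuple[float, int]]]) -> pd.DataFrame:
    """Minimal state panel for likelihood tests: child -> [(t, state), ...]."""
    rows = []
    for cid, obs in children.items():
        for t, s in obs:
            rows.append({"child_id": cid, "t": float(t), "state": int(s)})
    return pd.DataFrame(rows)
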