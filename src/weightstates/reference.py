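"""Bundled reference inputs for the three-state weight-status model.

These are the package's reference transition-intensity matrices for a
school-age cohort followed annually from about age 6.8 years, on the state
space (1 = normal weight, 2 = overweight, 3 = obese) with instantaneous
transitions allowed only between adjacent states.  They serve as the
simulator's default generating truth and as the worked-example input for
``weightstates reproduce-tables``.

Units: intensities are per year; the baseline state distribution is a
proportion vector over (normal, overweight, obese).
"""

from __future__ import annotations

import numpy as np

STATE_NAMES = ("normal", "overweight", "obese")

N_CHILDREN = 2334
N_WAVES = 6


def tridiagonal_q(q12: float, q21: float, q23: float, q32: float) -> np.ndarray:
    """Assemble a valid 3x3 intensity matrix from the four adjacent rates.

    Direct 1<->3 jumps are structurally impossible; diagonals are the
    negative row sums, so rows sum to zero.
    """
    return np.array(
        [
            [-q12, q12, 0.0],
            [q21, -(q21 + q23), q23],
            [0.0, q32, -q32],
        ]
    )


#: Reference intensity matrices (1/year) by stratum.
REFERENCE_INTENSITIES: dict[str, np.ndarray] = {
    "all": tridiagonal_q(0.086, 0.341, 0.257, 0.209),
    "girls": tridiagonal_q(0.066, 0.379, 0.295, 0.290),
    "boys": tridiagonal_q(0.111, 0.317, 0.235, 0.172),
}

#: Baseline weight-status distribution (normal, overweight, obese) by stratum.
BASELINE_STATE_DISTRIBUTION: dict[str, np.ndarray] = {
    "all": np.array([0.711, 0.181, 0.108]),
    "girls": np.array([0.791, 0.151, 0.058]),
    # the rounded boys' proportions sum to 0.999; renormalize to a distribution
    "boys": np.array([0.631, 0.210, 0.158]) / 0.999,
}

#: Observed 5-year prevalence of overweight among boys, with its 95% CI (%),
#: used by the worked example of the projection-validation rule.
OBSERVED_BOYS_OVERWEIGHT_5Y = {"observed": 21.2, "ci": (18.9, 23.5)}
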