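"""Bliss-independence synergy analysis of dose–response matrices.

Under Bliss independence two drugs kill independently, so the expected
combined effect is E_xy = E_x + E_y - E_x*E_y.  Positive deviation of the
observed effect from this expectation indicates synergy, negative deviation
antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CLAMP_TOL = 1e-6


def bliss_expected(ex: float, ey: float) -> float:
    """Expected combined effect of two independently acting drugs.

    Effects are fractions of the maximum effect in [0, 1]; inputs within a
    1e-6 tolerance of the interval are clamped, anything further out is an
    error.
    """
    ex = _validate_effect(ex, "ex")
    ey = _validate_effect(ey, "ey")
    return ex + ey - ex * ey


def _validate_effect(e: float, name: str) -> float:
    e = float(e)
    if not -_CLAMP_TOL <= e <= 1.0 + _CLAMP_TOL:
        raise ValueError(f"effect {name}={e} outside [0, 1]")
    return min(max(e, 0.0), 1.0)


@dataclass
class DoseResponseMatrix:
    """Viability fractions on a dose grid; row/column 0 are the single agents.

    ``viability`` is indexed by the doses of drug x (rows) and drug y
    (columns), both including dose 0, so cell (0, 0) is the untreated well.
    Replicate matrices, if any, are averaged before analysis.
    """

    viability: pd.DataFrame

    def __post_init__(self) -> None:
        dx = np.asarray(self.viability.index, float)
        dy = np.asarray(self.viability.columns, float)
        if dx.size < 2 or dy.size < 2:
            raise ValueError("need at least one nonzero dose of each drug")
        if dx[0] != 0 or dy[0] != 0:
            raise ValueError("first row and column must be the dose-0 single agents")
        if not (np.all(np.diff(dx) > 0) and np.all(np.diff(dy) > 0)):
            raise ValueError("doses must be strictly ascending")

    @property
    def doses_x(self) -> np.ndarray:
        return np.asarray(self.viability.index, float)

    @property
    def doses_y(self) -> np.ndarray:
        return np.asarray(self.viability.columns, float)

    def normalized(self) -> "DoseResponseMatrix":
        """Viability rescaled so the untreated well equals 1."""
        v00 = float(self.viability.iloc[0, 0])
        if v00 <= 0:
            raise ValueError("untreated well has non-positive signal")
        return DoseResponseMatrix(self.viability / v00)


@dataclass
class SynergyMatrix:
    """Deviation from Bliss expectation on the interior (both-drug) cells."""

    deviation: pd.DataFrame
    deviation_raw: pd.DataFrame  # before clamping observed effects to [0, 1]
    summary: dict = field(default_factory=dict)


def synergy_matrix(drm: DoseResponseMatrix) -> SynergyMatrix:
    """Deviation d(i,j) = E_obs(i,j) - E_bliss(E_x(i), E_y(j)) for i,j >= 1.

    Viability is first normalized to the untreated well; observed effects
    are clamped to [0, 1] before the deviation (raw deviations are kept
    alongside).  The summary reports the mean and maximum interior
    deviation.
    """
    norm = drm.normalized()
    effect_raw = 1.0 - norm.viability.to_numpy(float)
    effect = np.clip(effect_raw, 0.0, 1.0)
    ex = effect[1:, 0]
    ey = effect[0, 1:]
    expected = ex[:, None] + ey[None, :] - ex[:, None] * ey[None, :]
    dev = effect[1:, 1:] - expected
    dev_raw = effect_raw[1:, 1:] - expected
    index = norm.viability.index[1:]
    columns = norm.viability.columns[1:]
    deviation = pd.DataFrame(dev, index=index, columns=columns)
    return SynergyMatrix(
        deviation=deviation,
        deviation_raw=pd.DataFrame(dev_raw, index=index, columns=columns),
        summary={
            "mean_deviation": float(dev.mean()),
            "max_deviation": float(dev.max()),
        },
    )
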