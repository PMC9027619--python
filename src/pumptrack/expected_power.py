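"""Speed-to-expected-power characteristic of a centrifugal blood pump.

A healthy centrifugal pump draws a power that is, to good approximation, a
cubic polynomial of the impeller speed.  The characteristic is used in two
places: to normalise power trends across patients running at different set
speeds, and as the absolute reference level for the expected-power detectors
of the tracking algorithm.

The numeric coefficients of any particular device are manufacturer data and
are therefore configuration, not code.  The packaged default is a synthetic
cubic producing roughly 3.5–7.5 W over 2400–3200 rpm, the speed range typical
of clinical operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import SpeedRangeError
from .io import PatientLog


@dataclass(frozen=True)
class ExpectedPowerModel:
    """Polynomial speed → expected-power curve.

    Parameters
    ----------
    coeffs : tuple of float
        Polynomial coefficients ``(c0, c1, c2, c3)`` in ascending order:
        ``P_exp(speed) = c0 + c1·speed + c2·speed² + c3·speed³`` with speed in
        rpm and power in W.
    valid_speed_range : tuple of float
        ``(rpm_min, rpm_max)``; evaluation outside raises
        :class:`~pumptrack.errors.SpeedRangeError`.
    band_width_w : float
        Optional symmetric half-width of an expected-power band around the
        curve (0 = single curve).
    """

    coeffs: tuple[float, float, float, float]
    valid_speed_range: tuple[float, float]
    band_width_w: float = 0.0

    def __post_init__(self):
        lo, hi = self.valid_speed_range
        if not lo < hi:
            raise ValueError("valid_speed_range must be a nonempty interval")
        grid = np.linspace(lo, hi, 256)
        if np.any(np.polynomial.polynomial.polyval(grid, self.coeffs) <= 0):
            raise ValueError("expected power must be positive on the valid range")

    def expected_power(self, speed):
        """Evaluate the curve at ``speed`` (scalar or array), in W."""
        s = np.asarray(speed, dtype=float)
        lo, hi = self.valid_speed_range
        if np.any(s < lo) or np.any(s > hi):
            bad = np.atleast_1d(s)[(np.atleast_1d(s) < lo) | (np.atleast_1d(s) > hi)]
            raise SpeedRangeError(
                f"speed {bad[0]:.0f} rpm outside valid range [{lo:.0f}, {hi:.0f}]"
            )
        val = np.polynomial.polynomial.polyval(s, self.coeffs)
        return float(val) if np.isscalar(speed) else val

    def band(self, speed):
        """Expected-power band ``(low, high)`` at ``speed``."""
        centre = self.expected_power(speed)
        return centre - self.band_width_w, centre + self.band_width_w

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coeffs": list(self.coeffs),
                    "valid_speed_range": list(self.valid_speed_range),
                    "band_width_w": self.band_width_w,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ExpectedPowerModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            coeffs=tuple(obj["coeffs"]),
            valid_speed_range=tuple(obj["valid_speed_range"]),
            band_width_w=float(obj.get("band_width_w", 0.0)),
        )


#: Synthetic default characteristic: 0.5 + 2.0e-10·rpm³ W, valid 2000–3600 rpm.
DEFAULT_MODEL = ExpectedPowerModel(
    coeffs=(0.5, 0.0, 0.0, 2.0e-10),
    valid_speed_range=(2000.0, 3600.0),
)


def expected_power(model: ExpectedPowerModel, speed):
    """Functional alias for :meth:`ExpectedPowerModel.expected_power`."""
    return model.expected_power(speed)


def normalize_power(log: PatientLog, model: ExpectedPowerModel) -> np.ndarray:
    """Dimensionless power series: measured power / expected power at speed.

    A healthy pump hovers around 1.0; thrombus load pushes the ratio up.
    """
    return log.power / model.expected_power(log.speed)
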