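"""The exponential-decay model of retinal-layer thickness after CRAO.

Thickness at ``days`` since occlusion is modelled as

    thickness(days) = plateau + (initial - plateau) * exp(-k * days)

with ``initial`` the day-0 thickness (μm), ``plateau`` the asymptotic
thickness (μm) and ``k`` the per-day decay constant.  ``initial`` may be
below ``plateau`` during fitting (acute-phase swelling shows apparent
thickening); such fits are flagged downstream, not forbidden here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the decay model.

    Attributes
    ----------
    initial : float
        Thickness at day 0, μm.  Must be positive.
    plateau : float
        Asymptotic thickness, μm.  Must be non-negative.
    k : float
        Decay constant, per day.  Must be non-negative; ``k = 0`` is the
        degenerate constant curve.
    """

    initial: float
    plateau: float
    k: float

    def __post_init__(self) -> None:
        if not self.initial > 0:
            raise ValueError(f"initial thickness must be > 0 μm, got {self.initial}")
        if self.plateau < 0:
            raise ValueError(f"plateau must be >= 0 μm, got {self.plateau}")
        if self.k < 0:
            raise ValueError(f"decay constant must be >= 0 /day, got {self.k}")

    def to_dict(self) -> dict[str, float]:
        return {
            "initial_um": self.initial,
            "plateau_um": self.plateau,
            "k_per_day": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "DecayParams":
        return cls(
            initial=float(d["initial_um"]),
            plateau=float(d["plateau_um"]),
            k=float(d["k_per_day"]),
        )


def predict_thickness(params: DecayParams, days):
    """Model thickness at ``days`` since occlusion (scalar or array), μm.

    Raises ``ValueError`` for negative days: extrapolation before onset
    is undefined.
    """
    d = np.asarray(days, dtype=float)
    if np.any(d < 0):
        raise ValueError("days since onset must be >= 0")
    out = params.plateau + (params.initial - params.plateau) * np.exp(-params.k * d)
    if np.isscalar(days) or d.ndim == 0:
        return float(out)
    return out


def percent_change(t0_value: float, t_value: float) -> float:
    """Signed percent change of ``t_value`` relative to baseline ``t0_value``.

    Negative for thinning.  Full precision; rounding to one decimal is a
    presentation concern left to report builders.
    """
    if not t0_value > 0:
        raise ValueError(f"baseline thickness must be > 0 μm, got {t0_value}")
    return 100.0 * (t_value - t0_value) / t0_value
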