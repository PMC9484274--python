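"""Mass-balance calculation of bone mineral content.

During chemical demineralization the dense hydroxyapatite phase
(density ``rho_M``) dissolves and its volume is replaced by buffer
(density ``rho_W``), so the sample's wet weight drops. The weight of
mineral lost follows from the wet-weight change alone::

    V_M,lost = dW_wet / (rho_W - rho_M)
    W_M,lost = rho_M * V_M,lost

with ``dW_wet = w_after - w_before`` (negative, since rho_M > rho_W).
The remaining mineral content is expressed in weight percent of the
intact sample's mineral mass and serves as the class label of the
classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, InvalidArgumentError

__all__ = [
    "DEFAULT_RHO_MINERAL",
    "DEFAULT_RHO_WATER",
    "DemineralizationRecord",
    "mineral_lost",
    "mineral_content_percent",
]

#: Hydroxyapatite density, g/cm^3 (literature value).
DEFAULT_RHO_MINERAL = 3.16
#: Water / buffer density, g/cm^3.
DEFAULT_RHO_WATER = 1.00


@dataclass(frozen=True)
class DemineralizationRecord:
    """One weighing record of a sample before/after decalcifier treatment."""

    w_wet_before: float
    w_wet_after: float
    rho_m: float = DEFAULT_RHO_MINERAL
    rho_w: float = DEFAULT_RHO_WATER
    w_mineral_initial: float = float("nan")

    def __post_init__(self) -> None:
        if self.w_wet_before < 0 or self.w_wet_after < 0:
            raise InvalidArgumentError("wet weights must be >= 0")
        if not (self.rho_m > self.rho_w > 0):
            raise InvalidArgumentError("densities must satisfy rho_m > rho_w > 0")
        if self.w_wet_after > self.w_wet_before:
            raise InvalidArgumentError(
                "wet weight may not increase during demineralization"
            )

    @property
    def delta_w_wet(self) -> float:
        """Wet-weight change ``after - before`` in g (non-positive)."""
        return self.w_wet_after - self.w_wet_before


def mineral_lost(
    delta_w_wet: float,
    rho_m: float = DEFAULT_RHO_MINERAL,
    rho_w: float = DEFAULT_RHO_WATER,
) -> tuple[float, float]:
    """Volume (cm^3) and weight (g) of mineral lost for a wet-weight change.

    Parameters
    ----------
    delta_w_wet : float
        Wet-weight change ``after - before`` in g; must be <= 0 because
        mineral is denser than the buffer replacing it.
    rho_m, rho_w : float
        Densities of the mineral phase and the buffer, g/cm^3.

    Returns
    -------
    (v_lost, w_lost)
        Both non-negative; ``w_lost = rho_m * v_lost`` exactly.
    """
    if rho_m == rho_w:
        raise DegenerateDataError("rho_m == rho_w makes the mass balance degenerate")
    if not np.isfinite(delta_w_wet) or delta_w_wet > 0:
        raise InvalidArgumentError(
            "delta_w_wet must be <= 0: wet weight decreases when dense mineral "
            f"is replaced by buffer (got {delta_w_wet!r})"
        )
    v_lost = delta_w_wet / (rho_w - rho_m)
    return v_lost, rho_m * v_lost


def mineral_content_percent(w_lost_cumulative: float, w_mineral_initial: float) -> float:
    """Remaining mineral content in wt% of the intact sample.

    ``100 * (1 - w_lost_cumulative / w_mineral_initial)``, in [0, 100].
    """
    if w_mineral_initial <= 0:
        raise InvalidArgumentError("w_mineral_initial must be > 0")
    if w_lost_cumulative < 0 or w_lost_cumulative > w_mineral_initial:
        raise InvalidArgumentError(
            "cumulative mineral loss must lie in [0, w_mineral_initial]"
        )
    return 100.0 * (1.0 - w_lost_cumulative / w_mineral_initial)
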