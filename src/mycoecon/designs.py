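"""Environmental gradient designs for fundamental-niche assays.

The three gradients along which isolate growth is assayed: resource
stoichiometry (C:N ratio of the medium), temperature, and water potential
(osmotic stress imposed e.g. by PEG). Levels are the tested conditions;
``modeling_range`` bounds all curve summaries (optimum, breadth) to the
tested interval so that nothing is extrapolated beyond the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientDesign", "default_gradient_designs", "WATER_PROFILE_FLOOR"]

#: Water-potential floor (MPa) for community-weighted profiles: below this
#: value too few isolates still grow for the weighted mean to be meaningful.
WATER_PROFILE_FLOOR = -1.2


@dataclass(frozen=True)
class GradientDesign:
    """One environmental gradient of a niche assay.

    Parameters
    ----------
    name:
        Gradient identifier (``"CN"``, ``"temperature"``, ``"water_potential"``).
    levels:
        Strictly increasing tested levels, in ``units``.
    units:
        Physical units of the levels (``"ratio"``, ``"degC"``, ``"MPa"``).
    modeling_range:
        ``(lo, hi)`` interval to which curve summaries are restricted;
        must lie within ``[levels[0], levels[-1]]``.
    """

    name: str
    levels: tuple[float, ...]
    units: str
    modeling_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 4:
            raise ValueError(f"gradient {self.name!r} needs >= 4 levels, got {lv.size}")
        if not np.all(np.diff(lv) > 0):
            raise ValueError(f"gradient {self.name!r} levels must be strictly increasing")
        if self.modeling_range is None:
            object.__setattr__(self, "modeling_range", (float(lv[0]), float(lv[-1])))
        lo, hi = self.modeling_range
        if not (lv[0] - 1e-12 <= lo < hi <= lv[-1] + 1e-12):
            raise ValueError(
                f"modeling_range {self.modeling_range} outside tested levels "
                f"[{lv[0]}, {lv[-1]}] for gradient {self.name!r}"
            )

    @property
    def span(self) -> float:
        """Width of the tested interval."""
        return float(self.levels[-1] - self.levels[0])

    def grid(self, n: int = 201) -> np.ndarray:
        """Uniform grid over the modeling range."""
        lo, hi = self.modeling_range
        return np.linspace(lo, hi, n)


def default_gradient_designs() -> dict[str, GradientDesign]:
    """The study's three gradients with ~8 levels each.

    Ranges: C:N 5-200, temperature 12-33 degC, water potential -1.91 to
    -0.49 MPa (levels increasing, i.e. from most to least water-stressed).
    """
    return {
        "CN": GradientDesign(
            "CN", (5.0, 10.0, 20.0, 40.0, 80.0, 120.0, 160.0, 200.0), "ratio"
        ),
        "temperature": GradientDesign(
            "temperature", (12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0, 33.0), "degC"
        ),
        "water_potential": GradientDesign(
            "water_potential",
            tuple(np.round(np.linspace(-1.91, -0.49, 8), 4)),
            "MPa",
        ),
    }
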