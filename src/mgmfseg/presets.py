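"""Named matched-filter parameterizations from the vessel-detection literature.

Single-scale presets reproduce published parameter choices; ``mgmf`` is the
multiscale default (11 scales spanning sigma 1.5-2.5 with a 13 x 15 template
and 12 orientations).  ``al_rawi``, ``gmf_evol`` and ``gmf_entropy`` stem
from parameter-optimization studies whose final optimized values were not
published; they ship with the midpoints of the reported search spaces
(rounded to odd template sizes) and are marked approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GMFPreset", "PRESETS", "get_preset", "DEFAULT_SIGMAS"]

DEFAULT_SIGMAS: tuple[float, ...] = tuple(np.round(np.arange(1.5, 2.51, 0.1), 10))


@dataclass(frozen=True)
class GMFPreset:
    name: str
    sigmas: tuple[float, ...]
    L: int
    T: int
    kappa: int
    approximate: bool = False
    note: str = ""

    @property
    def multiscale(self) -> bool:
        return len(self.sigmas) > 1


PRESETS: dict[str, GMFPreset] = {
    p.name: p
    for p in [
        GMFPreset("chaudhuri", (2.0,), L=9, T=13, kappa=12),
        GMFPreset("cinsdikici", (2.0,), L=9, T=13, kappa=18),
        GMFPreset("kang", (1.5,), L=9, T=13, kappa=6),
        GMFPreset(
            "al_rawi", (2.25,), L=9, T=7, kappa=12, approximate=True,
            note="midpoints of the published search space L=[7..11], T=[2..10], sigma=[1.5..3]; "
            "the optimized values were not published",
        ),
        GMFPreset(
            "gmf_evol", (3.0,), L=11, T=11, kappa=12, approximate=True,
            note="midpoints of the published search space L=[8..15], T=[8..15], sigma=[1..5]; "
            "the differential-evolution optimum was not published",
        ),
        GMFPreset(
            "gmf_entropy", (2.0,), L=9, T=13, kappa=12, approximate=True,
            note="entropy-objective study; parameters unpublished, Chaudhuri-like values used",
        ),
        GMFPreset("mgmf", DEFAULT_SIGMAS, L=13, T=15, kappa=12),
    ]
}


def get_preset(name: str) -> GMFPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
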