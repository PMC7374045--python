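"""Parameter vectors and bounded parameter spaces.

A parameter set theta is a flat ``{name: value}`` mapping.  Names follow a
small grammar interpreted by :meth:`tmesim.model.TMEModel.resolve`:

``R:<type>:<cytokine>``   secretion rate of a cytokine by a cell type (R > 1 active)
``K:<type>:<cytokine>``   receptor activation threshold
``alpha:<gene>``          fraction of cancer cells carrying a mutation clamp
``s``                     cancer clustering parameter (rho_cc = s * rho_C)
``r_C`` / ``r_PSC``       cancer fraction (``r_PSC`` = stellate fraction = 1 - r_C
                          in the two-cell-type model)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Param", "ParameterSpace"]


@dataclass
class Param:
    name: str
    low: float
    high: float
    scale: str = "linear"          # 'linear' or 'log'
    frozen: float | None = None    # set -> excluded from sampling/optimization

    def __post_init__(self):
        if self.frozen is None and not self.low < self.high:
            raise ValueError(f"{self.name}: require low < high")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log'")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")


class ParameterSpace:
    """An ordered collection of bounded parameters, some possibly frozen."""

    def __init__(self, params: list[Param]):
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self.params = list(params)
        self.by_name = {p.name: p for p in self.params}

    @property
    def sampled(self) -> list[Param]:
        return [p for p in self.params if p.frozen is None]

    @property
    def frozen(self) -> dict[str, float]:
        return {p.name: p.frozen for p in self.params if p.frozen is not None}

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def freeze(self, **values) -> "ParameterSpace":
        """Return a copy with the given parameters frozen at fixed values."""
        out = []
        for p in self.params:
            if p.name in values:
                out.append(Param(p.name, p.low, p.high, p.scale, frozen=values[p.name]))
            else:
                out.append(Param(p.name, p.low, p.high, p.scale, frozen=p.frozen))
        return ParameterSpace(out)

    def drop(self, *names) -> "ParameterSpace":
        return ParameterSpace([p for p in self.params if p.name not in names])

    def random(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw theta uniformly (per scale) over the box; frozen values fixed."""
        theta = dict(self.frozen)
        for p in self.sampled:
            if p.scale == "log":
                theta[p.name] = float(10 ** rng.uniform(np.log10(p.low), np.log10(p.high)))
            else:
                theta[p.name] = float(rng.uniform(p.low, p.high))
        return theta

    def clip(self, theta: dict[str, float]) -> dict[str, float]:
        out = dict(theta)
        for p in self.params:
            if p.name in out and p.frozen is None:
                out[p.name] = float(min(max(out[p.name], p.low), p.high))
        out.update(self.frozen)
        return out
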