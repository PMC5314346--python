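"""Species abundance distribution container and CSV round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["SADCurve"]


@dataclass
class SADCurve:
    """Expected (or observed) number of species per abundance class.

    ``n[i]`` is the expected number of species with abundance ``m[i]``.  For
    analytic curves at very large community size the abundance axis switches
    from exact integers to a logarithmic grid above ``~1e4``; ``weights``
    then carry the quadrature weights so that sums over species translate to
    ``sum(weights * n)``.  Empirical curves from the simulators always have
    integer abundances and unit weights.
    """

    m: np.ndarray
    n: np.ndarray
    weights: np.ndarray | None = None
    M: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.m.shape != self.n.shape:
            raise ValueError("m and n must have equal shapes")
        if self.weights is None:
            self.weights = np.ones_like(self.m)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.m < 1):
            raise ValueError("abundances must be >= 1")

    @property
    def richness(self) -> float:
        """Total expected number of species, sum over the curve."""
        return float(np.sum(self.weights * self.n))

    @property
    def total_individuals(self) -> float:
        """Sum of m * n(m): the community size the curve accounts for."""
        return float(np.sum(self.weights * self.m * self.n))

    @property
    def singletons(self) -> float:
        """n(1), the expected number of species with a single individual."""
        idx = np.nonzero(self.m == 1.0)[0]
        if idx.size == 0:
            return 0.0
        return float(self.n[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"abundance": self.m, "count": self.n, "weight": self.weights})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SADCurve":
        df = pd.read_csv(path)
        if "abundance" not in df or "count" not in df:
            raise ValueError("SAD CSV needs 'abundance' and 'count' columns")
        w = df["weight"].to_numpy() if "weight" in df else None
        return cls(df["abundance"].to_numpy(), df["count"].to_numpy(), weights=w)

    @classmethod
    def from_abundances(cls, abundances: np.ndarray) -> "SADCurve":
        """Histogram a vector of per-species abundances into an SAD."""
        ab = np.asarray(abundances)
        if ab.size == 0:
            raise ValueError("empty abundance vector")
        vals, counts = np.unique(ab, return_counts=True)
        return cls(vals.astype(float), counts.astype(float))

    def export_json(self, path: str | Path, **extra: Any) -> None:
        """Write summary metadata {M, richness, ...} as JSON."""
        payload = {
            "M": self.M,
            "richness": self.richness,
            "total_individuals": self.total_individuals,
            "singletons": self.singletons,
            **self.meta,
            **extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))
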