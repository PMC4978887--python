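"""Empirical false-discovery-rate bookkeeping.

The FDR used throughout is the empirical E(V/R): the expected number of
significant traits under the null at significance level alpha (alpha * T)
divided by the observed number of significant traits R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class FdrReport:
    """q = alpha * n_traits_tested / n_significant; NA when nothing passes."""

    alpha: float
    n_traits_tested: int
    n_significant: int

    def __post_init__(self) -> None:
        if self.n_significant > self.n_traits_tested:
            raise ValueError("n_significant cannot exceed n_traits_tested")
        if self.n_significant < 0:
            raise ValueError("n_significant must be >= 0")

    @property
    def q(self) -> float:
        if self.n_significant == 0:
            return math.nan
        return self.alpha * self.n_traits_tested / self.n_significant

    def to_dict(self) -> dict:
        q = self.q
        return {
            "alpha": self.alpha,
            "n_traits_tested": self.n_traits_tested,
            "n_significant": self.n_significant,
            "q": None if math.isnan(q) else q,
        }
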