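"""Shared result records for permutation tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class GroupComparisonResult:
    """A permutation/enumeration test outcome.

    ``n_permutations`` is the number of label assignments examined: the full
    enumeration count when ``exact`` is True, else the Monte-Carlo draw count.
    Permutation p-values use the plus-one estimator (b + 1) / (B + 1); exact
    p-values are count / total (the identity assignment keeps p > 0).
    """

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool = False
    seed: Optional[int] = None
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value outside (0, 1]: {self.p_value}")
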