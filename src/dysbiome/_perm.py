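"""Label-assignment enumeration helpers for exact permutation tests.

A test switches from Monte-Carlo permutation to full enumeration when the
number of distinct label assignments is at most ``ENUMERATION_LIMIT``.
"""

from __future__ import annotations

from math import comb, factorial
from typing import Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

ENUMERATION_LIMIT = 20_000


def n_assignments(group_sizes: Sequence[int]) -> int:
    """Multinomial coefficient: distinct label vectors with these sizes."""
    n = sum(group_sizes)
    out = factorial(n)
    for k in group_sizes:
        out //= factorial(k)
    return out


def all_label_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct permutations of an integer label vector, as a matrix.

    Rows are label vectors; the observed assignment is among them. Intended
    only when :func:`n_assignments` is within ``ENUMERATION_LIMIT``.
    """
    return np.array(list(multiset_permutations(list(codes))), dtype=np.int64)


def two_group_masks(n: int, n1: int) -> np.ndarray:
    """Boolean matrix of all C(n, n1) memberships of the first group."""
    from itertools import combinations

    m = comb(n, n1)
    out = np.zeros((m, n), dtype=bool)
    for row, idx in enumerate(combinations(range(n), n1)):
        out[row, list(idx)] = True
    return out
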