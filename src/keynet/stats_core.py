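"""Exact tests and multiple-testing machinery shared across pipeline stages.

Conventions
-----------
* Two-sided Fisher's exact test uses the probability-ordering convention
  (sum the probabilities of all tables with the same margins that are at
  most as probable as the observed table).
* Gene-set enrichment uses the one-sided upper hypergeometric tail, i.e.
  it only detects over-representation; "fold enrichment" is the observed
  overlap divided by the overlap expected under hypergeometric sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "hypergeom_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts: rows = group, columns = trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        entries = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in entries):
            raise ValueError("contingency table entries must be non-negative integers")
        if sum(entries) == 0:
            raise ValueError("contingency table total must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table: ContingencyTable2x2 | np.ndarray | list) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Degenerate tables (an empty row or column margin) are undefined; a
    warning is issued and 1.0 returned.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = np.asarray(table, dtype=np.int64)
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    m = table.matrix
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        warnings.warn("Fisher test undefined for empty margin; returning p = 1.0")
        return 1.0
    return float(sps.fisher_exact(m, alternative="two-sided")[1])


def hypergeom_enrichment(
    overlap: int, set_size: int, target_size: int, universe: int
) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p for a set overlap.

    Parameters
    ----------
    overlap
        Number of elements shared between the query set and target set.
    set_size
        Size of the query set (number of draws).
    target_size
        Number of "success" elements in the universe.
    universe
        Size of the background universe.

    Returns
    -------
    (fold_enrichment, p) where fold = (overlap/set_size)/(target_size/universe)
    and p = P[X >= overlap] for X ~ Hypergeometric(universe, target_size, set_size).
    """
    for name, v in (
        ("overlap", overlap),
        ("set_size", set_size),
        ("target_size", target_size),
        ("universe", universe),
    ):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if set_size == 0 or target_size == 0 or universe == 0:
        raise ValueError("set_size, target_size and universe must be positive")
    if overlap > min(set_size, target_size):
        raise ValueError("overlap exceeds min(set_size, target_size)")
    if max(set_size, target_size) > universe:
        raise ValueError("set or target larger than universe")
    fold = (overlap / set_size) / (target_size / universe)
    p = float(sps.hypergeom.sf(overlap - 1, universe, target_size, set_size))
    return fold, min(p, 1.0)


def bh_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Stable with respect to input order: the returned array is aligned with
    the input. Values are monotone in rank order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out
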