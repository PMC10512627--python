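"""Normalization, abundance filtering, discovery/test splitting, cohort summary."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import CountMatrix
from .stats_core import fisher_exact_2x2

__all__ = [
    "SplitAssignment",
    "cpm_normalize",
    "filter_low_abundance",
    "split_discovery_test",
    "cohort_summary",
    "percentage",
    "log_cpm",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint discovery/test partition; discovery takes the ceiling share."""

    discovery: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        d, t = set(self.discovery), set(self.test)
        if d & t:
            raise ValueError("discovery and test sets overlap")
        n = len(d) + len(t)
        if len(d) != math.ceil(2 * n / 3):
            raise ValueError("discovery size must be ceiling(2n/3)")


def cpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-million on the full pre-filter matrix.

    Library sizes are per-sample column sums of the matrix as given; every
    column of the result sums to 1e6.
    """
    mat = counts.counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = mat / libsize[None, :] * 1e6
    return pd.DataFrame(cpm, index=counts.counts.index, columns=counts.counts.columns)


def filter_low_abundance(
    cpm: pd.DataFrame, threshold: float = 5.0, max_low_fraction: float = 0.10
) -> list[str]:
    """Genes kept by the low-abundance rule.

    A gene is removed iff its CPM is <= ``threshold`` in strictly more than
    ``max_low_fraction`` of samples; the boundary fraction itself is kept.
    """
    low_frac = (cpm.to_numpy() <= threshold).mean(axis=1)
    keep = low_frac <= max_low_fraction + 1e-12
    return [g for g, k in zip(cpm.index, keep) if k]


def split_discovery_test(
    samples: pd.DataFrame, seed: int, stratify: bool = False
) -> SplitAssignment:
    """Random 2:1 partition of sample IDs; discovery gets ceiling(2n/3).

    With ``stratify`` the 2:1 ratio is applied within each phenotype group
    (ceiling share per group, trimmed to the global ceiling rule).
    """
    ids = list(samples["sample_id"])
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 samples to split 2:1")
    n_disc = math.ceil(2 * n / 3)
    rng = np.random.default_rng(seed)
    if not stratify:
        perm = rng.permutation(n)
        disc = [ids[i] for i in perm[:n_disc]]
        test = [ids[i] for i in perm[n_disc:]]
    else:
        disc, test = [], []
        for _, grp in samples.groupby("asthma", sort=True):
            gids = list(grp["sample_id"])
            perm = rng.permutation(len(gids))
            k = math.ceil(2 * len(gids) / 3)
            disc.extend(gids[i] for i in perm[:k])
            test.extend(gids[i] for i in perm[k:])
        # trim to the exact global ceiling rule
        rng.shuffle(disc)
        while len(disc) > n_disc:
            test.append(disc.pop())
    return SplitAssignment(discovery=tuple(sorted(disc)), test=tuple(sorted(test)))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100 * count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def cohort_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Group counts, half-up percentages, and Fisher p for binary traits.

    One row per trait level: overall count and percentage, counts and
    percentages within the case and control groups, and (for binary
    traits other than the phenotype itself) a Fisher's exact p-value for
    the trait x phenotype 2x2 table.
    """
    if len(samples) == 0:
        raise ValueError("empty sample table")
    if "asthma" not in samples.columns:
        raise ValueError("sample table must contain an 'asthma' column")
    total = len(samples)
    cases = samples[samples["asthma"] == 1]
    ctrls = samples[samples["asthma"] == 0]
    rows = []

    def add_row(trait, count, case_count, ctrl_count, p=np.nan):
        rows.append(
            {
                "trait": trait,
                "count": count,
                "pct": percentage(count, total),
                "case_count": case_count,
                "case_pct": percentage(case_count, max(len(cases), 1)),
                "control_count": ctrl_count,
                "control_pct": percentage(ctrl_count, max(len(ctrls), 1)),
                "p": p,
            }
        )

    add_row("asthma", len(cases), len(cases), 0)
    for col in samples.columns:
        if col in ("sample_id", "asthma"):
            continue
        series = samples[col]
        levels = series.dropna().unique()
        if len(levels) <= 1:
            continue
        if len(levels) == 2 or series.dtype == object:
            for level in sorted(map(str, levels)):
                mask = series.astype(str) == level
                a = int((mask & (samples["asthma"] == 1)).sum())
                b = int((mask & (samples["asthma"] == 0)).sum())
                c, d = len(cases) - a, len(ctrls) - b
                p = fisher_exact_2x2([[a, b], [c, d]]) if len(levels) == 2 else np.nan
                add_row(f"{col}={level}", a + b, a, b, p)
    return pd.DataFrame(rows)


def log_cpm(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Natural-log CPM with a pseudocount; the expression scale used by
    co-expression, eQTL, discretization, and mediation stages."""
    return np.log(cpm_normalize(counts) + pseudocount)
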