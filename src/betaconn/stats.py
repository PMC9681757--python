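"""Permutation statistics for within-participant condition comparisons.

The omnibus repeated-measures test permutes condition labels within each
participant (the within-participant exchangeability null) and the
post-hoc pairwise test sign-flips within-participant differences,
exhaustively when feasible.  p-values follow the add-one convention
(1 + #{perm >= obs}) / (1 + n_perm) for Monte-Carlo nulls, so 0 is never
reported; exhaustive nulls use the exact enumeration fraction (the
identity permutation is part of the enumeration).  Benjamini-Hochberg
FDR corrects across the density sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConditionTable",
    "rm_permutation_test",
    "pairwise_permutation",
    "fdr_correct",
    "behavior_correlation",
]


@dataclass
class ConditionTable:
    """Participants x conditions table of one scalar network measure."""

    values: pd.DataFrame  # index: participants, columns: conditions
    measure: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError(
                "condition table must be complete for within-participant "
                "permutation exchangeability"
            )

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PermutationResult:
    statistic: float
    p: float
    n_perm: int
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)


def _rm_statistic(x: np.ndarray) -> float:
    """Between-condition sum of squares of condition means after
    within-participant centering."""
    centered = x - x.mean(axis=1, keepdims=True)
    return float((centered.mean(axis=0) ** 2).sum())


def rm_permutation_test(
    table: ConditionTable | pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Omnibus repeated-measures permutation test across conditions.

    The null is built by independently permuting the condition labels
    within each participant.  Returns the add-one Monte-Carlo p-value.
    """
    df = table.values if isinstance(table, ConditionTable) else table
    x = df.to_numpy(dtype=float)
    n_sub, n_cond = x.shape
    if n_cond < 2 or n_sub < 2:
        raise ValueError("need at least 2 conditions and 2 participants")
    centered = x - x.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        warnings.warn("constant condition table; omnibus p set to 1")
        return PermutationResult(statistic=0.0, p=1.0, n_perm=n_perm)
    obs = _rm_statistic(x)
    rng = np.random.default_rng(seed)
    # all permutations at once: n_perm x n_sub independent label shuffles
    idx = rng.permuted(
        np.tile(np.arange(n_cond), (n_perm, n_sub, 1)), axis=2
    )
    perm_vals = centered[np.arange(n_sub)[None, :, None], idx]
    null = (perm_vals.mean(axis=1) ** 2).sum(axis=1)
    count = int((null >= obs - 1e-12).sum())
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(statistic=obs, p=p, n_perm=n_perm)


def _signflip_null(diff: np.ndarray, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Null distribution of the mean paired difference under sign flips.

    Exhaustive when 2^n <= n_perm, else Monte-Carlo with n_perm draws.
    """
    n = diff.size
    if 2**n <= n_perm:
        signs = np.array(
            [[1 if (m >> i) & 1 == 0 else -1 for i in range(n)] for m in range(2**n)],
            dtype=float,
        )
        return (signs * diff).mean(axis=1), True
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    return (signs * diff).mean(axis=1), False


def pairwise_permutation(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Paired sign-flip permutation test between two conditions.

    ``a`` and ``b`` are per-participant values.  The statistic is the
    mean within-participant difference a - b; the null flips each
    difference's sign, exhaustively when 2^n <= n_perm.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need matched per-participant value vectors")
    diff = a - b
    obs = diff.mean()
    if np.allclose(diff, 0):
        return PermutationResult(statistic=0.0, p=1.0, n_perm=n_perm)
    null, exhaustive = _signflip_null(diff, n_perm, seed)
    tol = 1e-12
    if alternative == "two-sided":
        count = int((np.abs(null) >= abs(obs) - tol).sum())
    elif alternative == "greater":
        count = int((null >= obs - tol).sum())
    elif alternative == "less":
        count = int((null <= obs + tol).sum())
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    if exhaustive:
        p = count / null.size
    else:
        p = (1 + count) / (1 + n_perm)
    return PermutationResult(
        statistic=float(obs), p=float(p), n_perm=int(null.size), exhaustive=exhaustive
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def behavior_correlation(
    nodal_values: np.ndarray, behavior: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between a nodal measure (e.g. the target
    node's participation coefficient) and behavior (e.g. reaction time)
    across participants, with the two-sided t-based p-value."""
    x = np.asarray(nodal_values, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 participants")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation inputs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
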