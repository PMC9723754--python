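"""Variance partitioning of a linear model among three predictor groups.

The adjusted R² of the seven subset models ({1}, {2}, {3}, {1,2}, {1,3},
{2,3}, {1,2,3}) is decomposed by inclusion–exclusion into three unique
fractions, three pairwise-shared fractions and one three-way shared
fraction. Fractions can be slightly negative — an artifact of the
adjusted-R² correction — and are reported as computed, so the identity

    a + b + c + d + e + f + g = adjusted R² of the full model

holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def adjusted_r2(y, X, adjust: bool = True) -> float:
    """Adjusted R² of the OLS regression of ``y`` on ``X`` plus intercept.

    Uses the Ezekiel adjustment 1 − (1−R²)(n−1)/(n−p−1). With ``adjust``
    False, returns the raw R². An empty ``X`` gives 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = _as_matrix(X, n)
    p = X.shape[1]
    if p == 0:
        return 0.0
    if n <= p + 1:
        raise ValueError(f"degenerate fit: n={n} <= p+1={p + 1}")
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("response is constant; R² undefined")
    r2 = 1.0 - (resid**2).sum() / tss
    if not adjust:
        return float(r2)
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class PartitionResult:
    """Adjusted-R² partition among three groups of explanatory variables."""

    labels: tuple[str, str, str]
    subset_r2: dict[frozenset, float]      # the 7 subset-model adjusted R²
    unique: dict[str, float]               # a, b, c
    pairwise: dict[frozenset, float]       # d, e, f
    threeway: float                        # g
    total: float                           # full-model adjusted R²
    residual: float                        # 1 − total
    notes: list[str] = field(default_factory=list)

    def fractions(self) -> pd.Series:
        """All seven fractions plus total and residual, as a Series."""
        l1, l2, l3 = self.labels
        return pd.Series(
            {
                f"unique[{l1}]": self.unique[l1],
                f"unique[{l2}]": self.unique[l2],
                f"unique[{l3}]": self.unique[l3],
                f"shared[{l1},{l2}]": self.pairwise[frozenset((l1, l2))],
                f"shared[{l1},{l3}]": self.pairwise[frozenset((l1, l3))],
                f"shared[{l2},{l3}]": self.pairwise[frozenset((l2, l3))],
                f"shared[{l1},{l2},{l3}]": self.threeway,
                "total": self.total,
                "residual": self.residual,
            }
        )


class VariancePartitioner(BaseEstimator):
    """Partition explained variance in ``y`` among three predictor groups.

    Parameters
    ----------
    groups : mapping of label -> list of column names (exactly three).
    adjust : bool, default True
        Use adjusted R² (raw R² available for testing).

    Attributes
    ----------
    result_ : PartitionResult
    """

    def __init__(self, groups: dict | None = None, adjust: bool = True):
        self.groups = groups
        self.adjust = adjust

    def fit(self, X: pd.DataFrame, y):
        if not self.groups or len(self.groups) != 3:
            raise ValueError("groups must map exactly three labels to column lists")
        labels = tuple(self.groups)
        notes = []
        cols = {}
        for lab in labels:
            members = [c for c in self.groups[lab]]
            missing = [c for c in members if c not in X.columns]
            if missing:
                raise KeyError(f"group {lab!r} columns absent from X: {missing}")
            if not members:
                notes.append(f"group {lab!r} is empty; its fractions are 0")
                logger.warning("variance partition: group %r is empty", lab)
            cols[lab] = members

        y = np.asarray(y, dtype=float)

        def r2_of(subset: frozenset) -> float:
            members = [c for lab in labels if lab in subset for c in cols[lab]]
            if not members:
                return 0.0
            return adjusted_r2(y, X[members], adjust=self.adjust)

        singles = [frozenset([l]) for l in labels]
        pairs = [frozenset([a, b]) for i, a in enumerate(labels) for b in labels[i + 1:]]
        full = frozenset(labels)
        subset_r2 = {s: r2_of(s) for s in singles + pairs + [full]}

        l1, l2, l3 = labels
        R = subset_r2
        total = R[full]
        # inclusion–exclusion: unique fraction of a group is the gain of the
        # full model over the other two groups combined
        unique = {
            l1: total - R[frozenset((l2, l3))],
            l2: total - R[frozenset((l1, l3))],
            l3: total - R[frozenset((l1, l2))],
        }
        # pairwise fraction shared by a and b (not c):
        # R(ac) + R(bc) − R(abc) − R(c)
        pairwise = {}
        for a, b in ((l1, l2), (l1, l3), (l2, l3)):
            c = next(l for l in labels if l not in (a, b))
            pairwise[frozenset((a, b))] = (
                R[frozenset((a, c))]
                + R[frozenset((b, c))]
                - total
                - R[frozenset([c])]
            )
        threeway = total - sum(unique.values()) - sum(pairwise.values())
        self.result_ = PartitionResult(
            labels=labels,
            subset_r2=subset_r2,
            unique=unique,
            pairwise=pairwise,
            threeway=threeway,
            total=total,
            residual=1.0 - total,
            notes=notes,
        )
        return self


def partition_three_groups(y, G1, G2, G3, labels=("G1", "G2", "G3"),
                           adjust: bool = True) -> PartitionResult:
    """Partition ``y`` among three explicit predictor blocks.

    ``G1``, ``G2``, ``G3`` are 2-D arrays or DataFrames (possibly empty);
    see :class:`VariancePartitioner`.
    """
    frames, groups = [], {}
    for lab, G in zip(labels, (G1, G2, G3)):
        df = _as_frame(G, prefix=lab)
        groups[lab] = list(df.columns)
        frames.append(df)
    X = pd.concat([f for f in frames if f.shape[1]], axis=1) if any(
        f.shape[1] for f in frames
    ) else pd.DataFrame(index=range(len(np.asarray(y))))
    part = VariancePartitioner(groups=groups, adjust=adjust).fit(X, y)
    return part.result_


def _as_matrix(X, n: int) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    if arr.size == 0:
        return np.empty((n, 0))
    if arr.shape[0] != n:
        raise ValueError("X and y lengths differ")
    return arr


def _as_frame(G, prefix: str) -> pd.DataFrame:
    if isinstance(G, pd.DataFrame):
        return G
    arr = np.asarray(G, dtype=float)
    if arr.size == 0:
        return pd.DataFrame()
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"{prefix}_{i}" for i in range(arr.shape[1])])
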