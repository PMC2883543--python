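"""Linear regression of physicochemical properties on compound vectors.

The triplet components of a compound vector serve as independent variables
in a plain multivariate ordinary-least-squares fit of one property at a
time (hydrophobicity logP, molecular weight MW in g/mol, topological polar
surface area TPSA in square angstroms).  Properties are inputs, never
computed from structure here.  Predictive value is estimated by k-fold
cross-validation (default 10): a seeded shuffle is split into contiguous
near-equal folds, each fold is predicted by the model fit on the others,
and the pooled predictions are compared to the experimental values by
Pearson correlation.

Rank-deficient designs (duplicated or collinear triplet columns) are
handled by the minimum-norm least-squares solution and flagged; no
regularisation is applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PropertyRecord",
    "RegressionFit",
    "CvReport",
    "fit_ols",
    "cross_validate",
    "read_property_table",
    "write_property_tsv",
]


@dataclass
class PropertyRecord:
    """Per-compound property values; NaN marks a missing field."""

    compound_id: str
    logP: float = float("nan")
    MW: float = float("nan")
    TPSA: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isnan(self.MW) and self.MW <= 0:
            raise ValueError(f"{self.compound_id}: MW must be > 0")


@dataclass
class RegressionFit:
    coefficients: np.ndarray = field(repr=False)  # per component
    intercept: float
    R: float
    R2: float
    rank_deficient: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


@dataclass
class CvReport:
    predicted: np.ndarray
    fold_assignment: np.ndarray
    R: float


def _lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    A = np.column_stack([X, np.ones(len(X))])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    return beta, rank


def fit_ols(X: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Least-squares fit of y on the vector components plus an intercept.

    R is the Pearson correlation of fitted vs observed values and R2 its
    square (identical to the coefficient of determination for OLS with
    intercept).  An all-identical response leaves R undefined (NaN, with a
    warning).  Rank deficiency yields the minimum-norm solution, flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per response value")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    beta, rank = _lstsq(X, y)
    deficient = rank < X.shape[1] + 1
    if deficient:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {X.shape[1] + 1}); "
            "minimum-norm solution returned",
            stacklevel=2,
        )
    fitted = np.column_stack([X, np.ones(len(X))]) @ beta
    if np.ptp(y) == 0:
        warnings.warn("response is constant; R undefined", stacklevel=2)
        r = float("nan")
    else:
        sst = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum((y - fitted) ** 2))
        r2 = max(1.0 - sse / sst, 0.0)
        r = float(np.sqrt(r2))
    return RegressionFit(
        coefficients=beta[:-1],
        intercept=float(beta[-1]),
        R=r,
        R2=r * r if not np.isnan(r) else float("nan"),
        rank_deficient=deficient,
    )


def cross_validate(
    X: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0
) -> CvReport:
    """Seeded k-fold cross-validation with pooled-prediction correlation.

    Items are shuffled once and split into contiguous blocks whose sizes
    differ by at most one; each block is predicted from a fit on the rest,
    so every compound is predicted exactly once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    predicted = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for fold, test_idx in enumerate(np.array_split(perm, folds)):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        beta, _ = _lstsq(X[mask], y[mask])
        predicted[test_idx] = np.column_stack(
            [X[test_idx], np.ones(len(test_idx))]
        ) @ beta
        fold_of[test_idx] = fold
    r = float(np.corrcoef(predicted, y)[0, 1])
    return CvReport(predicted=predicted, fold_assignment=fold_of, R=r)


# --------------------------------------------------------------------------
# TSV I/O
# --------------------------------------------------------------------------


def read_property_table(source: str | io.TextIOBase) -> list[PropertyRecord]:
    """TSV with columns compound_id, logP, MW, TPSA (blank = missing)."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in ("compound_id", "logP", "MW", "TPSA") if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing column(s): {missing}")
    return [
        PropertyRecord(
            str(row.compound_id),
            float(row.logP) if pd.notna(row.logP) else float("nan"),
            float(row.MW) if pd.notna(row.MW) else float("nan"),
            float(row.TPSA) if pd.notna(row.TPSA) else float("nan"),
        )
        for row in df.itertuples()
    ]


def write_property_tsv(records: list[PropertyRecord]) -> str:
    def cell(x: float) -> str:
        return "" if np.isnan(x) else repr(x)

    out = ["compound_id\tlogP\tMW\tTPSA"]
    out.extend(
        f"{r.compound_id}\t{cell(r.logP)}\t{cell(r.MW)}\t{cell(r.TPSA)}"
        for r in records
    )
    return "\n".join(out) + "\n"
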