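"""Design-matrix construction with reference-cell dummy coding.

Categorical covariates are expanded into indicator columns, omitting one
reference category per covariate (the first declared category unless
overridden).  An intercept column is always included, and the binary
ANC-dimension regressor, when given, is appended last so counterfactual
prediction can overwrite a single known column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import EstimationInputError

INTERCEPT = "intercept"


def dummy_name(column: str, category) -> str:
    return f"{column}[{category}]"


@dataclass
class DesignMatrix:
    """Dense real design matrix plus column bookkeeping."""

    values: np.ndarray
    names: list[str]
    reference: dict[str, str] = field(default_factory=dict)
    dimension_col: str | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def with_dimension(self, d: int) -> np.ndarray:
        """Copy of the matrix with the dimension column set to ``d`` for all rows."""
        if self.dimension_col is None:
            return self.values.copy()
        out = self.values.copy()
        out[:, self.names.index(self.dimension_col)] = float(d)
        return out

    def drop_dimension(self) -> "DesignMatrix":
        """Covariate-only design (dimension column removed)."""
        if self.dimension_col is None:
            return self
        j = self.names.index(self.dimension_col)
        return DesignMatrix(
            values=np.delete(self.values, j, axis=1),
            names=[nm for i, nm in enumerate(self.names) if i != j],
            reference=dict(self.reference),
            dimension_col=None,
        )


def _categories(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [c for c in series.cat.categories if (series == c).any()]
    return sorted(pd.unique(series.dropna()))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns involved in a rank deficiency, via pivoted QR."""
    _, r, piv = scipy.linalg.qr(X, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def build_design_matrix(
    table: pd.DataFrame,
    dimension: pd.Series | np.ndarray | None,
    covariates: list[str],
    reference: dict[str, str] | None = None,
    dimension_name: str = "dimension",
) -> DesignMatrix:
    """Assemble intercept + dummy-coded covariates + optional dimension column.

    Parameters
    ----------
    table
        Microdata with the requested covariate columns.
    dimension
        Binary 0/1 regressor (the ANC dimension under study) or None.
    covariates
        Column names to dummy-code.  Numeric binary columns pass through
        as a single column.
    reference
        Optional override of the omitted category per covariate.
    """
    n = len(table)
    reference = dict(reference or {})
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [INTERCEPT]
    used_reference: dict[str, str] = {}

    for cov in covariates:
        if cov not in table.columns:
            raise EstimationInputError(f"covariate column {cov!r} not found")
        series = table[cov]
        if series.isna().any():
            raise EstimationInputError(f"covariate {cov!r} contains missing values")
        if pd.api.types.is_numeric_dtype(series) and set(pd.unique(series)) <= {0, 1}:
            if series.nunique() < 2:
                warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=2)
                continue
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
            continue
        cats = _categories(series)
        if len(cats) < 2:
            warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=2)
            continue
        ref = reference.get(cov, cats[0])
        if ref not in cats:
            raise EstimationInputError(
                f"reference category {ref!r} absent from covariate {cov!r}"
            )
        used_reference[cov] = ref
        for cat in cats:
            if cat == ref:
                continue
            cols.append((series == cat).to_numpy(dtype=float))
            names.append(dummy_name(cov, cat))

    dim_col_name = None
    if dimension is not None:
        d = np.asarray(dimension, dtype=float)
        if d.shape != (n,):
            raise EstimationInputError("dimension column length mismatch")
        if not np.isin(d, (0.0, 1.0)).all():
            raise EstimationInputError("dimension column must be binary 0/1")
        dim_col_name = getattr(dimension, "name", None) or dimension_name
        cols.append(d)
        names.append(str(dim_col_name))
        dim_col_name = str(dim_col_name)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise EstimationInputError(
            "design matrix is rank deficient; collinear columns: " + ", ".join(bad)
        )
    return DesignMatrix(values=X, names=names, reference=used_reference,
                        dimension_col=dim_col_name)
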