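"""Discrete information measures over binary variables, in bits.

Every measure accepts either a :class:`~synergynet.bayesnet.JointTable`
(exact computation) or tabular 0/1 data (plug-in, i.e. maximum-likelihood,
estimation from empirical cell frequencies).  Quantities:

- Shannon entropy H and multivariate mutual information MI(A;B),
- total correlation  TC = sum_i H(X_i) - H(X),
- dual total correlation  DTC = (1-n) H(X) + sum_i H(X \\ i),
- O-information  Omega = TC - DTC.  Omega < 0 flags synergy-dominated
  interdependence (the XOR triplet attains exactly -1 bit), Omega > 0
  redundancy-dominated (three copies of one bit attain +1 bit),
- Whole-Minus-Sum synergy  WMS = MI({P1,P2};T) - MI(P1;T) - MI(P2;T).

All logarithms are base 2.  ``0 * log 0`` is treated as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesnet import JointTable

__all__ = [
    "DataMatrix",
    "InfoQuantity",
    "entropy",
    "mutual_information",
    "total_correlation",
    "dual_total_correlation",
    "o_information",
    "wms_synergy",
    "mi_matrix",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DataMatrix:
    """An n-subjects × m-variables table of strictly 0/1 values.

    Construct with :meth:`from_frame`, which validates entries; missing
    values are rejected here -- per-computation listwise deletion is
    available by passing a raw DataFrame to the measures with
    ``missing="drop"``.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataMatrix":
        if frame.shape[0] < 1:
            raise ValueError("DataMatrix needs at least one row")
        labels = list(frame.columns)
        if len(set(labels)) != len(labels):
            dupes = sorted({c for c in labels if labels.count(c) > 1})
            raise ValueError(f"duplicate column label(s): {dupes}")
        if frame.isna().any().any():
            raise ValueError(
                "missing values present; drop them explicitly or pass the raw "
                "DataFrame with missing='drop'"
            )
        try:
            arr = frame.to_numpy().astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric entries in data table: {exc}") from None
        ok = np.isin(arr, (0.0, 1.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-binary entry at row {bad[0]}, column {labels[bad[1]]!r}"
            )
        clean = pd.DataFrame(arr.astype(np.int8), columns=labels)
        return cls(frame=clean)

    @classmethod
    def from_array(cls, values, columns) -> "DataMatrix":
        return cls.from_frame(pd.DataFrame(np.asarray(values), columns=list(columns)))

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n(self) -> int:
        return int(self.frame.shape[0])

    @property
    def m(self) -> int:
        return int(self.frame.shape[1])


@dataclass(frozen=True)
class InfoQuantity:
    """A scalar information quantity in bits, with provenance."""

    value: float
    estimator: str  # "exact" or "plugin"
    variables: tuple[str, ...]

    def __float__(self) -> float:
        return float(self.value)


def _entropy_from_probs(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0.0]
    return float(-(p * np.log2(p)).sum())


def _probs(source, variables, missing: str = "raise") -> tuple[np.ndarray, str]:
    """(probability vector over the sub-states of ``variables``, estimator)."""
    variables = list(variables)
    if len(set(variables)) != len(variables):
        raise ValueError(f"duplicate variable label(s) in {variables}")
    if isinstance(source, JointTable):
        unknown = [v for v in variables if v not in source.variables]
        if unknown:
            raise ValueError(f"unknown variable label(s): {unknown}")
        return source.marginalize(variables).probs.ravel(), "exact"
    if isinstance(source, DataMatrix):
        frame = source.frame
    elif isinstance(source, pd.DataFrame):
        frame = source
    else:
        raise TypeError(
            f"expected JointTable, DataMatrix or DataFrame, got {type(source).__name__}"
        )
    unknown = [v for v in variables if v not in frame.columns]
    if unknown:
        raise ValueError(f"unknown variable label(s): {unknown}")
    sub = frame[variables]
    if sub.isna().any().any():
        if missing == "drop":
            sub = sub.dropna()
            if sub.shape[0] == 0:
                raise ValueError("no complete rows left after listwise deletion")
        else:
            raise ValueError(
                "missing values in the requested columns; pass missing='drop' "
                "for listwise deletion"
            )
    arr = sub.to_numpy().astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("data contain non-binary entries")
    arr = arr.astype(np.int64)
    k = len(variables)
    codes = arr @ (1 << np.arange(k - 1, -1, -1, dtype=np.int64))
    counts = np.bincount(codes, minlength=1 << k)
    return counts / counts.sum(), "plugin"


def entropy(source, variables, missing: str = "raise", miller_madow: bool = False) -> InfoQuantity:
    """Shannon entropy H(variables) in bits.

    ``miller_madow=True`` adds the small-sample correction
    ``(cells_observed - 1) / (2 n ln 2)`` to plug-in estimates; the default
    is the plain maximum-likelihood estimator (the permutation null used by
    the scan pipeline makes bias correction unnecessary there).
    """
    p, est = _probs(source, variables, missing)
    h = _entropy_from_probs(p)
    if miller_madow and est == "plugin":
        n_obs = _n_rows(source, variables, missing)
        h += (np.count_nonzero(p) - 1) / (2.0 * n_obs * _LN2)
    return InfoQuantity(value=h, estimator=est, variables=tuple(variables))


def _n_rows(source, variables, missing) -> int:
    if isinstance(source, DataMatrix):
        frame = source.frame
    else:
        frame = source
    sub = frame[list(variables)]
    if missing == "drop":
        sub = sub.dropna()
    return int(sub.shape[0])


def _h(source, variables, missing) -> tuple[float, str]:
    p, est = _probs(source, variables, missing)
    return _entropy_from_probs(p), est


def mutual_information(source, set_a, set_b, missing: str = "raise") -> InfoQuantity:
    """MI(A;B) = H(A) + H(B) - H(A,B), symmetric and (exactly) non-negative."""
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both variable sets must be non-empty")
    overlap = sorted(set(set_a) & set(set_b))
    if overlap:
        raise ValueError(f"variable sets overlap: {overlap}")
    ha, est = _h(source, set_a, missing)
    hb, _ = _h(source, set_b, missing)
    hab, _ = _h(source, set_a + set_b, missing)
    return InfoQuantity(value=ha + hb - hab, estimator=est, variables=tuple(set_a + set_b))


def total_correlation(source, variables, missing: str = "raise") -> InfoQuantity:
    """TC = sum_i H(X_i) - H(X); zero iff all variables are independent (exact)."""
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("total correlation needs at least 2 variables")
    hx, est = _h(source, variables, missing)
    tc = sum(_h(source, [v], missing)[0] for v in variables) - hx
    return InfoQuantity(value=tc, estimator=est, variables=tuple(variables))


def dual_total_correlation(source, variables, missing: str = "raise") -> InfoQuantity:
    """DTC = (1-n) H(X) + sum_i H(X without i)."""
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("dual total correlation needs at least 2 variables")
    hx, est = _h(source, variables, missing)
    n = len(variables)
    rest = sum(
        _h(source, variables[:i] + variables[i + 1 :], missing)[0] for i in range(n)
    )
    return InfoQuantity(value=(1 - n) * hx + rest, estimator=est, variables=tuple(variables))


def o_information(source, variables, missing: str = "raise") -> InfoQuantity:
    """O-information Omega = (n-2) H(X) + sum_i [H(X_i) - H(X without i)].

    Negative values flag synergy-dominated dependence, positive values
    redundancy-dominated.  Computed directly from this formula (not as
    TC - DTC), so the algebraic identity Omega = TC - DTC serves as an
    independent cross-check.
    """
    variables = list(variables)
    if len(variables) < 3:
        raise ValueError("O-information needs at least 3 variables")
    hx, est = _h(source, variables, missing)
    n = len(variables)
    acc = (n - 2) * hx
    for i in range(n):
        acc += _h(source, [variables[i]], missing)[0]
        acc -= _h(source, variables[:i] + variables[i + 1 :], missing)[0]
    return InfoQuantity(value=acc, estimator=est, variables=tuple(variables))


def wms_synergy(source, parents, target: str, missing: str = "raise") -> InfoQuantity:
    """Whole-Minus-Sum synergy MI({P1,P2};T) - MI(P1;T) - MI(P2;T)."""
    parents = list(parents)
    if len(parents) != 2:
        raise ValueError("wms_synergy takes exactly two parent labels")
    labels = parents + [target]
    if len(set(labels)) != 3:
        raise ValueError(f"labels must be distinct, got {labels}")
    whole = mutual_information(source, parents, [target], missing).value
    parts = sum(
        mutual_information(source, [p], [target], missing).value for p in parents
    )
    est = "exact" if isinstance(source, JointTable) else "plugin"
    return InfoQuantity(value=whole - parts, estimator=est, variables=tuple(labels))


def mi_matrix(data: DataMatrix | pd.DataFrame, missing: str = "raise") -> pd.DataFrame:
    """Symmetric m×m matrix of pairwise plug-in MI in bits (diagonal 0).

    This is the "pairwise association network" view of a dataset; thresholding
    it reproduces what a purely dyadic analysis would see -- and misses.
    """
    frame = data.frame if isinstance(data, DataMatrix) else data
    labels = list(frame.columns)
    if len(labels) < 2:
        raise ValueError("mi_matrix needs at least 2 columns")
    m = len(labels)
    out = np.zeros((m, m))
    singles = [_h(frame, [v], missing)[0] for v in labels]
    for i in range(m):
        for j in range(i + 1, m):
            hij, _ = _h(frame, [labels[i], labels[j]], missing)
            out[i, j] = out[j, i] = singles[i] + singles[j] - hij
    return pd.DataFrame(out, index=labels, columns=labels)
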