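"""Ordination statistics: Spearman correlation and PCA variable screening.

The screening pipeline mirrors common practice for FA ordination studies:

1. drop FAs with fewer than 14 carbons (they can arise from de-novo
   biosynthesis in the consumer and carry no dietary signal);
2. iteratively drop the worst FA whose Kaiser–Meyer–Olkin measure of
   sampling adequacy (MSA) is ≤ 0.50, recomputing after every removal;
3. drop FAs with communality ≤ 0.50 under the retained-component
   solution (components with eigenvalue > 1, the Kaiser rule).

All KMO/PCA computations work on data scaled by standard deviation
(i.e., the correlation matrix), matching the variance-homogeneity
assumption of the ordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .nomenclature import canonicalize, parse_fa_name

__all__ = ["PcaScreenReport", "PcaResult", "ScreeningError", "spearman", "kmo", "pca", "pca_screen"]


class ScreeningError(ValueError):
    """Raised when variable screening cannot proceed (degenerate input)."""


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Returns ``(r, p)`` with a two-sided p-value from the t approximation.
    Requires equal-length vectors of at least 4 points and non-constant
    input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def _corr(Z: np.ndarray) -> np.ndarray:
    return np.corrcoef(Z, rowvar=False)


def kmo(data: pd.DataFrame) -> pd.Series:
    """Per-variable Kaiser–Meyer–Olkin measure of sampling adequacy.

    ``MSA_j = Σ r²_ij / (Σ r²_ij + Σ q²_ij)`` over ``i ≠ j``, where ``r``
    are simple and ``q`` anti-image (partial) correlations derived from
    the (pseudo-)inverse of the correlation matrix.
    """
    X = data.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ScreeningError("KMO requires at least 2 variables")
    C = _corr(X)
    Cinv = np.linalg.pinv(C)
    d = np.sqrt(np.abs(np.diag(Cinv)))
    Q = -Cinv / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R = C.copy()
    np.fill_diagonal(R, 0.0)
    r2 = (R**2).sum(axis=0)
    q2 = (Q**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        msa = r2 / (r2 + q2)
    return pd.Series(np.nan_to_num(msa, nan=0.0), index=data.columns)


@dataclass
class PcaResult:
    """Correlation-matrix PCA: eigenvalues, explained %, loadings, scores.

    Loadings are component correlations (eigenvector × √eigenvalue);
    per-component signs are fixed by making the largest-magnitude loading
    positive.
    """

    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame  # entities × components


def pca(data: pd.DataFrame) -> PcaResult:
    """PCA of SD-scaled (standardized) data via the correlation matrix.

    Rank-deficient data is handled by clipping tiny negative eigenvalues
    to zero; explained percentages always sum to 100.
    """
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ScreeningError("PCA requires at least 3 entities")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [c for c, s in zip(data.columns, sd) if s == 0]
        raise ScreeningError(f"constant variables cannot be SD-scaled: {const}")
    Z = (X - X.mean(axis=0)) / sd
    C = _corr(X)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading positive per component
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    loadings = eigvec * np.sqrt(eigval)
    scores = Z @ eigvec
    comp = [f"PC{k + 1}" for k in range(len(eigval))]
    return PcaResult(
        eigenvalues=eigval,
        explained_pct=100.0 * eigval / eigval.sum(),
        loadings=pd.DataFrame(loadings, index=data.columns, columns=comp),
        scores=pd.DataFrame(scores, index=data.index, columns=comp),
    )


def _communalities(data: pd.DataFrame) -> pd.Series:
    """Communalities under the Kaiser-rule (eigenvalue > 1) solution."""
    res = pca(data)
    n_comp = max(1, int((res.eigenvalues > 1.0).sum()))
    L = res.loadings.iloc[:, :n_comp].to_numpy()
    return pd.Series((L**2).sum(axis=1), index=data.columns)


@dataclass
class PcaScreenReport:
    """Outcome of the three-stage FA variable screening."""

    removed_short_chain: list[str] = field(default_factory=list)
    removed_kmo: list[str] = field(default_factory=list)
    removed_communality: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    kmo_values: dict[str, float] = field(default_factory=dict)
    communalities: dict[str, float] = field(default_factory=dict)


def pca_screen(
    data: pd.DataFrame,
    kmo_threshold: float = 0.50,
    communality_threshold: float = 0.50,
    min_carbons: int = 14,
) -> PcaScreenReport:
    """Screen FA variables before ordination.

    Columns must be parseable FA names.  Applies, in order: the short-chain
    filter (< ``min_carbons`` carbons), iterative worst-first KMO removal
    (strictly > ``kmo_threshold`` required to stay), and a single
    communality pass (> ``communality_threshold`` required).  Raises
    :class:`ScreeningError` if fewer than 2 FAs survive at any stage.
    """
    if data.shape[0] < 3:
        raise ScreeningError("screening requires at least 3 entities")
    df = data.copy()
    df.columns = [canonicalize(c) for c in df.columns]

    report = PcaScreenReport()
    short = [c for c in df.columns if parse_fa_name(c).n_carbons < min_carbons]
    report.removed_short_chain = short
    df = df.drop(columns=short)

    # Alternate the two filters until both hold on the retained set:
    # iterative worst-first KMO removal, then a communality pass; a
    # communality removal can shift the remaining MSAs, so re-check.
    while True:
        while True:
            if df.shape[1] < 2:
                raise ScreeningError("fewer than 2 FAs survive KMO screening")
            msa = kmo(df)
            failing = msa[msa <= kmo_threshold]
            if failing.empty:
                break
            worst = failing.idxmin()
            report.removed_kmo.append(worst)
            df = df.drop(columns=[worst])
        comm = _communalities(df)
        low = [c for c in df.columns if comm[c] <= communality_threshold]
        if not low:
            break
        report.removed_communality.extend(low)
        df = df.drop(columns=low)
        if df.shape[1] < 2:
            raise ScreeningError("fewer than 2 FAs survive communality screening")
    report.kmo_values = kmo(df).to_dict()
    report.communalities = _communalities(df).to_dict()
    report.retained = list(df.columns)
    return report
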