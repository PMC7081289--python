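"""Expression-based immune measures and the feature association matrix.

Cytolytic activity (CYT) summarizes tumor-infiltrating T-cell effector
expression as the geometric mean of granzyme A (GZMA) and perforin-1
(PRF1) RPKM.  Associations between the immune measures (CYT, TIL burden,
TIL clonality), tumor mutation burden, and the immunogenicity score are
assessed by Spearman rank correlation — robust to outliers and to any
monotone normalization of the inputs — with non-significant (p > 0.05)
pairs masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Features of the standard association matrix, in display order.
DEFAULT_FEATURES = ("immunogenicity", "cyt", "tmb", "til_burden", "til_clonality")


def cyt_score(
    gzma_rpkm: float | np.ndarray,
    prf1_rpkm: float | np.ndarray,
    pseudocount: float = 0.01,
) -> float | np.ndarray:
    """Cytolytic activity: geometric mean of pseudocounted GZMA and PRF1 RPKM.

    cyt = sqrt((gzma + eps)(prf1 + eps)); the pseudocount keeps the score
    finite and positive for zero-expression samples.  Symmetric in its two
    arguments.
    """
    g = np.asarray(gzma_rpkm, dtype=float)
    p = np.asarray(prf1_rpkm, dtype=float)
    if np.any(g < 0) or np.any(p < 0):
        raise ValueError("RPKM expression must be non-negative")
    out = np.sqrt((g + pseudocount) * (p + pseudocount))
    if np.isscalar(gzma_rpkm) and np.isscalar(prf1_rpkm):
        return float(out)
    return out


@dataclass(frozen=True)
class AssociationMatrix:
    """Pairwise Spearman correlations with a significance mask.

    ``mask`` is True where the correlation is *not* significant (p > alpha)
    or undefined; rho has a unit diagonal and both matrices are symmetric.
    """

    features: tuple[str, ...]
    rho: np.ndarray
    pvalue: np.ndarray
    mask: np.ndarray
    alpha: float = 0.05

    def to_long(self) -> pd.DataFrame:
        """Long-format view (feature_a, feature_b, rho, p, significant)."""
        rows = []
        k = len(self.features)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "feature_a": self.features[i],
                        "feature_b": self.features[j],
                        "rho": self.rho[i, j],
                        "p": self.pvalue[i, j],
                        "significant": bool(~self.mask[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def association_matrix(
    features: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    adjust: Optional[str] = None,
) -> AssociationMatrix:
    """Spearman correlation matrix over per-patient features.

    Missing values (e.g. patients with undefined immunogenicity) are
    handled pairwise-complete.  Ties receive average ranks; p-values are
    two-sided.  A constant feature has no defined rank correlation: the
    pair is masked and a warning issued.  ``adjust="bh"`` applies a
    Benjamini-Hochberg correction to the off-diagonal p-values before
    masking; the default masks at raw p > alpha.
    """
    cols = tuple(columns) if columns else tuple(
        c for c in DEFAULT_FEATURES if c in features.columns
    )
    if len(cols) < 2:
        raise ValueError("need at least two features")
    data = features.loc[:, cols].astype(float)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            x = data.iloc[:, i].to_numpy()
            y = data.iloc[:, j].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3:
                raise ValueError(
                    f"fewer than 3 complete observations for "
                    f"({cols[i]}, {cols[j]})"
                )
            if np.all(x == x[0]) or np.all(y == y[0]):
                warnings.warn(
                    f"constant feature in pair ({cols[i]}, {cols[j]}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
            pairs.append((i, j))
    if adjust == "bh":
        raw = np.array([pval[i, j] for i, j in pairs])
        finite = np.isfinite(raw)
        adj = raw.copy()
        if finite.any():
            adj[finite] = stats.false_discovery_control(raw[finite], method="bh")
        for (i, j), p in zip(pairs, adj):
            pval[i, j] = pval[j, i] = p
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    with np.errstate(invalid="ignore"):
        mask = ~(pval <= alpha)
    np.fill_diagonal(mask, False)
    mask |= ~np.isfinite(rho)
    return AssociationMatrix(
        features=cols, rho=rho, pvalue=pval, mask=mask, alpha=alpha
    )
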