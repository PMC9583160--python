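"""Significance-screened Pearson correlation matrices.

Pairwise Pearson correlations between gene statistics and/or biogeochemical
covariates, with a raw two-sided p-value per pair (t-distributed with n-2
degrees of freedom under the null) and a boolean significance flag at a
configurable alpha (default 0.05). Non-significant pairs are retained in the
long output but flagged, so masked exports blank exactly the cells a
correlogram would hide. Missing values are handled pairwise-complete and the
per-pair n is reported. No multiple-testing correction is applied by default;
Benjamini-Hochberg adjustment is available behind an explicit flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS = 3


@dataclass(frozen=True)
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    p: float
    n: int
    significant: bool


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p and pair count on pairwise-complete data.

    Returns ``(nan, nan, n)`` when fewer than :data:`MIN_PAIRS` complete
    pairs remain or either vector is constant (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < MIN_PAIRS or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def correlation_matrix(
    left: pd.DataFrame,
    right: pd.DataFrame | None = None,
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise correlations between columns of two sample-indexed tables.

    Parameters
    ----------
    left, right:
        DataFrames indexed by sample_id with numeric columns (e.g. a
        richness matrix vs. an environmental covariate table). With
        ``right=None`` the upper triangle of ``left`` vs itself is computed.
    alpha:
        Significance threshold on the (possibly adjusted) p-value.
    bh_adjust:
        Apply Benjamini-Hochberg FDR adjustment before flagging. Off by
        default: the screen mirrors raw p < alpha masking.

    Returns
    -------
    Long DataFrame ``var_a, var_b, r, p, n, significant``; undefined pairs
    (constant vector, n < 3) are excluded.
    """
    symmetric = right is None
    if symmetric:
        right = left
    shared = left.index.intersection(right.index)
    if len(shared) == 0:
        raise ValueError("left and right share no samples")
    left = left.loc[shared]
    right = right.loc[shared]
    if symmetric:
        pairs = itertools.combinations_with_replacement(left.columns, 2)
    else:
        pairs = itertools.product(left.columns, right.columns)
    rows = []
    for a, b in pairs:
        r, p, n = pearson(left[a].to_numpy(), right[b].to_numpy())
        if np.isnan(r):
            continue
        rows.append((a, b, r, p, n))
    out = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "n"])
    pvals = out["p"].to_numpy()
    if bh_adjust and len(out):
        pvals = stats.false_discovery_control(pvals, method="bh")
        out["p_adj"] = pvals
    out["significant"] = pvals < alpha
    return out


def significant_r_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Wide matrix of r with non-significant cells blanked (NaN).

    The corrplot-style export: rows are ``var_a``, columns ``var_b``; the
    matrix is symmetrized when both orientations of a pair are implied.
    """
    masked = results.copy()
    masked.loc[~masked["significant"], "r"] = np.nan
    wide = masked.pivot_table(
        index="var_a", columns="var_b", values="r", dropna=False
    )
    # mirror pairs recorded in one orientation only
    common = wide.index.intersection(wide.columns)
    if len(common) == len(wide.index) == len(wide.columns):
        sym = wide.combine_first(wide.T)
        return sym.loc[wide.index, wide.index]
    return wide


def write_correlations(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
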