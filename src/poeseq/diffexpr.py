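"""Differential expression between reproductive and sterile workers.

A deliberately simple negative-binomial stage: median-of-ratios size
factors, per-gene method-of-moments dispersion, an NB log-linear model
with a log size-factor offset, and a Wald test on the reproductive-status
coefficient, BH-corrected.  Tissues are analyzed separately (pass the
per-tissue count/design subset).  There is no dispersion shrinkage,
regularized fold change or independent filtering.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .poe import bh_adjust

log = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library scale factors.

    For each library j: the median over genes of count_gj divided by the
    gene's geometric mean across libraries, computed over genes with
    strictly positive counts everywhere.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no gene has positive counts in every library; supply deeper "
            "counts or use a pseudo-reference fallback"
        )
    geo = np.exp(np.log(positive).mean(axis=1))
    return positive.div(geo, axis=0).median(axis=0).rename("size_factor")


def _mom_dispersion(y: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha from normalized counts."""
    mu = y.mean()
    if mu <= 0:
        return _MIN_ALPHA
    var = y.var(ddof=1)
    return max((var - mu) / mu**2, _MIN_ALPHA)


def de_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    covariates: Sequence[str] = ("family", "age", "weight", "direction"),
    min_total: int = 10,
    q_thresh: float = 0.01,
) -> pd.DataFrame:
    """Per-gene NB Wald test of reproductive vs sterile status.

    ``counts`` is genes x libraries (columns must match
    ``design['library_id']``).  Genes with total count below ``min_total``
    are removed before testing.  The status coefficient is reported as a
    log2 fold change of reproductive over sterile.  Returns a DataFrame
    with ``gene_id, log2_fold_change, p, q, direction_of_change,
    significant``.
    """
    design = design.set_index("library_id").loc[counts.columns].reset_index()
    sf = size_factors(counts)
    offset = np.log(sf.loc[counts.columns].to_numpy())

    cols = [np.ones(len(design))]
    names = ["intercept"]
    status_num = (design["status"] == "reproductive").astype(float).to_numpy()
    cols.append(status_num)
    names.append("status[reproductive]")
    for cov in covariates:
        vals = design[cov]
        if vals.dtype.kind in "if":
            cols.append(vals.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(vals.unique())
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float).to_numpy())
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; aliased covariates among {names}")

    keep = counts.sum(axis=1) >= min_total
    records = []
    for gene_id, row in counts[keep].iterrows():
        y = row.to_numpy(dtype=float)
        alpha = _mom_dispersion(y / sf.to_numpy())
        try:
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
        except Exception as exc:  # noqa: BLE001 - per-gene fits may fail
            log.warning("DE fit failed for gene %s: %s", gene_id, exc)
            continue
        beta = float(res.params[1])
        se = float(res.bse[1])
        if se == 0 or not np.isfinite(se):
            continue
        z = beta / se
        p = 2 * norm.sf(abs(z))
        records.append(
            {
                "gene_id": gene_id,
                "log2_fold_change": beta / np.log(2),
                "p": p,
            }
        )
    out = pd.DataFrame(records)
    if out.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "log2_fold_change", "p", "q",
                "direction_of_change", "significant",
            ]
        )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction_of_change"] = np.where(
        out["log2_fold_change"] > 0, "up_reproductive", "up_sterile"
    )
    out["significant"] = out["q"] < q_thresh
    return out.reset_index(drop=True)
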