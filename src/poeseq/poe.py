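"""Per-gene parent-of-origin inference.

For every gene in the analyzed universe the maternal/paternal read totals
across libraries are modeled with a quasibinomial logistic regression:
a binomial GLM (logit link) whose variance is inflated by a Pearson
overdispersion factor.  Design factors (cross direction, family and —
in the joint mode — reproductive status) enter with sum-to-zero (effects)
coding, so the intercept is the grand-mean logit of the maternal
proportion and its test asks whether the allelic ratio deviates from 0.5.
The intercept p-value uses a t reference on the residual degrees of
freedom with the dispersion-scaled standard error, the standard
quasi-likelihood practice at small sample sizes.

Significant genes (Benjamini-Hochberg q < 0.05) are classified with the
conservative proportion rule: per-library maternal proportions are
averaged hierarchically (tissue, then worker type, then colony, then the
grand mean over the four family x direction colonies) and a gene is called
MATERNAL only if that mean exceeds 0.6 with every colony on the maternal
side of 0.5 (mirrored for PATERNAL at 0.4); a significant gene whose bias
follows the subspecies lineage — the maternal proportion flips across
cross directions — receives a LINEAGE label instead, and everything else
is BIALLELIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .simulate import DIRECTION_MATERNAL_LINEAGE

log = logging.getLogger(__name__)

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"
LINEAGE_A = "LINEAGE_A"
LINEAGE_B = "LINEAGE_B"
BIALLELIC = "BIALLELIC"

_EPS_SCALE = 1e-10


@dataclass
class GeneFit:
    """Quasibinomial fit summary for one gene."""

    beta: np.ndarray  # coefficients, intercept first
    se: np.ndarray  # dispersion-scaled standard errors
    dispersion: float  # Pearson chi-squared / residual df
    p_intercept: float  # two-sided t test of beta0 = 0
    df_resid: int
    converged: bool


def effects_design_matrix(
    design: pd.DataFrame, factors: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    """Sum-to-zero coded design matrix with an intercept column.

    For a factor with levels l1 < ... < lk (sorted), columns are the
    indicators of l1..l(k-1) minus the indicator of lk, so each factor's
    effects sum to zero and the intercept is the grand mean across levels.
    """
    cols = [np.ones(len(design))]
    names = ["intercept"]
    for f in factors:
        levels = sorted(design[f].unique())
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels in this subset")
        last = design[f] == levels[-1]
        for lev in levels[:-1]:
            col = (design[f] == lev).astype(float) - last.astype(float)
            cols.append(col.to_numpy())
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


def fit_gene(
    maternal: np.ndarray,
    paternal: np.ndarray,
    design: pd.DataFrame,
    factors: Sequence[str] = ("direction", "family"),
) -> GeneFit:
    """Fit the quasibinomial logistic regression for one gene.

    ``maternal``/``paternal`` are per-library totals aligned with
    ``design`` rows.  Dispersion is the Pearson statistic over residual
    degrees of freedom, used as estimated (no floor); the intercept test is
    two-sided t on ``df_resid`` degrees of freedom.
    """
    maternal = np.asarray(maternal, dtype=float)
    paternal = np.asarray(paternal, dtype=float)
    if len(maternal) != len(design) or len(paternal) != len(design):
        raise ValueError("count vectors must align with design rows")
    positive = (maternal + paternal) > 0
    if positive.sum() < 2:
        raise ValueError("need at least 2 libraries with positive totals")
    X, names = effects_design_matrix(design, factors)
    df_resid = int(positive.sum()) - X.shape[1]
    if df_resid <= 0:
        raise ValueError(
            f"saturated design: {int(positive.sum())} libraries for "
            f"{X.shape[1]} coefficients"
        )
    endog = np.column_stack([maternal[positive], paternal[positive]])
    model = sm.GLM(endog, X[positive], family=sm.families.Binomial())
    with warnings.catch_warnings():
        # exactly balanced genes trigger a spurious separation warning
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit()
    dispersion = float(res.pearson_chi2) / df_resid
    if dispersion < _EPS_SCALE:
        # perfect fit: zero Pearson residuals give a zero standard error;
        # a zero intercept then means exactly balanced data (p = 1)
        p0 = 1.0 if abs(res.params[0]) < 1e-8 else 0.0
        se = np.zeros_like(np.asarray(res.params))
    else:
        se = np.asarray(res.bse, dtype=float) * np.sqrt(dispersion)
        tstat = float(res.params[0]) / se[0]
        p0 = float(2 * t_dist.sf(abs(tstat), df_resid))
    return GeneFit(
        beta=np.asarray(res.params, dtype=float),
        se=se,
        dispersion=dispersion,
        p_intercept=p0,
        df_resid=df_resid,
        converged=bool(res.converged),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def conservative_proportion(
    gene_rows: pd.DataFrame, design: pd.DataFrame
) -> Tuple[float, Dict[str, float], Dict[str, float]]:
    """Hierarchically averaged maternal expression proportion.

    Per-library proportions are averaged tissue -> worker type -> colony,
    then the grand mean weights the four family x direction colonies
    equally; this deliberately discards library-size information so no
    single deep library can dominate.  Returns ``(grand_mean, per_colony,
    per_direction)``; raises if any colony of the design subset has no data
    for the gene.
    """
    meta = design.set_index("library_id")[
        ["colony", "family", "direction", "tissue", "worker_type"]
    ]
    d = gene_rows.join(meta, on="library_id")
    d = d[(d["maternal"] + d["paternal"]) > 0].copy()
    d["prop"] = d["maternal"] / (d["maternal"] + d["paternal"])
    for colony in design["colony"].unique():
        if not (d["colony"] == colony).any():
            raise ValueError(f"no allelic data for colony {colony!r}")
    tiss = d.groupby(["colony", "worker_type", "tissue"])["prop"].mean()
    wtype = tiss.groupby(["colony", "worker_type"]).mean()
    colony_mean = wtype.groupby("colony").mean()
    per_colony = colony_mean.to_dict()
    dir_of_colony = design.drop_duplicates("colony").set_index("colony")["direction"]
    per_direction = (
        colony_mean.groupby(dir_of_colony.reindex(colony_mean.index)).mean().to_dict()
    )
    return float(colony_mean.mean()), per_colony, per_direction


def classify_gene(
    q: float,
    mean_prop: float,
    per_colony: Dict[str, float],
    per_direction: Dict[str, float],
    q_thresh: float = 0.05,
    prop_hi: float = 0.6,
    prop_lo: float = 0.4,
) -> str:
    """Label a gene from its q-value and averaged proportions.

    MATERNAL/PATERNAL require significance, the conservative mean beyond
    the proportion gate, and every colony on the same side of 0.5 (the
    same-direction-in-every-cross consistency rule).  If instead the bias
    tracks the subspecies lineage — after recoding each direction's
    proportion to the lineage-A allele, both directions sit beyond the gate
    on the same side — the gene is lineage-biased, never a parent-of-origin
    call.
    """
    colony_props = np.array(list(per_colony.values()))
    if q < q_thresh:
        if mean_prop > prop_hi and np.all(colony_props > 0.5):
            return MATERNAL
        if mean_prop < prop_lo and np.all(colony_props < 0.5):
            return PATERNAL
        if len(per_direction) == 2:
            lineage_a_prop = {
                d: (p if DIRECTION_MATERNAL_LINEAGE[d] == "A" else 1 - p)
                for d, p in per_direction.items()
            }
            vals = np.array(list(lineage_a_prop.values()))
            if np.all(vals > prop_hi):
                return LINEAGE_A
            if np.all(vals < prop_lo):
                return LINEAGE_B
    return BIALLELIC


def run_poe(
    gene_table: pd.DataFrame,
    design: pd.DataFrame,
    status: str = "reproductive",
    q_thresh: float = 0.05,
    prop_hi: float = 0.6,
    prop_lo: float = 0.4,
    factors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit, adjust and classify every gene of a gene-level count table.

    ``status`` selects the analyzed libraries: ``"reproductive"`` or
    ``"sterile"`` fit per-status models with direction and family as
    covariates (the default analysis); ``"both"`` fits one joint model per
    gene with reproductive status as an additional factor.  BH adjustment
    is applied across the genes actually fitted within this analysis.

    Returns one row per gene: intercept/coefficients, Pearson dispersion,
    p and q for the intercept, the conservative mean proportion, per-colony
    and per-direction proportions, and the class label.
    """
    if status not in ("reproductive", "sterile", "both"):
        raise ValueError(f"invalid status {status!r}")
    if factors is None:
        factors = ("direction", "family") if status != "both" else (
            "direction",
            "family",
            "status",
        )
    sub_design = design if status == "both" else design[design["status"] == status]
    sub_design = sub_design.reset_index(drop=True)
    lib_set = set(sub_design["library_id"])
    tab = gene_table[gene_table["library_id"].isin(lib_set)]

    lib_index = pd.Series(np.arange(len(sub_design)), index=sub_design["library_id"])
    records = []
    for gene_id, rows in tab.groupby("gene_id"):
        m = np.zeros(len(sub_design))
        p = np.zeros(len(sub_design))
        idx = lib_index[rows["library_id"]].to_numpy()
        m[idx] = rows["maternal"].to_numpy()
        p[idx] = rows["paternal"].to_numpy()
        try:
            fit = fit_gene(m, p, sub_design, factors)
        except ValueError as exc:
            log.warning("gene %s skipped: %s", gene_id, exc)
            continue
        if not fit.converged:
            log.warning("gene %s skipped: IRLS did not converge", gene_id)
            continue
        mean_prop, per_colony, per_direction = conservative_proportion(
            rows[["library_id", "maternal", "paternal"]], sub_design
        )
        records.append(
            {
                "gene_id": gene_id,
                "beta0": float(fit.beta[0]),
                "dispersion": fit.dispersion,
                "p": fit.p_intercept,
                "mean_maternal_prop": mean_prop,
                "percolony": per_colony,
                "perdirection": per_direction,
            }
        )
    if not records:
        return pd.DataFrame(
            columns=[
                "gene_id", "beta0", "dispersion", "p", "q",
                "mean_maternal_prop", "label",
            ]
        )
    out = pd.DataFrame(records)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["label"] = [
        classify_gene(
            r.q, r.mean_maternal_prop, r.percolony, r.perdirection,
            q_thresh, prop_hi, prop_lo,
        )
        for r in out.itertuples()
    ]
    for colony in sub_design["colony"].unique():
        out[f"prop_{colony}"] = out["percolony"].map(lambda d: d.get(colony, np.nan))
    for direction in sub_design["direction"].unique():
        out[f"prop_dir_{direction}"] = out["perdirection"].map(
            lambda d: d.get(direction, np.nan)
        )
    out = out.drop(columns=["percolony", "perdirection"])
    return out.sort_values("gene_id").reset_index(drop=True)
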