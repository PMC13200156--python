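"""Symptom-severity (craving) correlations with regional volumes in cases.

Within the case group, each region's gray-matter volume is correlated with
the continuous craving score; Bonferroni correction over the tested family
controls the family-wise error rate.  By default the family is all N
regions (the most conservative choice); a subcortical-only family or an
explicit region subset can be requested, as can Spearman correlation or a
TIV-partialled variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .contrast import GMVTable


def _residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


class CravingCorrelation(BaseEstimator):
    """Region-wise craving-volume correlations with Bonferroni control.

    Parameters
    ----------
    method : {"pearson", "spearman"}
    alpha : float
        Family-wise significance level applied to Bonferroni-adjusted p.
    family : {"all", "subcortical"}
        Which regions form the correction family when no explicit subset
        is passed to :meth:`fit`.
    control_tiv : bool
        If True, partial out TIV from both craving and volumes before
        correlating (off by default).

    Fitted attributes
    -----------------
    results_ : pandas.DataFrame with columns region, r, p_raw, p_bonf,
        significant — sorted by r descending.
    n_tested_ : int
    """

    def __init__(
        self,
        method: str = "pearson",
        alpha: float = 0.05,
        family: str = "all",
        control_tiv: bool = False,
    ):
        self.method = method
        self.alpha = alpha
        self.family = family
        self.control_tiv = control_tiv

    def fit(self, table: GMVTable, regions=None, tiers=None) -> "CravingCorrelation":
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown method {self.method!r}")
        if table.craving is None:
            raise ValueError("cohort table has no craving scores")
        mask = table.group == "case"
        craving = table.craving[mask]
        missing = np.flatnonzero(~np.isfinite(craving))
        if missing.size:
            ids = [table.subject_ids[i] for i in np.flatnonzero(mask)[missing]]
            raise ValueError(f"missing craving scores for subjects {ids}")
        if craving.size < 4:
            raise ValueError("need >=4 case subjects with craving scores")
        if np.ptp(craving) == 0:
            raise ValueError("craving score is constant across cases")

        if regions is None:
            if self.family == "subcortical":
                if tiers is None:
                    raise ValueError("family='subcortical' requires region tiers")
                regions = np.flatnonzero(np.asarray(tiers) == "subcortical")
            else:
                regions = np.arange(table.n_regions)
        regions = np.asarray(regions, dtype=int)

        vols = table.values[mask][:, regions]
        score = craving
        if self.control_tiv:
            tiv = table.tiv[mask]
            vols = _residualize(vols, tiv)
            score = _residualize(score, tiv)

        corr = stats.pearsonr if self.method == "pearson" else stats.spearmanr
        r = np.empty(regions.size)
        p = np.empty(regions.size)
        for k in range(regions.size):
            if np.ptp(vols[:, k]) == 0:
                r[k], p[k] = 0.0, 1.0
                continue
            res = corr(score, vols[:, k])
            r[k], p[k] = res.statistic, res.pvalue
        p_bonf = multipletests(p, method="bonferroni")[1]
        names = [table.region_ids[i] for i in regions]
        df = pd.DataFrame(
            {
                "region": names,
                "region_index": regions,
                "r": r,
                "p_raw": p,
                "p_bonf": p_bonf,
                "significant": p_bonf < self.alpha,
            }
        ).sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
        self.results_ = df
        self.n_tested_ = int(regions.size)
        return self


def craving_correlations(
    table: GMVTable,
    regions=None,
    alpha: float = 0.05,
    method: str = "pearson",
    control_tiv: bool = False,
    tiers=None,
    family: str = "all",
) -> pd.DataFrame:
    """Functional wrapper over :class:`CravingCorrelation`."""
    est = CravingCorrelation(
        method=method, alpha=alpha, family=family, control_tiv=control_tiv
    )
    return est.fit(table, regions=regions, tiers=tiers).results_
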