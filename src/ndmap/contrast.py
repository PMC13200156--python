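"""Regional group contrast: per-region GLM with TIV covariate, FDR, rectification.

For each atlas region independently an ordinary-least-squares model

    volume ~ intercept + group_indicator + TIV

is fit across subjects; the group coefficient, its t-statistic and
two-sided p quantify the case-control volume difference while total
intracranial volume absorbs head-size differences.  Under the default
"loss-positive" convention the indicator codes controls as 1, so a
positive coefficient/t means LOWER volume in cases (atrophy) and a
negative one means expansion.  Rectifying the t-map at zero then yields
the atrophy pattern (max(t, 0)) or the expansion pattern (max(-t, 0))
fed to the diffusion model.

Because every region shares the same design matrix, the whole contrast is
one QR factorization plus matrix products; statsmodels is the natural
cross-check for any single region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

GROUP_LABELS = ("case", "control")

#: residual-variance floor, relative to the squared data scale.  An exact
#: linear fit (e.g. noise-free simulated volumes) leaves only rounding
#: error in the residuals; flooring the variance at (1e-8 * scale)^2 keeps
#: t finite and — since the floor is common to all regions sharing one
#: design — proportional to the coefficient, preserving the pattern's ranks.
_VAR_FLOOR_REL = 1e-8


@dataclass
class GMVTable:
    """Subject-by-region gray-matter-volume table with per-subject metadata.

    ``values`` is S x N (volume units); ``group`` holds "case"/"control";
    ``tiv`` is total intracranial volume; ``craving`` (optional) a
    continuous symptom-severity score, NaN where not collected.
    """

    values: np.ndarray
    subject_ids: list[str]
    group: np.ndarray
    tiv: np.ndarray
    region_ids: list[str]
    craving: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group)
        self.tiv = np.asarray(self.tiv, dtype=float)
        s, n = self.values.shape
        if len(self.subject_ids) != s or self.group.shape != (s,) or self.tiv.shape != (s,):
            raise ValueError("subject metadata length does not match values rows")
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match values columns")
        unknown = set(np.unique(self.group)) - set(GROUP_LABELS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        for g in GROUP_LABELS:
            if not np.any(self.group == g):
                raise ValueError(f"group '{g}' is empty")
        if np.any(self.tiv <= 0):
            raise ValueError("tiv must be strictly positive")
        if self.craving is not None:
            self.craving = np.asarray(self.craving, dtype=float)
            if self.craving.shape != (s,):
                raise ValueError("craving length does not match values rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"subject_id": self.subject_ids, "group": self.group, "tiv": self.tiv}
        )
        if self.craving is not None:
            df["craving"] = self.craving
        df = pd.concat(
            [df, pd.DataFrame(self.values, columns=self.region_ids)], axis=1
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, region_ids: list[str] | None = None) -> "GMVTable":
        df = pd.read_csv(path)
        meta_cols = ["subject_id", "group", "tiv"]
        craving = None
        if "craving" in df.columns:
            meta_cols.append("craving")
            craving = df["craving"].to_numpy(dtype=float)
        regions = [c for c in df.columns if c not in meta_cols]
        if region_ids is not None:
            missing = [r for r in region_ids if r not in regions]
            if missing:
                raise ValueError(f"cohort table missing region columns {missing}")
            regions = list(region_ids)
        return cls(
            values=df[regions].to_numpy(dtype=float),
            subject_ids=df["subject_id"].astype(str).tolist(),
            group=df["group"].to_numpy(),
            tiv=df["tiv"].to_numpy(dtype=float),
            region_ids=regions,
            craving=craving,
        )


@dataclass
class RegionalContrast:
    """Per-region group-difference statistics under a stated sign convention."""

    estimate: np.ndarray
    tvalue: np.ndarray
    pvalue: np.ndarray
    p_fdr: np.ndarray
    direction_convention: str
    region_ids: list[str] = field(default_factory=list)
    df_resid: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids or np.arange(len(self.estimate)),
                "estimate": self.estimate,
                "tvalue": self.tvalue,
                "pvalue": self.pvalue,
                "p_fdr": self.p_fdr,
                "direction": self.direction_convention,
            }
        )


class RegionalGLM(BaseEstimator):
    """Mass-univariate group contrast with TIV as nuisance covariate.

    Parameters
    ----------
    direction : {"loss_positive", "gain_positive"}
        "loss_positive" (default) codes the indicator so that a positive
        group coefficient means lower volume in cases.

    Fitted attributes
    -----------------
    estimate_, tvalue_, pvalue_, p_fdr_ : (N,) ndarrays
    df_resid_ : int
    contrast_ : RegionalContrast
    """

    def __init__(self, direction: str = "loss_positive"):
        self.direction = direction

    def fit(self, table: GMVTable, y=None) -> "RegionalGLM":
        if self.direction not in ("loss_positive", "gain_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")
        y_mat = table.values
        s, n = y_mat.shape
        for g in GROUP_LABELS:
            if (table.group == g).sum() < 3:
                raise ValueError(f"need >=3 subjects per group; '{g}' has fewer")
        # control=1 under loss_positive: coefficient = control minus case
        indicator = (table.group == "control").astype(float)
        if self.direction == "gain_positive":
            indicator = 1.0 - indicator
        tiv_c = table.tiv - table.tiv.mean()  # centering for conditioning only
        x = np.column_stack([np.ones(s), indicator, tiv_c])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(
                "design matrix is rank deficient (group/TIV collinear or constant)"
            )
        q, r = np.linalg.qr(x)
        beta = np.linalg.solve(r, q.T @ y_mat)  # 3 x N
        resid = y_mat - x @ beta
        dof = s - x.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        scale = np.abs(y_mat).max() or 1.0
        sigma2 = np.maximum(sigma2, (_VAR_FLOOR_REL * scale) ** 2)
        xtx_inv = np.linalg.inv(r.T @ r)
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        tval = beta[1] / se
        pval = 2.0 * stats.t.sf(np.abs(tval), dof)

        constant = np.ptp(y_mat, axis=0) == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} region(s) have constant volumes; "
                "t set to 0, p to 1",
                stacklevel=2,
            )
            tval = np.where(constant, 0.0, tval)
            pval = np.where(constant, 1.0, pval)
            beta[1] = np.where(constant, 0.0, beta[1])

        self.estimate_ = beta[1]
        self.tvalue_ = tval
        self.pvalue_ = pval
        self.p_fdr_ = fdr_correct(pval)
        self.df_resid_ = dof
        self.contrast_ = RegionalContrast(
            estimate=self.estimate_,
            tvalue=self.tvalue_,
            pvalue=self.pvalue_,
            p_fdr=self.p_fdr_,
            direction_convention=self.direction,
            region_ids=list(table.region_ids),
            df_resid=dof,
        )
        return self


def fit_regional_glm(table: GMVTable, direction: str = "loss_positive") -> RegionalContrast:
    """Fit ``volume ~ 1 + group + TIV`` per region; see :class:`RegionalGLM`."""
    return RegionalGLM(direction=direction).fit(table).contrast_


def fdr_correct(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    bad = np.flatnonzero(~np.isfinite(p))
    if bad.size:
        raise ValueError(f"non-finite p-value at index {bad[0]}")
    if np.any((p < 0) | (p > 1)):
        i = int(np.flatnonzero((p < 0) | (p > 1))[0])
        raise ValueError(f"p-value out of [0, 1] at index {i}")
    return multipletests(p, method="fdr_bh")[1]


def rectify_contrast(
    rc: RegionalContrast, mode: str, statistic: str = "tvalue"
) -> np.ndarray:
    """Half-wave rectify the contrast into an atrophy or expansion pattern.

    Under the loss-positive convention, ``mode="atrophy"`` keeps positive
    values (volume loss) and ``mode="expansion"`` keeps sign-flipped
    negative values, so atrophy + expansion = |statistic| elementwise.
    ``statistic`` selects the t-map (default) or the raw coefficient map.
    """
    if mode not in ("atrophy", "expansion"):
        raise ValueError(f"mode must be 'atrophy' or 'expansion', got {mode!r}")
    if statistic not in ("tvalue", "estimate"):
        raise ValueError(f"statistic must be 'tvalue' or 'estimate', got {statistic!r}")
    vec = rc.tvalue if statistic == "tvalue" else rc.estimate
    out = np.maximum(vec, 0.0) if mode == "atrophy" else np.maximum(-vec, 0.0)
    if not np.any(out > 0):
        raise ValueError(f"no signal in requested direction '{mode}'")
    return out
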