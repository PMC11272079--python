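"""Phylogenetic generalized least squares of a tip phenotype on dN/dS.

The regression y = a + b*omega is fitted across the tips of a phylogeny
with error covariance proportional to the Brownian-motion (BM) matrix V,
whose (i, j) entry is the shared root-to-MRCA path length of tips i and
j.  The slope's two-sided P comes from a t test at n - 2 df.  With five
species the fit has 3 residual df, so only strong relationships reach
P < 0.05.

Sentinel branch estimates are imputed before fitting: ``>1`` (GT1)
records enter as omega = 1.5 and ``-`` (LOWDIV) records as omega = 0.
Genes with two or more GT1 branches are considered untestable (the ratio
is formally infinite on several branches) and should be excluded; the
threshold is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ratetable import BranchRateRecord, OmegaCode
from .trees import PhyloTree

logger = logging.getLogger("ovorate")

__all__ = [
    "bm_covariance",
    "impute_sentinels",
    "is_testable",
    "PGLS",
    "PGLSResults",
    "reproduce_published_predictions",
]

GT1_IMPUTED_OMEGA = 1.5
LOWDIV_IMPUTED_OMEGA = 0.0


def bm_covariance(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance: entry (i, j) is the root-to-MRCA
    path length.  The tree is used as rooted at its seed node."""
    tips, depths = tree.mrca_depths()
    n = len(tips)
    v = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            v[i, j] = depths[(a, b)]
    return tips, v


def impute_sentinels(
    records: "list[BranchRateRecord]",
    tips: "list[str] | None" = None,
    gt1_value: float = GT1_IMPUTED_OMEGA,
    lowdiv_value: float = LOWDIV_IMPUTED_OMEGA,
) -> dict[str, float]:
    """Numeric omega per tip: GT1 -> gt1_value, LOWDIV -> lowdiv_value."""
    by_branch = {r.branch: r for r in records}
    tips = tips if tips is not None else list(by_branch)
    out = {}
    for tip in tips:
        if tip not in by_branch:
            raise KeyError(f"no rate record for tip {tip!r}")
        r = by_branch[tip]
        if r.code is OmegaCode.GT1:
            out[tip] = gt1_value
            logger.info("imputing omega=%g for GT1 sentinel on %s", gt1_value, tip)
        elif r.code is OmegaCode.LOWDIV:
            out[tip] = lowdiv_value
            logger.info("imputing omega=%g for LOWDIV sentinel on %s", lowdiv_value, tip)
        else:
            out[tip] = float(r.omega)
    return out


def is_testable(records: "list[BranchRateRecord]", max_gt1: int = 1) -> bool:
    """A gene with more than ``max_gt1`` GT1 branches is untestable by PGLS
    (its ratio is formally infinite on several branches)."""
    return sum(r.code is OmegaCode.GT1 for r in records) <= max_gt1


@dataclass
class PGLSResults:
    """Fitted PGLS regression."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    slope_t: float
    slope_p: float
    df_resid: int
    tips: list[str]
    vcv: np.ndarray = field(repr=False)
    sigma2: float = 0.0
    loglik: float = 0.0

    def predict(self, x) -> np.ndarray:
        """yhat = intercept + slope * x (x scalar or array-like)."""
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def predict_rounded(self, x, decimals: int = 2) -> np.ndarray:
        return np.round(self.predict(x), decimals)

    def summary(self) -> str:
        return "\n".join(
            [
                "PGLS (Brownian-motion covariance)",
                "=" * 46,
                f"n tips = {len(self.tips)}    residual df = {self.df_resid}",
                f"intercept = {self.intercept:10.4f}  (SE {self.intercept_se:.4f})",
                f"slope     = {self.slope:10.4f}  (SE {self.slope_se:.4f})",
                f"slope t   = {self.slope_t:10.4f}   two-sided P = {self.slope_p:.4g}",
            ]
        )


class PGLS:
    """GLS regression of tip phenotypes on a tip covariate under BM.

    Parameters
    ----------
    y : mapping or Series
        Phenotype per tip (e.g. ovariole number per female).
    x : mapping or Series
        Covariate per tip (per-branch dN/dS, sentinels already imputed).
    tree : PhyloTree, optional
        Source of the BM covariance; alternatively pass ``vcv`` directly.
    """

    def __init__(self, y, x, tree: PhyloTree | None = None, vcv=None, tips=None):
        if tree is not None:
            tips, v = bm_covariance(tree)
        elif vcv is not None:
            v = np.asarray(vcv, dtype=float)
            if tips is None:
                raise ValueError("tips must accompany an explicit vcv")
        else:
            raise ValueError("provide a tree or an explicit vcv")
        if len(tips) < 3:
            raise ValueError("PGLS needs at least 3 tips")
        y = pd.Series(y)
        x = pd.Series(x)
        missing = set(tips) - set(y.index) | (set(tips) - set(x.index))
        if missing:
            raise KeyError(f"missing data for tips: {sorted(missing)}")
        self.tips = list(tips)
        self.y = y.loc[self.tips].to_numpy(dtype=float)
        self.x = x.loc[self.tips].to_numpy(dtype=float)
        self.vcv = v

    @classmethod
    def from_gene(
        cls,
        records: "list[BranchRateRecord]",
        phenotypes,
        tree: PhyloTree,
        gt1_value: float = GT1_IMPUTED_OMEGA,
        lowdiv_value: float = LOWDIV_IMPUTED_OMEGA,
    ) -> "PGLS":
        tips, _ = bm_covariance(tree)
        x = impute_sentinels(records, tips, gt1_value, lowdiv_value)
        return cls(phenotypes, x, tree=tree)

    def fit(self) -> PGLSResults:
        design = sm.add_constant(self.x)
        model = sm.GLS(self.y, design, sigma=self.vcv)
        res = model.fit()
        return PGLSResults(
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            intercept_se=float(res.bse[0]),
            slope_se=float(res.bse[1]),
            slope_t=float(res.tvalues[1]),
            slope_p=float(res.pvalues[1]),
            df_resid=int(res.df_resid),
            tips=self.tips,
            vcv=self.vcv,
            sigma2=float(res.scale),
            loglik=float(res.llf),
        )


def reproduce_published_predictions(
    gt1_value: float = GT1_IMPUTED_OMEGA,
    lowdiv_value: float = LOWDIV_IMPUTED_OMEGA,
) -> pd.DataFrame:
    """Recompute every published per-species PGLS prediction.

    For each regression row (intercept, slope) the per-species prediction
    is intercept + slope * omega with sentinel imputation applied to the
    published branch omega tokens.  Returns a tidy frame with computed and
    published predictions per gene and species.
    """
    from . import datasets

    omega = datasets.branch_omega_published().set_index("gene_id")
    pgls = datasets.pgls_published()
    rows = []
    for row in pgls.itertuples():
        gene = row.gene_id
        for sp in datasets.SPECIES:
            token = str(omega.loc[gene, sp])
            if token == ">1":
                w = gt1_value
            elif token == "-":
                w = lowdiv_value
            else:
                w = float(token)
            computed = row.intercept + row.slope * w
            published = float(getattr(row, f"pred_{sp}"))
            rows.append(
                {
                    "gene_id": gene,
                    "symbol": row.symbol,
                    "species": sp,
                    "omega": w,
                    "computed": computed,
                    "computed_rounded": round(computed, 2),
                    "published": published,
                }
            )
    return pd.DataFrame(rows)
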