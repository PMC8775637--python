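"""Posterior summaries in the field's reporting conventions.

Coefficient tables report posterior mean, posterior SD, equal-tailed
2.5%/97.5% bounds and the odds ratio exp(mean); random coefficients
additionally report the posterior summary of their mixing-distribution SD
and the heterogeneity split Phi(mu/sigma) / 1 - Phi(mu/sigma): the fraction
of the rider population whose coefficient is positive (respectively
negative) under the normal mixing distribution.  Model pairs are compared
on DIC with the conventional "difference greater than 10 excludes the
higher-DIC model" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import DICResult, PosteriorDraws

__all__ = [
    "odds_ratio",
    "heterogeneity_share",
    "summarize",
    "ModelComparison",
    "compare_models",
    "DIC_EXCLUSION_MARGIN",
]

#: DIC difference beyond which the higher-DIC model may be excluded.
DIC_EXCLUSION_MARGIN = 10.0


def odds_ratio(coef_mean: float) -> float:
    """exp(mean): multiplicative change in occupancy odds per contrast."""
    if not math.isfinite(coef_mean):
        raise ValueError("coefficient must be finite")
    return math.exp(coef_mean)


def heterogeneity_share(mu: float, sigma: float) -> tuple[float, float]:
    """(positive, negative) population shares under a N(mu, sigma^2) coefficient.

    Phi(mu/sigma) is the fraction of riders for whom the contrast raises the
    occupancy odds; the complement is the fraction for whom it lowers them.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pos = float(norm.cdf(mu / sigma))
    return pos, 1.0 - pos


def summarize(draws: PosteriorDraws, share_from_draws: bool = False) -> pd.DataFrame:
    """Pooled posterior summary table, one row per coefficient.

    Columns: ``mean``, ``sd``, ``q2.5``, ``q97.5``, ``odds_ratio``; for
    random coefficients also the mixing-SD summary (``sigma_mean`` etc.) and
    the heterogeneity shares.  Shares default to the plug-in arithmetic
    Phi(mean / sigma_mean), matching the published tables; with
    ``share_from_draws=True`` the posterior mean of Phi(mu/sigma) across
    draws is used instead.
    """
    if draws.n_draws == 0:
        raise ValueError("no post-burn-in draws to summarize")
    mu = draws.mu_pooled()
    sd_draws = draws.sd_pooled()
    rows = []
    for j, label in enumerate(draws.columns):
        col = mu[:, j]
        row = {
            "parameter": label,
            "random": label in draws.random_set,
            "mean": col.mean(),
            "sd": col.std(ddof=1) if len(col) > 1 else 0.0,
            "q2.5": np.quantile(col, 0.025),
            "q97.5": np.quantile(col, 0.975),
            "odds_ratio": math.exp(col.mean()) if label != "intercept" else np.nan,
            "sigma_mean": np.nan,
            "sigma_sd": np.nan,
            "sigma_q2.5": np.nan,
            "sigma_q97.5": np.nan,
            "share_positive": np.nan,
            "share_negative": np.nan,
        }
        if label in draws.random_set:
            r = draws.random_set.index(label)
            s = sd_draws[:, r]
            row["sigma_mean"] = s.mean()
            row["sigma_sd"] = s.std(ddof=1) if len(s) > 1 else 0.0
            row["sigma_q2.5"] = np.quantile(s, 0.025)
            row["sigma_q97.5"] = np.quantile(s, 0.975)
            if share_from_draws:
                pos = float(np.mean(norm.cdf(col / s)))
            else:
                pos, _ = heterogeneity_share(row["mean"], row["sigma_mean"])
            row["share_positive"] = pos
            row["share_negative"] = 1.0 - pos
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelComparison:
    dic_a: DICResult
    dic_b: DICResult
    label_a: str = "model A"
    label_b: str = "model B"

    @property
    def difference(self) -> float:
        return abs(self.dic_a.dic - self.dic_b.dic)

    @property
    def preferred(self) -> str | None:
        if self.difference > DIC_EXCLUSION_MARGIN:
            return self.label_a if self.dic_a.dic < self.dic_b.dic else self.label_b
        return None

    @property
    def verdict(self) -> str:
        if self.preferred is None:
            return "no exclusion"
        loser = self.label_b if self.preferred == self.label_a else self.label_a
        return f"exclude higher-DIC model: {loser}"

    def to_dict(self) -> dict:
        return {
            self.label_a: {"dbar": self.dic_a.dbar, "pD": self.dic_a.pd, "DIC": self.dic_a.dic},
            self.label_b: {"dbar": self.dic_b.dbar, "pD": self.dic_b.pd, "DIC": self.dic_b.dic},
            "difference": self.difference,
            "verdict": self.verdict,
        }


def compare_models(
    a: DICResult, b: DICResult, label_a: str = "model A", label_b: str = "model B"
) -> ModelComparison:
    """DIC comparison with the strict difference-greater-than-10 rule.

    Both results must come from the same dataset; fingerprints are checked
    when present.
    """
    if a.fingerprint and b.fingerprint and a.fingerprint != b.fingerprint:
        raise ValueError("DIC results were computed on different datasets")
    return ModelComparison(dic_a=a, dic_b=b, label_a=label_a, label_b=label_b)
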