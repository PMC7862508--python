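"""Fixed-effect inverse-variance meta-analysis of per-cohort estimates.

Pooling happens on the coefficient scale (log-odds for logistic models);
odds ratios appear only in presentation tables. Cochran's Q and I2 are
computed as standard quality diagnostics even though they are not part of
the headline output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import AssocResult
from .errors import ValidationError


@dataclass
class MetaResult:
    """Inverse-variance pooled estimate with per-cohort weights.

    ``per_cohort`` columns: cohort, beta, se, weight_pct (weights sum to
    100). Heterogeneity: Cochran Q with df = k-1, its p-value, and
    I2 = max(0, (Q - df)/Q) * 100.
    """

    outcome: str
    model: str
    k: int
    beta_pooled: float
    se_pooled: float
    pvalue: float
    per_cohort: pd.DataFrame
    Q: float
    df: int
    p_Q: float
    I2_pct: float

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta_pooled)) if self.model == "logistic" else None

    def conf_int(self, alpha: float = 0.05):
        q = sps.norm.ppf(1 - alpha / 2)
        return (self.beta_pooled - q * self.se_pooled,
                self.beta_pooled + q * self.se_pooled)

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_cohort.copy()
        rows.insert(0, "outcome", self.outcome)
        rows.insert(1, "model", self.model)
        rows["Q"] = np.nan
        rows["df"] = np.nan
        rows["p_Q"] = np.nan
        rows["I2_pct"] = np.nan
        rows["pvalue"] = np.nan
        pooled = pd.DataFrame(
            [
                {
                    "outcome": self.outcome, "model": self.model,
                    "cohort": "(pooled)", "beta": self.beta_pooled,
                    "se": self.se_pooled, "weight_pct": 100.0,
                    "pvalue": self.pvalue, "Q": self.Q, "df": self.df,
                    "p_Q": self.p_Q, "I2_pct": self.I2_pct,
                }
            ]
        )
        return pd.concat([rows, pooled], ignore_index=True)[
            ["outcome", "model", "cohort", "beta", "se", "weight_pct",
             "pvalue", "Q", "df", "p_Q", "I2_pct"]
        ]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MetaResult":
        pooled = frame[frame["cohort"] == "(pooled)"].iloc[0]
        per = frame[frame["cohort"] != "(pooled)"][
            ["cohort", "beta", "se", "weight_pct"]
        ].reset_index(drop=True).astype(
            {"beta": float, "se": float, "weight_pct": float}
        )
        return cls(
            outcome=str(pooled["outcome"]), model=str(pooled["model"]),
            k=len(per), beta_pooled=float(pooled["beta"]),
            se_pooled=float(pooled["se"]), pvalue=float(pooled["pvalue"]),
            per_cohort=per, Q=float(pooled["Q"]), df=int(pooled["df"]),
            p_Q=float(pooled["p_Q"]), I2_pct=float(pooled["I2_pct"]),
        )

    def summary(self) -> str:
        lines = [
            f"Fixed-effect meta-analysis: {self.outcome} ({self.model}), "
            f"k = {self.k}",
            f"  pooled beta = {self.beta_pooled:.4f} "
            f"(se {self.se_pooled:.4f}, p = {self.pvalue:.3g})",
        ]
        if self.model == "logistic":
            lo, hi = self.conf_int()
            lines.append(
                f"  pooled OR = {np.exp(self.beta_pooled):.3f} "
                f"[{np.exp(lo):.3f}, {np.exp(hi):.3f}]"
            )
        lines.append(
            f"  heterogeneity: Q = {self.Q:.3f} (df {self.df}, "
            f"p = {self.p_Q:.3g}), I2 = {self.I2_pct:.1f}%"
        )
        return "\n".join(lines)


def fixed_effect_meta(estimates: list[AssocResult]) -> MetaResult:
    """Pool per-cohort estimates with inverse-variance fixed-effect weights.

    ``w_k = 1/se_k^2``; ``beta = sum(w b)/sum(w)``; ``se = 1/sqrt(sum w)``;
    two-sided normal p-value. All estimates must share outcome and model
    family and have positive standard errors.
    """
    if len(estimates) < 1:
        raise ValidationError("meta-analysis needs at least one estimate")
    outcomes = {e.outcome for e in estimates}
    models = {e.model for e in estimates}
    if len(outcomes) > 1:
        raise ValidationError(f"mixed outcomes in meta-analysis: {outcomes}")
    if len(models) > 1:
        raise ValidationError(f"mixed model families in meta-analysis: {models}")
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(~(se > 0)):
        bad = [e.cohort for e, s in zip(estimates, se) if not s > 0]
        raise ValidationError(f"non-positive se for cohort(s) {bad}")
    beta = np.array([e.beta for e in estimates], dtype=float)
    w = 1.0 / se**2
    beta_pooled = float(np.sum(w * beta) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_pooled / se_pooled
    pvalue = float(min(max(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    k = len(estimates)
    Q = float(np.sum(w * (beta - beta_pooled) ** 2))
    df = k - 1
    p_Q = float(sps.chi2.sf(Q, df)) if df > 0 else float("nan")
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    per = pd.DataFrame(
        {
            "cohort": [e.cohort for e in estimates],
            "beta": beta,
            "se": se,
            "weight_pct": 100.0 * w / np.sum(w),
        }
    )
    return MetaResult(
        outcome=estimates[0].outcome, model=estimates[0].model, k=k,
        beta_pooled=beta_pooled, se_pooled=se_pooled, pvalue=pvalue,
        per_cohort=per, Q=Q, df=df, p_Q=p_Q, I2_pct=I2,
    )


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-cohort rows in input order, pooled last.

    Columns: cohort, beta, se, or, ci_low, ci_high (exp(beta +/- 1.96 se)),
    weight_pct.
    """
    q = sps.norm.ppf(0.975)
    rows = meta.per_cohort.copy()
    pooled = pd.DataFrame(
        [{"cohort": "(pooled)", "beta": meta.beta_pooled,
          "se": meta.se_pooled, "weight_pct": 100.0}]
    )
    tab = pd.concat([rows, pooled], ignore_index=True)
    tab["or"] = np.exp(tab["beta"])
    tab["ci_low"] = np.exp(tab["beta"] - q * tab["se"])
    tab["ci_high"] = np.exp(tab["beta"] + q * tab["se"])
    return tab[["cohort", "beta", "se", "or", "ci_low", "ci_high", "weight_pct"]]
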