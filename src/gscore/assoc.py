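"""Per-cohort regression of outcomes on the standardized score.

Thin layer over statsmodels GLM/OLS: logistic regression for binary traits,
linear regression for continuous ones, with principal components and array
platform as covariates. Also provides tertile-contrast odds ratios and the
mediation-by-adjustment attenuation measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConvergenceError, ValidationError
from .score import ScoreResult, TERTILE_LABELS

logger = logging.getLogger(__name__)

_RESULT_COLUMNS = (
    "cohort", "outcome", "model", "term", "beta", "se", "pvalue",
    "n", "n_cases", "covariates", "adjustment_tag",
)


@dataclass
class AssocResult:
    """A single regression coefficient: effect per unit of the term.

    For ``model="logistic"`` the coefficient is a log-odds ratio; exp(beta)
    is then reported as an OR. ``term`` identifies the predictor the
    estimate refers to (``z_score`` for per-SD score effects, or a tertile
    contrast such as ``high_vs_low``).
    """

    cohort: str
    outcome: str
    model: str
    beta: float
    se: float
    pvalue: float
    n: int
    term: str = "z_score"
    n_cases: int | None = None
    covariates: tuple = ()
    adjustment_tag: str = "none"

    def __post_init__(self) -> None:
        if self.model not in ("logistic", "linear"):
            raise ValidationError(f"unknown model family {self.model!r}")
        self.covariates = tuple(self.covariates)

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta)) if self.model == "logistic" else None

    def conf_int(self, alpha: float = 0.05):
        """Wald CI on the coefficient scale: beta +/- z_{alpha/2} * se."""
        q = sps.norm.ppf(1 - alpha / 2)
        return self.beta - q * self.se, self.beta + q * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cohort": self.cohort,
                    "outcome": self.outcome,
                    "model": self.model,
                    "term": self.term,
                    "beta": self.beta,
                    "se": self.se,
                    "pvalue": self.pvalue,
                    "n": self.n,
                    "n_cases": self.n_cases,
                    "covariates": ",".join(self.covariates),
                    "adjustment_tag": self.adjustment_tag,
                }
            ],
            columns=list(_RESULT_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AssocResult":
        row = frame.iloc[0]
        cov = row.get("covariates")
        cov = tuple(str(cov).split(",")) if isinstance(cov, str) and cov else ()
        n_cases = row.get("n_cases")
        return cls(
            cohort=str(row["cohort"]),
            outcome=str(row["outcome"]),
            model=str(row["model"]),
            term=str(row["term"]),
            beta=float(row["beta"]),
            se=float(row["se"]) if pd.notna(row["se"]) else float("nan"),
            pvalue=float(row["pvalue"]) if pd.notna(row["pvalue"]) else float("nan"),
            n=int(row["n"]),
            n_cases=int(n_cases) if pd.notna(n_cases) else None,
            covariates=cov,
            adjustment_tag=str(row["adjustment_tag"]),
        )


def _design_matrix(df: pd.DataFrame, predictors) -> pd.DataFrame:
    """Numeric design matrix; categorical covariates (e.g. platform) are
    expanded to indicator contrasts dropping the first level."""
    parts = []
    for col in predictors:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).to_frame(col))
    X = pd.concat(parts, axis=1)
    return sm.add_constant(X, has_constant="add")


def _merge_score(samples: pd.DataFrame, score: ScoreResult) -> pd.DataFrame:
    sc = pd.DataFrame({"sample_id": score.sample_ids, "z_score": score.z_score})
    if score.tertile is not None:
        sc["tertile"] = score.tertile
    df = samples.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    sc["sample_id"] = sc["sample_id"].astype(str)
    return df.merge(sc, on="sample_id", how="inner")


def _fit(y, X, family: str):
    if family == "logistic":
        import warnings

        from statsmodels.tools.sm_exceptions import (
            PerfectSeparationError,
            PerfectSeparationWarning,
        )
        try:
            with warnings.catch_warnings():
                # separation is re-raised as ConvergenceError below
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                model = sm.GLM(y, X, family=sm.families.Binomial())
                res = model.fit(maxiter=100, tol=1e-8)
        except PerfectSeparationError as exc:  # pragma: no cover - version dependent
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
            raise ConvergenceError(
                "logistic fit did not converge (quasi-separation: "
                f"max |beta| = {np.max(np.abs(res.params)):.3g})"
            )
        return res
    return sm.OLS(y, X).fit()


def fit_glm(samples: pd.DataFrame, score: ScoreResult, outcome: str,
            covariates=(), family: str = "logistic", cohort: str = "cohort",
            adjustment_tag: str = "none") -> AssocResult:
    """Fit ``outcome ~ z_score + covariates`` and report the z_score term.

    Logistic (binomial GLM via IRLS) for binary 0/1 outcomes, OLS for
    continuous ones. Complete-case analysis; two-sided Wald p-value.
    """
    if family not in ("logistic", "linear"):
        raise ValidationError(f"unknown family {family!r}")
    covariates = list(covariates)
    df = _merge_score(samples, score)
    if outcome not in df.columns:
        raise ValidationError(f"outcome column {outcome!r} not in sample table")
    cols = [outcome, "z_score"] + covariates
    cc = df[cols + ["sample_id"]].dropna()
    n_dropped = len(df) - len(cc)
    if n_dropped:
        logger.info("fit_glm[%s~%s]: dropped %d incomplete case(s)",
                    outcome, cohort, n_dropped)
    y = cc[outcome].astype(float)
    if y.nunique() < 2:
        raise ValidationError(f"outcome {outcome!r} is constant after "
                              "complete-case filtering")
    if family == "logistic" and not set(y.unique()) <= {0.0, 1.0}:
        raise ValidationError(f"binary outcome {outcome!r} must be coded 0/1")
    X = _design_matrix(cc, ["z_score"] + covariates)
    if len(cc) < X.shape[1] + 2:
        raise ValidationError(
            f"too few complete cases ({len(cc)}) for {X.shape[1]} predictors"
        )
    res = _fit(y, X, family)
    beta = float(res.params["z_score"])
    se = float(res.bse["z_score"])
    p = 2.0 * float(sps.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return AssocResult(
        cohort=cohort, outcome=outcome, model=family, beta=beta, se=se,
        pvalue=min(max(p, np.finfo(float).tiny), 1.0), n=len(cc),
        n_cases=int(y.sum()) if family == "logistic" else None,
        covariates=tuple(covariates), adjustment_tag=adjustment_tag,
    )


def tertile_contrast(samples: pd.DataFrame, score: ScoreResult, outcome: str,
                     covariates=(), cohort: str = "cohort") -> list[AssocResult]:
    """Odds ratios of the medium and high score tertiles vs the low tertile.

    Logistic fit of ``outcome ~ I(medium) + I(high) + covariates``; returns
    one AssocResult per contrast (terms ``medium_vs_low`` and
    ``high_vs_low``).
    """
    if score.tertile is None:
        raise ValidationError("score has no tertile labels; run tertile_groups first")
    covariates = list(covariates)
    df = _merge_score(samples, score)
    cols = [outcome, "tertile"] + covariates
    cc = df[cols].dropna()
    counts = cc["tertile"].value_counts()
    empty = [t for t in TERTILE_LABELS if counts.get(t, 0) == 0]
    if empty:
        raise ValidationError(
            f"empty tertile(s) after complete-case filtering: {empty}"
        )
    y = cc[outcome].astype(float)
    if not set(y.unique()) <= {0.0, 1.0}:
        raise ValidationError(f"tertile contrast needs a 0/1 outcome, got {outcome!r}")
    cc = cc.assign(
        medium=(cc["tertile"] == "medium").astype(float),
        high=(cc["tertile"] == "high").astype(float),
    )
    X = _design_matrix(cc, ["medium", "high"] + covariates)
    res = _fit(y, X, "logistic")
    out = []
    for term, col in (("medium_vs_low", "medium"), ("high_vs_low", "high")):
        beta = float(res.params[col])
        se = float(res.bse[col])
        p = 2.0 * float(sps.norm.sf(abs(beta / se))) if se > 0 else 0.0
        out.append(
            AssocResult(
                cohort=cohort, outcome=outcome, model="logistic", beta=beta,
                se=se, pvalue=min(max(p, np.finfo(float).tiny), 1.0),
                n=len(cc), n_cases=int(y.sum()), term=term,
                covariates=tuple(covariates), adjustment_tag="none",
            )
        )
    return out


@dataclass
class AttenuationResult:
    """Percent change of the score coefficient after mediator adjustment."""

    cohort: str
    outcome: str
    beta_base: float
    beta_adjusted: float
    pvalue_base: float
    pvalue_adjusted: float
    pct_attenuation: float
    undefined: bool = False


def attenuation(base: AssocResult, adjusted: AssocResult,
                tol: float = 1e-8) -> AttenuationResult:
    """Attenuation of the score effect by covariate adjustment.

    ``pct = 100 * (1 - beta_adjusted / beta_base)``; flagged undefined when
    the base coefficient is numerically zero. The adjusted model must nest
    the base model (same cohort, outcome; superset of covariates).
    """
    if (base.cohort, base.outcome) != (adjusted.cohort, adjusted.outcome):
        raise ValidationError(
            "attenuation requires matching cohort and outcome: "
            f"{(base.cohort, base.outcome)} vs {(adjusted.cohort, adjusted.outcome)}"
        )
    if not set(base.covariates) <= set(adjusted.covariates):
        raise ValidationError(
            "adjusted model must include all covariates of the base model"
        )
    undefined = abs(base.beta) < tol
    pct = float("nan") if undefined else 100.0 * (1.0 - adjusted.beta / base.beta)
    if undefined:
        logger.warning("attenuation: base coefficient ~ 0; percentage undefined")
    return AttenuationResult(
        cohort=base.cohort, outcome=base.outcome,
        beta_base=base.beta, beta_adjusted=adjusted.beta,
        pvalue_base=base.pvalue, pvalue_adjusted=adjusted.pvalue,
        pct_attenuation=pct, undefined=undefined,
    )
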