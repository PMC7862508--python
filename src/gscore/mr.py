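"""Two-sample Mendelian randomization.

Harmonizes exposure/outcome GWAS summary statistics to shared effect
alleles, then estimates the causal effect of the exposure(s) per SD by

* **IVW** — fixed-effect inverse-variance weighting, equivalent to a
  no-intercept weighted regression of outcome effects ``by`` on exposure
  effects ``bx`` with weights ``1/sy^2``;
* **MR-Egger** — the same weighted regression with a free intercept (the
  intercept measures directional pleiotropy); instrument effects are first
  re-oriented so all ``bx >= 0``;
* **weighted median** — the per-SNP Wald-ratio value where the cumulative
  instrument weight (``bx^2/sy^2``, normalized) crosses 0.5, robust while
  at least half of the weight comes from valid instruments; its SE comes
  from a seeded parametric bootstrap;
* **MV-IVW** — joint weighted regression on two exposures' effects, giving
  direct (conditional) effects.

A relationship is flagged *reliable* when at least two of the three
univariable methods give P < 0.05 (strict); the reported estimate is always
IVW's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearityError,
    EmptyInstrumentError,
    ValidationError,
)
from .io import SummaryStats
from .score import is_palindromic, weights_from_stats

logger = logging.getLogger(__name__)

UNIVARIABLE_METHODS = ("IVW", "Egger", "WeightedMedian")
CONSENSUS_RULE = ">=2 of 3 methods P<0.05"


@dataclass
class HarmonizedSet:
    """Instrument-level exposure/outcome effects on aligned effect alleles.

    ``df`` columns: ``snp, bx, sx, by, sy`` (+ ``bx2, sx2`` for a second
    exposure), ``flipped`` (outcome coded on the opposite allele),
    ``excluded`` and ``reason``. Excluded rows are retained for reporting
    but ignored by the estimators.
    """

    df: pd.DataFrame
    exposure: str = "exposure"
    outcome: str = "outcome"
    exposure2: str | None = None
    filter_counts: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[~self.df["excluded"]]

    @property
    def n_retained(self) -> int:
        return int((~self.df["excluded"]).sum())


def _effects(stats: SummaryStats) -> pd.DataFrame:
    """snp/a1/a2/beta/se for one table, deriving beta from z where needed."""
    ws = weights_from_stats(stats)
    return ws.df.rename(columns={"weight": "beta"})[
        ["snp", "a1", "a2", "beta", "se"]
    ]


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              second_exposure: SummaryStats | None = None,
              drop_palindromic: bool = True) -> HarmonizedSet:
    """Align outcome (and second-exposure) effects to the exposure's
    effect alleles.

    Where a table codes a SNP on the swapped allele pair, its effect sign
    is flipped. Palindromic SNPs are excluded (strand ambiguity), as are
    SNPs with irreconcilable allele pairs or missing from any table.

    Raises
    ------
    EmptyInstrumentError  if exposure and outcome share no SNP at all.
    """
    if exposure.cohort is not None and exposure.cohort == outcome.cohort:
        logger.warning(
            "harmonize: exposure and outcome tables declare the same cohort "
            "tag %r; two-sample assumptions may be violated", exposure.cohort
        )
    ex = _effects(exposure).rename(columns={"beta": "bx", "se": "sx"})
    out = _effects(outcome).rename(
        columns={"beta": "by", "se": "sy", "a1": "a1_o", "a2": "a2_o"}
    )
    if not set(ex["snp"]) & set(out["snp"]):
        raise EmptyInstrumentError(
            "no SNP overlap between exposure and outcome tables"
        )
    m = ex.merge(out, on="snp", how="left")
    excluded = np.zeros(len(m), dtype=bool)
    reason = np.array([""] * len(m), dtype=object)
    flipped = np.zeros(len(m), dtype=bool)

    missing = m["by"].isna().to_numpy()
    excluded |= missing
    reason[missing] = "missing_in_outcome"

    present = ~missing
    same = present & (m["a1"] == m["a1_o"]).to_numpy() & (m["a2"] == m["a2_o"]).to_numpy()
    swap = present & (m["a1"] == m["a2_o"]).to_numpy() & (m["a2"] == m["a1_o"]).to_numpy()
    mismatch = present & ~(same | swap)
    excluded |= mismatch
    reason[mismatch] = "allele_mismatch"
    flipped |= swap
    m.loc[swap, "by"] = -m.loc[swap, "by"]

    pal = is_palindromic(m["a1"], m["a2"])
    if drop_palindromic and pal.any():
        newly = pal & ~excluded
        reason[newly] = "palindromic"
        excluded |= pal

    m = m.drop(columns=["a1_o", "a2_o"])

    if second_exposure is not None:
        ex2 = _effects(second_exposure).rename(
            columns={"beta": "bx2", "se": "sx2", "a1": "a1_2", "a2": "a2_2"}
        )
        m = m.merge(ex2, on="snp", how="left")
        miss2 = m["bx2"].isna().to_numpy()
        newly = miss2 & ~excluded
        reason[newly] = "missing_in_second_exposure"
        excluded |= miss2
        same2 = ~miss2 & (m["a1"] == m["a1_2"]).to_numpy() & (m["a2"] == m["a2_2"]).to_numpy()
        swap2 = ~miss2 & (m["a1"] == m["a2_2"]).to_numpy() & (m["a2"] == m["a1_2"]).to_numpy()
        mism2 = ~miss2 & ~(same2 | swap2)
        newly = mism2 & ~excluded
        reason[newly] = "allele_mismatch"
        excluded |= mism2
        m.loc[swap2, "bx2"] = -m.loc[swap2, "bx2"]
        m = m.drop(columns=["a1_2", "a2_2"])

    m["flipped"] = flipped
    m["excluded"] = excluded
    m["reason"] = reason
    n_dropped = int(excluded.sum())
    if n_dropped:
        logger.info("harmonize: excluded %d of %d SNP(s): %s",
                    n_dropped, len(m),
                    dict(pd.Series(reason[excluded]).value_counts()))
    return HarmonizedSet(
        df=m.reset_index(drop=True), exposure=exposure.trait,
        outcome=outcome.trait,
        exposure2=second_exposure.trait if second_exposure is not None else None,
    )


@dataclass
class MREstimate:
    """One MR method's causal-effect estimate (per SD of the exposure)."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    exposure: str | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def conf_int(self, alpha: float = 0.05):
        q = sps.norm.ppf(1 - alpha / 2)
        return self.beta - q * self.se, self.beta + q * self.se


def _weighted_regression(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares: coefficients and unscaled covariance.

    Returns (coef, cov_unscaled, sigma2_hat) where cov_unscaled =
    (X'WX)^-1 and sigma2_hat is the weighted residual mean square (NaN
    when there are no residual degrees of freedom).
    """
    A = X.T @ (w[:, None] * X)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise CollinearityError(
            f"design matrix numerically singular (condition number {cond:.3g})"
        )
    coef = np.linalg.solve(A, X.T @ (w * y))
    cov = np.linalg.inv(A)
    dof = len(y) - X.shape[1]
    if dof > 0:
        resid = y - X @ coef
        sigma2 = float(np.sum(w * resid**2) / dof)
    else:
        sigma2 = float("nan")
    return coef, cov, sigma2


def _two_sided_normal_p(z: float) -> float:
    return float(min(max(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))


def ivw(h: HarmonizedSet) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    ``beta = sum(bx by / sy^2) / sum(bx^2 / sy^2)``;
    ``se = 1/sqrt(sum(bx^2/sy^2))``; two-sided normal p. No intercept, no
    residual-scale inflation (the estimator's original fixed-effect form).
    """
    d = h.retained
    if len(d) < 2:
        raise EmptyInstrumentError(f"IVW needs >=2 SNPs, got {len(d)}")
    bx = d["bx"].to_numpy(float)
    by = d["by"].to_numpy(float)
    sy = d["sy"].to_numpy(float)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    return MREstimate(
        method="IVW", beta=beta, se=se,
        pvalue=_two_sided_normal_p(beta / se), n_snps=len(d),
        exposure=h.exposure,
    )


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of ``by = a + b*bx``.

    SNPs are re-oriented so all bx >= 0 (the standard identification
    condition). Weights are ``1/sy^2``; standard errors use a
    multiplicative residual scale bounded below by 1; p-values from the t
    distribution with k-2 df.
    """
    d = h.retained
    if len(d) < 3:
        raise EmptyInstrumentError(f"MR-Egger needs >=3 SNPs, got {len(d)}")
    bx = d["bx"].to_numpy(float)
    by = d["by"].to_numpy(float)
    sy = d["sy"].to_numpy(float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise CollinearityError("all exposure effects equal; Egger slope "
                                "unidentified")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    coef, cov, sigma2 = _weighted_regression(X, by, w)
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov) * scale)
    dof = len(bx) - 2
    p_slope = float(2.0 * sps.t.sf(abs(coef[1] / ses[1]), dof))
    p_int = float(2.0 * sps.t.sf(abs(coef[0] / ses[0]), dof))
    return MREstimate(
        method="Egger", beta=float(coef[1]), se=float(ses[1]),
        pvalue=min(max(p_slope, np.finfo(float).tiny), 1.0),
        n_snps=len(d), exposure=h.exposure,
        intercept=float(coef[0]), intercept_se=float(ses[0]),
        intercept_p=min(max(p_int, np.finfo(float).tiny), 1.0),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value where cumulative sorted weight crosses 0.5, with linear
    interpolation between adjacent ratios."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-SNP Wald ratios ``r_j = by_j/bx_j`` carry weights
    ``w_j = bx_j^2/sy_j^2`` (normalized); the estimate interpolates the
    cumulative weight at 0.5. SNPs with ``bx = 0`` are dropped with a
    warning. The SE resamples ``bx_j ~ N(bx_j, sx_j)``,
    ``by_j ~ N(by_j, sy_j)`` ``n_boot`` times (seed required when
    ``n_boot > 0``).
    """
    d = h.retained
    zero = d["bx"] == 0
    if zero.any():
        logger.warning("weighted_median: dropped %d SNP(s) with bx = 0",
                       int(zero.sum()))
        d = d[~zero]
    if len(d) < 3:
        raise EmptyInstrumentError(
            f"weighted median needs >=3 SNPs with bx != 0, got {len(d)}"
        )
    bx = d["bx"].to_numpy(float)
    sx = d["sx"].to_numpy(float)
    by = d["by"].to_numpy(float)
    sy = d["sy"].to_numpy(float)
    est = _weighted_median_point(by / bx, bx**2 / sy**2)
    if n_boot <= 0:
        return MREstimate(method="WeightedMedian", beta=est, se=float("nan"),
                          pvalue=float("nan"), n_snps=len(d),
                          exposure=h.exposure)
    if seed is None:
        raise ValidationError("weighted_median bootstrap requires a seed")
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(len(bx)) * sx
        byb = by + rng.standard_normal(len(by)) * sy
        ok = bxb != 0
        boot[b] = _weighted_median_point(byb[ok] / bxb[ok],
                                         bxb[ok]**2 / sy[ok]**2)
    se = float(boot.std(ddof=1))
    p = _two_sided_normal_p(est / se) if se > 0 else float("nan")
    return MREstimate(method="WeightedMedian", beta=est, se=se, pvalue=p,
                      n_snps=len(d), exposure=h.exposure)


def mv_ivw(h: HarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: joint weighted regression of ``by`` on
    ``(bx1, bx2)`` without intercept, weights ``1/sy^2``.

    Each slope is the direct effect of that exposure per SD, conditional on
    the other. All-zero exposure columns are dropped (with a warning),
    reducing to univariable IVW; rank deficiency raises with the condition
    number.
    """
    if "bx2" not in h.df.columns:
        raise ValidationError("mv_ivw needs a harmonized second exposure (bx2)")
    d = h.retained
    if len(d) < 3:
        raise EmptyInstrumentError(f"MV-IVW needs >=3 SNPs, got {len(d)}")
    names = [h.exposure, h.exposure2 or "exposure2"]
    cols = [d["bx"].to_numpy(float), d["bx2"].to_numpy(float)]
    keep = [i for i, c in enumerate(cols) if np.any(c != 0)]
    if len(keep) < len(cols):
        dropped = [names[i] for i in range(len(cols)) if i not in keep]
        logger.warning("mv_ivw: dropped all-zero exposure column(s) %s", dropped)
    X = np.column_stack([cols[i] for i in keep])
    by = d["by"].to_numpy(float)
    w = 1.0 / d["sy"].to_numpy(float) ** 2
    sw = np.sqrt(w)
    cond = np.linalg.cond(sw[:, None] * X)
    if cond > 1e8:
        raise CollinearityError(
            f"exposure effect matrix rank deficient (condition number {cond:.3g})"
        )
    coef, cov, _ = _weighted_regression(X, by, w)
    ses = np.sqrt(np.diag(cov))
    return [
        MREstimate(
            method="MV-IVW", beta=float(b), se=float(s),
            pvalue=_two_sided_normal_p(b / s), n_snps=len(d),
            exposure=names[i],
        )
        for b, s, i in zip(coef, ses, keep)
    ]


def sensitivity_filter(instruments: HarmonizedSet,
                       risk_stats: list[SummaryStats],
                       p_threshold: float = 1e-3) -> HarmonizedSet:
    """Exclude instruments moderately associated with any risk factor.

    A SNP is excluded when its p-value in *any* supplied risk-factor table
    is strictly below ``p_threshold``. A SNP missing from a table is not
    excluded by that table. Per-factor exclusion counts are recorded in
    ``filter_counts`` and logged.
    """
    df = instruments.df.copy()
    excluded = df["excluded"].to_numpy(bool).copy()
    reason = df["reason"].to_numpy(object).copy()
    counts: dict[str, int] = {}
    for stats in risk_stats:
        pvals = stats.df.set_index("snp")["p"]
        p = df["snp"].map(pvals)
        hit = (p < p_threshold).fillna(False).to_numpy(bool)
        counts[stats.trait] = int((hit & ~excluded).sum())
        newly = hit & ~excluded
        reason[newly] = f"risk_factor:{stats.trait}"
        excluded |= hit
    df["excluded"] = excluded
    df["reason"] = reason
    logger.info("sensitivity_filter: per-factor exclusions %s "
                "(threshold P < %g)", counts, p_threshold)
    return HarmonizedSet(
        df=df, exposure=instruments.exposure, outcome=instruments.outcome,
        exposure2=instruments.exposure2, filter_counts=counts,
    )


@dataclass
class MRResult:
    """All MR method estimates for one exposure-outcome pair plus the
    consensus verdict."""

    exposure: str
    outcome: str
    estimates: dict
    n_snps_used: int
    reliable: bool | None = None
    rule: str = CONSENSUS_RULE
    exposure2: str | None = None

    @property
    def reported(self) -> MREstimate:
        """The headline estimate: always the IVW row."""
        return self.estimates["IVW"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, est in self.estimates.items():
            rows.append(
                {
                    "exposure": est.exposure or self.exposure,
                    "outcome": self.outcome,
                    "method": est.method,
                    "beta": est.beta,
                    "se": est.se,
                    "pvalue": est.pvalue,
                    "n_snps": est.n_snps,
                    "intercept": est.intercept,
                    "intercept_se": est.intercept_se,
                    "intercept_p": est.intercept_p,
                    "reliable": self.reliable,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["exposure", "outcome", "method", "beta", "se", "pvalue",
                     "n_snps", "intercept", "intercept_se", "intercept_p",
                     "reliable"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MRResult":
        estimates = {}
        for _, row in frame.iterrows():
            est = MREstimate(
                method=str(row["method"]), beta=float(row["beta"]),
                se=float(row["se"]) if pd.notna(row["se"]) else float("nan"),
                pvalue=float(row["pvalue"]) if pd.notna(row["pvalue"]) else float("nan"),
                n_snps=int(row["n_snps"]),
                exposure=str(row["exposure"]),
                intercept=float(row["intercept"]) if pd.notna(row["intercept"]) else None,
                intercept_se=float(row["intercept_se"]) if pd.notna(row["intercept_se"]) else None,
                intercept_p=float(row["intercept_p"]) if pd.notna(row["intercept_p"]) else None,
            )
            key = est.method if est.method != "MV-IVW" else f"MV-IVW:{est.exposure}"
            estimates[key] = est
        rel = frame["reliable"].iloc[0]
        reliable = bool(rel) if pd.notna(rel) else None
        return cls(
            exposure=str(frame["exposure"].iloc[0]),
            outcome=str(frame["outcome"].iloc[0]),
            estimates=estimates, n_snps_used=int(frame["n_snps"].iloc[0]),
            reliable=reliable,
        )

    def summary(self) -> str:
        lines = [
            f"Two-sample MR: {self.exposure} -> {self.outcome} "
            f"({self.n_snps_used} instruments)",
            f"{'method':<16}{'beta':>9}{'se':>9}{'OR':>8}{'p':>12}",
        ]
        for est in self.estimates.values():
            name = est.method
            if est.method == "MV-IVW":
                name = f"MV-IVW[{est.exposure}]"
            lines.append(
                f"{name:<16}{est.beta:>9.4f}{est.se:>9.4f}"
                f"{np.exp(est.beta):>8.3f}{est.pvalue:>12.3g}"
            )
            if est.intercept is not None:
                lines.append(
                    f"  Egger intercept = {est.intercept:.5f} "
                    f"(se {est.intercept_se:.5f}, p = {est.intercept_p:.3g})"
                )
        if self.reliable is not None:
            lines.append(
                f"consensus ({self.rule}): "
                f"{'reliable' if self.reliable else 'not reliable'}; "
                f"reported estimate from IVW"
            )
        return "\n".join(lines)


def consensus(result: MRResult) -> MRResult:
    """Apply the 2-of-3 rule: reliable iff at least two univariable methods
    have p strictly below 0.05. The reported estimate stays IVW's."""
    missing = [m for m in UNIVARIABLE_METHODS if m not in result.estimates]
    if missing:
        raise ValidationError(f"consensus needs method row(s) {missing}")
    n_sig = sum(
        1 for m in UNIVARIABLE_METHODS if result.estimates[m].pvalue < 0.05
    )
    return replace(result, reliable=n_sig >= 2)


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    Statsmodels-style usage::

        model = MRModel.from_summary_stats(exposure_stats, outcome_stats)
        result = model.fit(n_boot=1000, seed=7)
        print(result.summary())
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.harmonized = harmonized

    @classmethod
    def from_summary_stats(cls, exposure: SummaryStats, outcome: SummaryStats,
                           second_exposure: SummaryStats | None = None,
                           drop_palindromic: bool = True) -> "MRModel":
        return cls(harmonize(exposure, outcome, second_exposure,
                             drop_palindromic=drop_palindromic))

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> MRResult:
        """Run IVW, MR-Egger, weighted median (and MV-IVW when a second
        exposure is harmonized) and apply the consensus rule."""
        h = self.harmonized
        estimates: dict[str, MREstimate] = {}
        estimates["IVW"] = ivw(h)
        estimates["Egger"] = egger(h)
        estimates["WeightedMedian"] = weighted_median(h, n_boot=n_boot, seed=seed)
        if "bx2" in h.df.columns:
            for est in mv_ivw(h):
                estimates[f"MV-IVW:{est.exposure}"] = est
        result = MRResult(
            exposure=h.exposure, outcome=h.outcome, estimates=estimates,
            n_snps_used=h.n_retained, exposure2=h.exposure2,
        )
        return consensus(result)
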