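"""Synthetic cohorts and two-sample GWAS summary statistics under a known
causal structure.

The generative model mirrors the mediation hypothesis the pipeline is built
to test: independent SNPs (Hardy-Weinberg, no LD) contribute additively to a
latent intelligence; a discretized 0-13 test score measures it with noise;
education follows intelligence (or vice versa, chosen per run); measured
intelligence and education drive risk-factor liabilities (BMI, smoking, T2D,
hypertension, HDL, LDL); coronary disease arises from a liability combining
risk factors plus optional direct effects. Downstream traits depend on the
*measured* mediators, so covariate adjustment for a mediator blocks its path
exactly. Binary traits use a liability-threshold model. Matched two-sample
summary statistics come either from marginal regressions on two disjoint
simulated samples or from a fast analytic mode that draws effect estimates
around their truth with standard GWAS standard-error approximations.

Every preset's defaults are the study conditions the pipeline is validated
under; all randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .io import DosageDataset, SummaryStats

logger = logging.getLogger(__name__)

RISK_FACTORS = ("bmi", "smoking", "t2d", "hypertension", "hdl", "ldl")
BINARY_RISK_FACTORS = ("smoking", "t2d", "hypertension")

#: non-palindromic ordered allele pairs assigned to simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                 ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]


def _default_iq_rf() -> dict:
    return {"bmi": -0.08, "smoking": -0.10, "t2d": -0.05,
            "hypertension": -0.06, "hdl": 0.06, "ldl": 0.0}


def _default_edu_rf() -> dict:
    return {"bmi": -0.12, "smoking": -0.18, "t2d": -0.08,
            "hypertension": -0.08, "hdl": 0.10, "ldl": -0.04}


def _default_rf_cad() -> dict:
    return {"bmi": 0.15, "smoking": 0.30, "t2d": 0.25,
            "hypertension": 0.30, "hdl": -0.20, "ldl": 0.20}


def _default_prevalence() -> dict:
    return {"cad": 0.06, "t2d": 0.08, "smoking": 0.45, "hypertension": 0.30}


@dataclass
class PathCoefficients:
    """Standardized path coefficients of the causal diagram.

    ``g_iq`` is the effect of the standardized true genetic score on latent
    intelligence; mediator-to-trait paths are per SD of the *measured*
    mediator. ``direction`` resolves the intelligence<->education
    bidirectionality as a per-run choice (a simultaneous cyclic model is
    not identifiable); a shared genetic component ``g_edu_shared`` links
    the two either way.
    """

    g_iq: float = 0.22
    iq_edu: float = 0.45
    edu_iq: float = 0.45
    direction: str = "iq_to_edu"
    g_edu_shared: float = 0.10
    iq_rf: dict = field(default_factory=_default_iq_rf)
    edu_rf: dict = field(default_factory=_default_edu_rf)
    rf_cad: dict = field(default_factory=_default_rf_cad)
    iq_cad: float = -0.08
    edu_cad: float = -0.15

    @classmethod
    def all_null(cls) -> "PathCoefficients":
        return cls(g_iq=0.0, iq_edu=0.0, edu_iq=0.0, g_edu_shared=0.0,
                   iq_rf=dict.fromkeys(RISK_FACTORS, 0.0),
                   edu_rf=dict.fromkeys(RISK_FACTORS, 0.0),
                   rf_cad=dict.fromkeys(RISK_FACTORS, 0.0),
                   iq_cad=0.0, edu_cad=0.0)


@dataclass
class Pleiotropy:
    """Direct instrument-to-outcome effects violating MR validity."""

    n_pleiotropic: int = 0
    effect_sd: float = 0.01
    directional_mean: float = 0.0


@dataclass
class CaseControl:
    """Case-control ascertainment: oversample cases from a population pool
    generated at the given sampling-frame prevalence."""

    n_cases: int
    n_controls: int
    prevalence: float = 0.06


@dataclass
class SimConfig:
    """Full configuration of one simulation run. ``seed`` is mandatory."""

    seed: int
    n_snps: int = 242
    n_samples: int = 5000
    maf_range: tuple = (0.05, 0.5)
    weight_scale: float = 0.015
    paths: PathCoefficients = field(default_factory=PathCoefficients)
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    case_control: CaseControl | None = None
    prevalence: dict = field(default_factory=_default_prevalence)
    iq_measurement_r: float = 0.8
    mr_beta_intelligence: float = -0.29
    mr_beta_education: float = -0.48
    instrument_z_min: float = 5.45
    instrument_z_spread: float = 12.0
    edu_bx_correlation: float = 0.6
    gwas_n_exposure: float = 270_000
    gwas_n_outcome: float = 180_000
    outcome_case_fraction: float = 0.33
    n_pcs: int = 5

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_snps < 1 or self.n_samples < 1:
            raise ConfigError("n_snps and n_samples must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"maf_range must lie inside (0,1): {self.maf_range}")
        for name, v in self.prevalence.items():
            if not 0.0 < v < 1.0:
                raise ConfigError(f"prevalence[{name}] must be in (0,1): {v}")
        p = self.paths
        if p.direction not in ("iq_to_edu", "edu_to_iq"):
            raise ConfigError(f"unknown direction {p.direction!r}")
        if not 0.0 <= abs(p.g_iq) < 1.0:
            raise ConfigError("g_iq must have |g_iq| < 1 (liability share)")
        if not 0.0 < self.iq_measurement_r <= 1.0:
            raise ConfigError("iq_measurement_r must be in (0,1]")
        for label, contrib in (
            ("education", p.iq_edu**2 + p.g_edu_shared**2
             if p.direction == "iq_to_edu" else p.edu_iq**2 + p.g_edu_shared**2),
            ("cad liability", sum(v**2 for v in p.rf_cad.values())
             + p.iq_cad**2 + p.edu_cad**2),
            *[(f"risk factor {rf}", p.iq_rf.get(rf, 0.0)**2
               + p.edu_rf.get(rf, 0.0)**2) for rf in RISK_FACTORS],
        ):
            if contrib >= 1.0:
                raise ConfigError(
                    f"liability variance contributions for {label} sum to "
                    f"{contrib:.3f} >= 1; model infeasible"
                )
        if self.case_control is not None:
            cc = self.case_control
            if cc.n_cases < 1 or cc.n_controls < 1:
                raise ConfigError("case/control counts must be positive")
            if not 0.0 < cc.prevalence < 1.0:
                raise ConfigError("case_control.prevalence must be in (0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "paths" in d and isinstance(d["paths"], dict):
            d["paths"] = PathCoefficients(**d["paths"])
        if "pleiotropy" in d and isinstance(d["pleiotropy"], dict):
            d["pleiotropy"] = Pleiotropy(**d["pleiotropy"])
        if "case_control" in d and isinstance(d["case_control"], dict):
            d["case_control"] = CaseControl(**d["case_control"])
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class SimOutput:
    """What one simulation run produced: the individual-level dataset and/or
    summary-statistic tables, plus the ground truth needed to recompute any
    expected estimate."""

    truth: dict
    dataset: DosageDataset | None = None
    summary_stats: dict | None = None


# ---------------------------------------------------------------------------
# genetic architecture

def _draw_architecture(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Instrument SNPs: Hardy-Weinberg frequencies and per-allele effects.

    Effect magnitudes come from the tail of a normal (|N| > 1 SD): published
    instrument lists are the *selected* genome-wide-significant hits of a
    large discovery GWAS, so near-zero effects do not occur among them. With
    the default sample sizes this puts every instrument's implied discovery
    z-statistic above the genome-wide threshold.
    """
    m = cfg.n_snps
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], m)
    lower = sps.norm.cdf(1.0)  # truncate |effect| below 1 scale-SD
    magnitude = sps.norm.ppf(rng.uniform(lower, 1.0, m))
    w = np.where(rng.random(m) < 0.5, -1.0, 1.0) * cfg.weight_scale * magnitude
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    snp = np.array([f"rs{100001 + i}" for i in range(m)], dtype=object)
    g_var = float(np.sum(w**2 * 2.0 * maf * (1.0 - maf)))
    return {
        "snp": snp, "a1": a1, "a2": a2, "maf": maf, "w": w,
        "g_sd": float(np.sqrt(g_var)) if g_var > 0 else 0.0,
    }


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _resid_sd(*coefs: float) -> float:
    """SD of the residual term keeping a latent near unit variance
    (covariances between standardized parents are ignored; documented)."""
    rest = 1.0 - sum(c**2 for c in coefs)
    return float(np.sqrt(max(rest, 0.05)))


def _draw_population(cfg: SimConfig, n: int, rng: np.random.Generator,
                     arch: dict) -> tuple[np.ndarray, pd.DataFrame]:
    """Dosage matrix (m, n) and phenotype table for n unascertained samples."""
    p = cfg.paths
    maf, w = arch["maf"], arch["w"]
    # Binomial(2, maf) as two Bernoulli draws; float from the start is
    # markedly faster than a post-hoc astype on cohort-sized matrices
    m = len(maf)
    D = np.asarray(rng.random((m, n)) < maf[:, None], dtype=float)
    D += rng.random((m, n)) < maf[:, None]
    g = w @ (D - 2.0 * maf[:, None])
    g_std = g / arch["g_sd"] if arch["g_sd"] > 0 else np.zeros(n)

    latent_iq = p.g_iq * g_std + _resid_sd(p.g_iq) * rng.standard_normal(n)
    r = cfg.iq_measurement_r
    iq_obs = r * latent_iq + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    iq_measured = np.clip(np.round(6.5 + 2.1 * iq_obs), 0, 13)
    iq_std = _standardize(iq_measured)

    if p.direction == "iq_to_edu":
        edu_lat = (p.iq_edu * iq_std + p.g_edu_shared * g_std
                   + _resid_sd(p.iq_edu, p.g_edu_shared) * rng.standard_normal(n))
    else:
        edu_lat = (p.g_edu_shared * g_std
                   + _resid_sd(p.g_edu_shared) * rng.standard_normal(n))
    edu_years = np.clip(np.round(11.0 + 3.3 * edu_lat), 7, 20)
    edu_std = _standardize(edu_years)
    if p.direction == "edu_to_iq":
        # education drives measured intelligence instead
        iq_obs = (p.edu_iq * edu_std + p.g_iq * g_std
                  + _resid_sd(p.edu_iq, p.g_iq) * rng.standard_normal(n))
        iq_measured = np.clip(np.round(6.5 + 2.1 * iq_obs), 0, 13)
        iq_std = _standardize(iq_measured)

    cols = {"iq_measured": iq_measured, "edu_years": edu_years}
    rf_latent = {}
    for rf in RISK_FACTORS:
        a, b = p.iq_rf.get(rf, 0.0), p.edu_rf.get(rf, 0.0)
        lat = (a * iq_std + b * edu_std
               + _resid_sd(a, b) * rng.standard_normal(n))
        rf_latent[rf] = lat
    cols["bmi"] = 27.0 + 4.2 * rf_latent["bmi"]
    cols["hdl"] = 1.45 + 0.35 * rf_latent["hdl"]
    cols["ldl"] = 3.55 + 0.85 * rf_latent["ldl"]
    for rf in BINARY_RISK_FACTORS:
        thr = sps.norm.ppf(1.0 - cfg.prevalence[rf])
        cols[rf] = (rf_latent[rf] > thr).astype(int)

    rf_term = sum(p.rf_cad.get(rf, 0.0) * rf_latent[rf] for rf in RISK_FACTORS)
    resid = _resid_sd(*(list(p.rf_cad.values()) + [p.iq_cad, p.edu_cad]))
    liab = (rf_term + p.iq_cad * iq_std + p.edu_cad * edu_std
            + resid * rng.standard_normal(n))
    prev = (cfg.case_control.prevalence if cfg.case_control is not None
            else cfg.prevalence["cad"])
    cols["cad"] = (liab > sps.norm.ppf(1.0 - prev)).astype(int)

    for k in range(1, cfg.n_pcs + 1):
        cols[f"PC{k}"] = rng.standard_normal(n)
    cols["platform"] = np.where(rng.random(n) < 0.5, "axiom", "bileve")
    return D, pd.DataFrame(cols)


def _ascertain(cfg: SimConfig, rng: np.random.Generator,
               arch: dict) -> tuple[np.ndarray, pd.DataFrame]:
    """Oversample cases from population pools until the requested counts."""
    cc = cfg.case_control
    D_parts, S_parts = [], []
    n_cases = n_controls = 0
    chunk = int(max(2000, 1.3 * max(cc.n_cases / cc.prevalence,
                                    cc.n_controls / (1 - cc.prevalence))))
    for _ in range(200):
        D, S = _draw_population(cfg, chunk, rng, arch)
        D_parts.append(D)
        S_parts.append(S)
        n_cases += int(S["cad"].sum())
        n_controls += int((1 - S["cad"]).sum())
        if n_cases >= cc.n_cases and n_controls >= cc.n_controls:
            break
    else:  # pragma: no cover
        raise ConfigError("case-control ascertainment did not reach the "
                          "requested counts; prevalence too low?")
    D = np.concatenate(D_parts, axis=1)
    S = pd.concat(S_parts, ignore_index=True)
    case_idx = np.flatnonzero(S["cad"].to_numpy() == 1)[: cc.n_cases]
    ctrl_idx = np.flatnonzero(S["cad"].to_numpy() == 0)[: cc.n_controls]
    keep = np.concatenate([case_idx, ctrl_idx])
    keep = keep[np.argsort(keep, kind="stable")]
    return D[:, keep], S.iloc[keep].reset_index(drop=True)


def simulate_cohort(cfg: SimConfig, truth: dict | None = None) -> SimOutput:
    """Generate one individual-level cohort under the configured DAG.

    Returns a :class:`SimOutput` whose dataset holds dosages, variant
    metadata (effect allele = the allele whose count the weight refers to,
    ref_eaf = its population frequency) and the phenotype/covariate sheet;
    ``truth`` records every parameter needed to recompute expectations.
    Passing the ``truth`` of a previous run reuses its genetic architecture
    (same SNPs, alleles, frequencies and weights), as when several cohorts
    share one instrument set.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if truth is not None:
        arch = {k: truth[k] for k in ("snp", "a1", "a2", "maf", "w", "g_sd")}
    else:
        arch = _draw_architecture(cfg, rng)
    if cfg.case_control is not None:
        D, S = _ascertain(cfg, rng, arch)
    else:
        D, S = _draw_population(cfg, cfg.n_samples, rng, arch)
    S.insert(0, "sample_id", [f"S{i + 1:06d}" for i in range(len(S))])
    variants = pd.DataFrame(
        {"snp": arch["snp"], "a1": arch["a1"], "a2": arch["a2"],
         "ref_eaf": arch["maf"]}
    )
    dataset = DosageDataset(variants=variants, dosages=D, samples=S)
    truth = {
        "snp": arch["snp"], "a1": arch["a1"], "a2": arch["a2"],
        "maf": arch["maf"], "w": arch["w"], "g_sd": arch["g_sd"],
        "config": cfg,
    }
    return SimOutput(truth=truth, dataset=dataset)


# ---------------------------------------------------------------------------
# two-sample summary statistics

def _sumstat_frame(arch, beta, se, n) -> pd.DataFrame:
    """Assemble a canonical summary-statistic frame, orienting each SNP's
    effect allele to be exposure-increasing (beta >= 0 in truth is handled
    by the caller passing oriented alleles/frequencies)."""
    z = beta / se
    return pd.DataFrame(
        {
            "snp": arch["snp"], "a1": arch["a1"], "a2": arch["a2"],
            "eaf": arch["maf"], "beta": beta, "se": se, "z": z,
            "p": np.clip(2.0 * sps.norm.sf(np.abs(z)),
                         np.finfo(float).tiny, 1.0),
            "n": float(n),
        }
    )


def _oriented_arch(arch: dict) -> tuple[dict, np.ndarray]:
    """Flip allele labels so the effect allele is intelligence-increasing,
    the convention of published instrument lists."""
    flip = arch["w"] < 0
    out = dict(arch)
    out["a1"] = np.where(flip, arch["a2"], arch["a1"])
    out["a2"] = np.where(flip, arch["a1"], arch["a2"])
    out["maf"] = np.where(flip, 1.0 - arch["maf"], arch["maf"])
    out["w"] = np.abs(arch["w"])
    return out, flip


def _marginal_ols(D: np.ndarray, y: np.ndarray):
    """Vectorized per-SNP simple linear regression of y on dosage."""
    n = len(y)
    dc = D - D.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.sum(dc**2, axis=1)
    beta = dc @ yc / sxx
    resid_ss = np.sum(yc**2) - beta**2 * sxx
    se = np.sqrt(resid_ss / (n - 2) / sxx)
    return beta, se


def _marginal_logistic(D: np.ndarray, y: np.ndarray, n_iter: int = 25):
    """Vectorized per-SNP logistic regression (intercept + dosage) by IRLS."""
    m, n = D.shape
    ybar = max(min(y.mean(), 1 - 1e-9), 1e-9)
    a = np.full(m, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)
    for _ in range(n_iter):
        eta = a[:, None] + b[:, None] * D
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = mu * (1.0 - mu)
        r = y[None, :] - mu
        s0 = wt.sum(axis=1)
        s1 = (wt * D).sum(axis=1)
        s2 = (wt * D**2).sum(axis=1)
        g0 = r.sum(axis=1)
        g1 = (r * D).sum(axis=1)
        det = s0 * s2 - s1**2
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < 1e-10:
            break
    eta = a[:, None] + b[:, None] * D
    mu = 1.0 / (1.0 + np.exp(-eta))
    wt = mu * (1.0 - mu)
    s0 = wt.sum(axis=1)
    s1 = (wt * D).sum(axis=1)
    s2 = (wt * D**2).sum(axis=1)
    se = np.sqrt(s0 / (s0 * s2 - s1**2))
    return b, se


def simulate_summary_stats(cfg: SimConfig, mode: str = "analytic",
                           include_second_exposure: bool = False,
                           risk_traits: tuple = (),
                           truth: dict | None = None) -> SimOutput:
    """Two-sample GWAS summary statistics with known causal truth.

    ``analytic`` mode draws ``bx_hat ~ N(bx_true, sx)`` and
    ``by_hat ~ N(by_true, sy)`` with standard GWAS standard-error
    approximations (continuous exposure; case-control outcome with the
    configured case fraction) — exposure and outcome errors are independent
    by construction, matching the two-sample design. ``cohort`` mode runs
    marginal per-SNP regressions on two disjoint simulated samples.

    ``truth`` may carry the architecture of a previously simulated cohort so
    the tables refer to the same instruments. Pleiotropy (direct
    SNP-to-outcome effects) follows ``cfg.pleiotropy``. Optional
    ``risk_traits`` adds one table per named risk factor (used by the MR
    sensitivity filter).
    """
    if mode not in ("analytic", "cohort"):
        raise ConfigError(f"unknown summary-statistic mode {mode!r}")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1 if truth is not None else cfg.seed)
    arch = truth if truth is not None and "w" in truth else _draw_architecture(cfg, rng)
    arch = {k: arch[k] for k in ("snp", "a1", "a2", "maf", "w", "g_sd")}
    oriented, _flip = _oriented_arch(arch)
    p = cfg.paths
    maf, w = oriented["maf"], oriented["w"]
    m = len(w)
    var_allele = 2.0 * maf * (1.0 - maf)

    if truth is not None or mode == "cohort":
        # per-allele effect on the standardized measured exposure, consistent
        # with the cohort-generating chain
        bx_true = (p.g_iq * cfg.iq_measurement_r * w / oriented["g_sd"]
                   if oriented["g_sd"] > 0 else np.zeros(m))
    else:
        # standalone analytic mode: instrument strength drawn directly as a
        # selected-hits z distribution (every SNP genome-wide significant,
        # I2_GX ~ 0.97) -- the regime where all three estimators are valid
        zdraw = cfg.instrument_z_min + rng.exponential(
            cfg.instrument_z_spread, m)
        bx_true = zdraw / np.sqrt(var_allele * cfg.gwas_n_exposure)
    sd_bx = bx_true.std() if bx_true.std() > 0 else cfg.weight_scale
    bx2_true = (cfg.edu_bx_correlation * bx_true
                + 0.8 * np.abs(rng.normal(0.0, sd_bx, m)))

    alpha = np.zeros(m)
    pl = cfg.pleiotropy
    if pl.n_pleiotropic > 0:
        idx = rng.choice(m, size=min(pl.n_pleiotropic, m), replace=False)
        alpha[idx] = rng.normal(pl.directional_mean, pl.effect_sd, len(idx))
    by_true = cfg.mr_beta_intelligence * bx_true + alpha
    if include_second_exposure:
        by_true = by_true + cfg.mr_beta_education * bx2_true

    v = cfg.outcome_case_fraction
    sx = 1.0 / np.sqrt(var_allele * cfg.gwas_n_exposure)
    sy = 1.0 / np.sqrt(var_allele * cfg.gwas_n_outcome * v * (1.0 - v))

    if mode == "analytic":
        bx_hat = bx_true + rng.standard_normal(m) * sx
        by_hat = by_true + rng.standard_normal(m) * sy
        bx2_hat = bx2_true + rng.standard_normal(m) * sx
    else:
        n_each = cfg.n_samples
        cfg_exp = replace(cfg, case_control=None)
        D1, S1 = _draw_population(cfg_exp, n_each, rng, arch)
        D2, S2 = _draw_population(cfg_exp, n_each, rng, arch)
        # orient dosages to the published (exposure-increasing) allele
        D1 = np.where(_flip[:, None], 2.0 - D1, D1)
        D2 = np.where(_flip[:, None], 2.0 - D2, D2)
        iq1 = _standardize(S1["iq_measured"].to_numpy(float))
        bx_hat, sx = _marginal_ols(D1, iq1)
        y2 = S2["cad"].to_numpy(float)
        by_hat, sy = _marginal_logistic(D2, y2)
        edu1 = _standardize(S1["edu_years"].to_numpy(float))
        bx2_hat, _sx2 = _marginal_ols(D1, edu1)

    tables = {
        "intelligence": SummaryStats(
            trait="intelligence",
            df=_sumstat_frame(oriented, bx_hat, sx, cfg.gwas_n_exposure),
            cohort="exposure_sample",
        ),
        "cad": SummaryStats(
            trait="cad",
            df=_sumstat_frame(oriented, by_hat, sy, cfg.gwas_n_outcome),
            cohort="outcome_sample",
        ),
    }
    if include_second_exposure:
        tables["education"] = SummaryStats(
            trait="education",
            df=_sumstat_frame(oriented, bx2_hat, sx, cfg.gwas_n_exposure),
            cohort="exposure_sample",
        )
    for rf in risk_traits:
        chain = p.iq_rf.get(rf, 0.0) + p.iq_edu * p.edu_rf.get(rf, 0.0)
        b_rf_true = chain * bx_true
        s_rf = 1.0 / np.sqrt(var_allele * cfg.gwas_n_outcome)
        b_rf = b_rf_true + rng.standard_normal(m) * s_rf
        tables[rf] = SummaryStats(
            trait=rf,
            df=_sumstat_frame(oriented, b_rf, s_rf, cfg.gwas_n_outcome),
            cohort="risk_factor_sample",
        )
    truth_out = {
        "snp": oriented["snp"], "maf": maf, "w": w, "g_sd": oriented["g_sd"],
        "bx_true": bx_true, "bx2_true": bx2_true, "by_true": by_true,
        "alpha": alpha, "beta_intelligence": cfg.mr_beta_intelligence,
        "beta_education": cfg.mr_beta_education, "config": cfg,
    }
    return SimOutput(truth=truth_out, summary_stats=tables)


# ---------------------------------------------------------------------------
# presets

def _preset_config(name: str, seed: int | None) -> SimConfig:
    if name == "tiny":
        return SimConfig(
            seed=11 if seed is None else seed, n_snps=10, n_samples=60,
            prevalence={"cad": 0.3, "t2d": 0.2, "smoking": 0.45,
                        "hypertension": 0.3},
        )
    if name == "default":
        return SimConfig(seed=42 if seed is None else seed)
    if name == "mediation-null":
        # full mediation: score -> measured intelligence -> disease, no
        # direct or risk-factor paths; balanced case-control design
        paths = PathCoefficients.all_null()
        paths.g_iq = 0.3
        paths.iq_cad = -0.6
        return SimConfig(
            seed=7 if seed is None else seed, n_samples=20_000,
            paths=paths,
            case_control=CaseControl(n_cases=10_000, n_controls=10_000,
                                     prevalence=0.2),
        )
    if name == "pleiotropic":
        return SimConfig(
            seed=13 if seed is None else seed,
            pleiotropy=Pleiotropy(n_pleiotropic=48, effect_sd=0.01,
                                  directional_mean=0.01),
            mr_beta_intelligence=-0.3,
        )
    raise ConfigError(f"unknown preset name {name!r}")


def make_fixture(name: str, seed: int | None = None) -> SimOutput:
    """Deterministic, seeded small datasets for tests and examples.

    ``tiny``: 10 SNPs x 60 samples plus matching summary statistics.
    ``default``: 242 SNPs x 5000 samples under the full default DAG.
    ``mediation-null``: full mediation, no direct effects, balanced
    case-control at n = 20,000.
    ``pleiotropic``: summary statistics with 20% invalid (directionally
    pleiotropic) instruments.
    """
    cfg = _preset_config(name, seed)
    if name == "pleiotropic":
        return simulate_summary_stats(cfg, mode="analytic")
    out = simulate_cohort(cfg)
    if name in ("tiny", "default"):
        stats = simulate_summary_stats(cfg, mode="analytic", truth=out.truth,
                                       include_second_exposure=True)
        out.summary_stats = stats.summary_stats
        out.truth.update({k: stats.truth[k]
                          for k in ("bx_true", "bx2_true", "by_true", "alpha")})
    return out
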