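"""Weighted genetic score (gIQ): effect-size derivation, allele alignment,
score computation, standardization and tertile grouping.

The score for sample *s* is ``raw_s = sum_j w_j * d_js`` where ``d_js`` is
the effect-allele dosage (0–2) of SNP *j* and ``w_j`` its per-allele effect
on the exposure. Missing dosages are imputed by the expected dosage
``2 * effect-allele frequency``. Raw scores are z-standardized within the
analysis dataset (mean 0, SD 1, sample SD with n-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    AlleleMismatchError,
    DegenerateScoreError,
    DegenerateVarianceError,
    EmptyInstrumentError,
    InsufficientSamplesError,
)
from .io import DosageDataset, SummaryStats

logger = logging.getLogger(__name__)

#: strand-ambiguous allele pairs, excluded from alignment by default
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

TERTILE_LABELS = ("low", "medium", "high")


@dataclass
class WeightSet:
    """Per-SNP weights (effect sizes on the exposure's SD scale).

    ``df`` columns: ``snp, a1, a2, eaf, weight, se`` (``a1`` = effect
    allele; ``eaf`` its frequency in the weight source; ``se`` the weight's
    standard error, kept for MR use). ``offset`` is an additive bookkeeping
    constant accumulated by allele flips so that raw scores are invariant to
    which allele a cohort labels "effect".
    """

    df: pd.DataFrame
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if self.df["snp"].duplicated().any():
            raise DegenerateVarianceError("duplicate snp_id in WeightSet")
        w = self.df["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)):
            bad = self.df.loc[~np.isfinite(w), "snp"].tolist()
            raise DegenerateVarianceError(f"non-finite weight(s) for {bad[:5]}")

    def __len__(self) -> int:
        return len(self.df)


def estimate_beta_from_z(stats: SummaryStats) -> WeightSet:
    """Per-allele effect sizes on the standardized trait from z statistics.

    For a standardized trait, ``beta = z / sqrt(2 p (1-p) (n + z^2))`` and
    ``se = 1 / sqrt(2 p (1-p) (n + z^2))`` where ``p`` is the effect-allele
    frequency and ``n`` the GWAS sample size.

    Raises
    ------
    DegenerateVarianceError
        if any record has eaf of 0 or 1 (zero allelic variance), naming
        the SNP.
    """
    df = stats.df
    z = stats.zscores().to_numpy(float)
    eaf = df["eaf"].to_numpy(float)
    n = df["n"].to_numpy(float)
    if np.any(np.isnan(z)) or np.any(np.isnan(eaf)) or np.any(np.isnan(n)):
        bad = df.loc[np.isnan(z) | np.isnan(eaf) | np.isnan(n), "snp"].tolist()
        raise DegenerateVarianceError(
            f"records lacking z/eaf/n needed for effect-size estimation: {bad[:5]}"
        )
    degenerate = (eaf <= 0) | (eaf >= 1)
    if degenerate.any():
        bad = df.loc[degenerate, "snp"].tolist()
        raise DegenerateVarianceError(
            f"eaf of 0 or 1 gives zero variance for SNP(s) {bad[:5]}"
        )
    denom = np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z**2))
    out = pd.DataFrame(
        {
            "snp": df["snp"],
            "a1": df["a1"],
            "a2": df["a2"],
            "eaf": eaf,
            "weight": z / denom,
            "se": 1.0 / denom,
        }
    )
    return WeightSet(out)


def weights_from_stats(stats: SummaryStats, use_reported_beta: bool = True) -> WeightSet:
    """Build a WeightSet from a summary-statistic table.

    Reported per-allele betas are used where present (and
    ``use_reported_beta``); otherwise effect sizes are derived from z/eaf/n
    via :func:`estimate_beta_from_z`.
    """
    df = stats.df
    if use_reported_beta and df["beta"].notna().all() and df["se"].notna().all():
        out = df[["snp", "a1", "a2", "eaf"]].copy()
        out["weight"] = df["beta"].to_numpy(float)
        out["se"] = df["se"].to_numpy(float)
        return WeightSet(out)
    return estimate_beta_from_z(stats)


def exclude_snps(weights: WeightSet, snp_ids) -> WeightSet:
    """Remove the listed SNPs from a WeightSet (absent ids ignored, warned)."""
    snp_ids = list(snp_ids)
    present = set(weights.df["snp"])
    unknown = [s for s in snp_ids if s not in present]
    if unknown:
        logger.warning("exclude_snps: %d id(s) not in WeightSet (ignored): %s",
                       len(unknown), unknown[:5])
    keep = ~weights.df["snp"].isin(set(snp_ids))
    removed = int((~keep).sum())
    logger.info("exclude_snps: removed %d of %d weights", removed, len(weights))
    return WeightSet(weights.df[keep], offset=weights.offset)


def is_palindromic(a1, a2) -> np.ndarray:
    a1 = np.asarray(a1, dtype=object)
    a2 = np.asarray(a2, dtype=object)
    return np.fromiter(
        ((x, y) in PALINDROMIC_PAIRS for x, y in zip(a1, a2)),
        dtype=bool, count=len(a1),
    )


def align_alleles(weights: WeightSet, variants: pd.DataFrame,
                  drop_palindromic: bool = True) -> WeightSet:
    """Re-express weights on the dataset's effect-allele coding.

    For shared SNPs where the dataset's effect allele equals the weight's
    *other* allele, the weight is negated and ``2*w`` added to the offset,
    which leaves ``offset + sum_j w_j d_js`` numerically identical to the
    original coding. Palindromic (A/T, C/G) SNPs are excluded by default
    because strand cannot be resolved. Irreconcilable allele pairs raise.

    The returned WeightSet follows the variant order of ``variants`` and
    carries ``eaf`` re-expressed for the dataset's effect allele.
    """
    v = variants[["snp", "a1", "a2"]].rename(
        columns={"a1": "a1_d", "a2": "a2_d"}
    )
    m = v.merge(weights.df, on="snp", how="inner")
    if len(m) == 0:
        return WeightSet(
            pd.DataFrame(columns=["snp", "a1", "a2", "eaf", "weight", "se"]),
            offset=weights.offset,
        )
    same = (m["a1"] == m["a1_d"]) & (m["a2"] == m["a2_d"])
    swapped = (m["a1"] == m["a2_d"]) & (m["a2"] == m["a1_d"])
    mismatch = ~(same | swapped)
    if mismatch.any():
        bad = m.loc[mismatch, ["snp", "a1", "a2", "a1_d", "a2_d"]]
        first = bad.iloc[0]
        raise AlleleMismatchError(
            f"irreconcilable alleles for SNP {first['snp']!r}: "
            f"{first['a1']}/{first['a2']} vs {first['a1_d']}/{first['a2_d']}"
            + (f" (+{len(bad) - 1} more)" if len(bad) > 1 else "")
        )
    pal = is_palindromic(m["a1_d"], m["a2_d"])
    if drop_palindromic and pal.any():
        logger.warning("align_alleles: excluded %d palindromic SNP(s): %s",
                       int(pal.sum()), m.loc[pal, "snp"].tolist()[:5])
        m = m[~pal]
        same, swapped = same[~pal], swapped[~pal]
    w = m["weight"].to_numpy(float)
    eaf = m["eaf"].to_numpy(float)
    flipped = swapped.to_numpy()
    offset = weights.offset + float(np.sum(2.0 * w[flipped]))
    out = pd.DataFrame(
        {
            "snp": m["snp"].to_numpy(),
            "a1": m["a1_d"].to_numpy(),
            "a2": m["a2_d"].to_numpy(),
            "eaf": np.where(flipped, 1.0 - eaf, eaf),
            "weight": np.where(flipped, -w, w),
            "se": m["se"].to_numpy(float),
        }
    )
    return WeightSet(out, offset=offset)


@dataclass
class ScoreResult:
    """Per-sample raw and standardized gIQ with optional tertile labels."""

    sample_ids: np.ndarray
    raw_score: np.ndarray
    z_score: np.ndarray
    tertile: np.ndarray | None = None
    n_imputed_entries: int = 0
    n_snps_used: int = 0
    n_snps_skipped: int = 0

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_score": self.raw_score,
                "z_score": self.z_score,
            }
        )
        if self.tertile is not None:
            out["tertile"] = self.tertile
        return out


def compute_score(data: DosageDataset, weights: WeightSet,
                  freq_source: str = "weights",
                  drop_palindromic: bool = True) -> ScoreResult:
    """Weighted allele sum per sample, z-standardized within the dataset.

    Missing dosages are imputed by the expected dosage ``2*eaf`` of the
    dataset's effect allele; ``freq_source`` selects whether that frequency
    comes from the weight source's eaf column (default) or from the cohort's
    observed dosage mean (``"cohort"``). Weight SNPs absent from the dataset
    are skipped with a logged count.

    Raises
    ------
    EmptyInstrumentError  if no weight SNP overlaps the dataset.
    DegenerateScoreError  if the raw score has zero variance.
    """
    if freq_source not in ("weights", "cohort"):
        raise ValueError(f"freq_source must be 'weights' or 'cohort', got {freq_source!r}")
    aligned = align_alleles(weights, data.variants, drop_palindromic=drop_palindromic)
    if len(aligned) == 0:
        raise EmptyInstrumentError("no overlapping instrument SNPs between "
                                   "weights and dataset")
    n_skipped = len(weights) - len(aligned)
    if n_skipped:
        logger.info("compute_score: skipped %d weight SNP(s) (absent or "
                    "palindromic)", n_skipped)

    idx = pd.Index(data.variants["snp"]).get_indexer(aligned.df["snp"])
    D = data.dosages[idx].copy()

    eaf = aligned.df["eaf"].to_numpy(float)
    if freq_source == "cohort" or np.any(np.isnan(eaf)):
        if freq_source == "weights" and np.any(np.isnan(eaf)):
            logger.warning("compute_score: weight eaf missing for some SNPs; "
                           "falling back to cohort frequencies")
        with np.errstate(invalid="ignore"):
            cohort_eaf = np.nanmean(D, axis=1) / 2.0
        eaf = np.where(np.isnan(eaf) | (freq_source == "cohort"), cohort_eaf, eaf)

    miss = np.isnan(D)
    n_imputed = int(miss.sum())
    if n_imputed:
        fill = np.broadcast_to((2.0 * eaf)[:, None], D.shape)
        D[miss] = fill[miss]

    w = aligned.df["weight"].to_numpy(float)
    raw = aligned.offset + w @ D
    sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    if sd == 0.0:
        raise DegenerateScoreError("raw score has zero variance; cannot "
                                   "standardize")
    z = (raw - raw.mean()) / sd
    return ScoreResult(
        sample_ids=data.samples["sample_id"].to_numpy(),
        raw_score=raw,
        z_score=z,
        n_imputed_entries=n_imputed,
        n_snps_used=len(aligned),
        n_snps_skipped=n_skipped,
    )


def tertile_groups(score: ScoreResult) -> ScoreResult:
    """Rank-based split into low/medium/high groups of near-equal size.

    Group sizes differ by at most one; when n is not divisible by 3 the
    extra samples go to the lower groups first (deterministic). Ties are
    broken by stable sample order.
    """
    n = len(score)
    if n < 3:
        raise InsufficientSamplesError(f"tertile grouping needs >=3 samples, got {n}")
    if np.ptp(score.raw_score) == 0:
        logger.warning("tertile_groups: all scores equal; split follows "
                       "stable sample order")
    order = np.argsort(score.z_score, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for lab, size in zip(TERTILE_LABELS, sizes):
        labels[order[start:start + size]] = lab
        start += size
    return replace(score, tertile=labels)
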