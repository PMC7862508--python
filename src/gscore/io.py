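"""Tabular I/O: GWAS summary statistics, dosage matrices, sample sheets, results.

On-disk dialect is tab-delimited UTF-8 with a header row (comma accepted on
read). Dosages may alternatively be supplied as an uncompressed VCF with a
FORMAT/DS field. Missing values are written as empty fields and read back as
missing; floats survive a write/read round trip to 12 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: canonical column names of the summary-statistic dialect (left: on-disk)
SUMSTAT_COLUMNS = {
    "SNP": "snp",
    "A1": "a1",
    "A2": "a2",
    "FREQ": "eaf",
    "BETA": "beta",
    "SE": "se",
    "Z": "z",
    "P": "p",
    "N": "n",
}
_SUMSTAT_NUMERIC = ("eaf", "beta", "se", "z", "p", "n")
_SUMSTAT_ALL = ("snp", "a1", "a2", "eaf", "beta", "se", "z", "p", "n")


@dataclass
class SummaryStats:
    """Per-SNP association records for one trait from one consortium.

    ``df`` holds the canonical columns ``snp, a1, a2, eaf, beta, se, z, p, n``
    (absent quantities are NaN). ``a1`` is the effect allele. Each record must
    carry either ``beta``+``se`` or ``z``+``eaf``+``n``; the missing pair is
    derivable downstream.
    """

    trait: str
    df: pd.DataFrame
    cohort: str | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _SUMSTAT_ALL:
            if col not in df.columns:
                df[col] = "" if col in ("snp", "a1", "a2") else np.nan
        for col in _SUMSTAT_NUMERIC:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self.df = df[list(_SUMSTAT_ALL)].reset_index(drop=True)
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
            raise ValidationError(f"duplicate snp_id in {self.trait!r}: {dups[:5]}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def zscores(self) -> pd.Series:
        """z statistics, derived from beta/se where not reported directly."""
        z = self.df["z"].copy()
        m = z.isna() & self.df["beta"].notna() & self.df["se"].notna()
        z[m] = self.df.loc[m, "beta"] / self.df.loc[m, "se"]
        return z

    def write(self, path) -> None:
        out = self.df.rename(columns={v: k for k, v in SUMSTAT_COLUMNS.items()})
        out.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="")


def _clean_sumstat_rows(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Row-level validation: drop malformed rows, logging their row numbers.

    Validation is total — a row is either kept intact or dropped with a
    reason; nothing is silently coerced.
    """
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in _SUMSTAT_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan

    ok_alleles = (
        df["a1"].isin(_BASES) & df["a2"].isin(_BASES) & (df["a1"] != df["a2"])
    )
    ok_eaf = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    ok_se = df["se"].isna() | (df["se"] > 0)
    ok_p = df["p"].isna() | ((df["p"] > 0) & (df["p"] <= 1))
    ok_n = df["n"].isna() | (df["n"] > 0)
    has_beta = df["beta"].notna() & df["se"].notna()
    has_z = df["z"].notna() & df["eaf"].notna() & df["n"].notna()
    ok_scheme = has_beta | has_z

    keep = ok_alleles & ok_eaf & ok_se & ok_p & ok_n & ok_scheme
    if not keep.all():
        bad = df.index[~keep] + 2  # 1-based file rows incl. header
        logger.warning(
            "%s: dropped %d malformed row(s) at file line(s) %s",
            source, int((~keep).sum()), list(bad[:10]),
        )
    df = df[keep]
    dup = df["snp"].duplicated()
    if dup.any():
        logger.warning(
            "%s: dropped %d duplicate snp_id row(s): %s",
            source, int(dup.sum()), df.loc[dup, "snp"].tolist()[:5],
        )
        df = df[~dup]
    return df.reset_index(drop=True)


def read_summary_stats(path, column_map: dict | None = None,
                       trait: str | None = None,
                       cohort: str | None = None) -> SummaryStats:
    """Read a tab- or comma-delimited GWAS summary-statistic table.

    Parameters
    ----------
    path : file path
    column_map : optional mapping from the file's column names to the
        canonical names (``snp, a1, a2, eaf, beta, se, z, p, n`` or their
        upper-case on-disk spellings ``SNP, A1, A2, FREQ, BETA, SE, Z, P, N``).
    trait, cohort : labels attached to the returned object.

    Raises
    ------
    FormatError
        when a mandatory column (snp/a1/a2, plus beta+se or z+eaf+n) is
        absent after remapping.
    """
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    raw = raw.rename(
        columns={c: SUMSTAT_COLUMNS.get(c.upper(), c.lower()) for c in raw.columns}
    )
    for col in ("snp", "a1", "a2"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if not ({"beta", "se"} <= set(raw.columns)
            or {"z", "eaf", "n"} <= set(raw.columns)):
        raise FormatError(
            f"{path}: need columns BETA+SE or Z+FREQ+N to define effects"
        )
    df = _clean_sumstat_rows(raw, str(path))
    return SummaryStats(trait=trait or "trait", df=df, cohort=cohort)


@dataclass
class DosageDataset:
    """SNP x sample effect-allele dosages plus variant and sample metadata.

    ``variants``: DataFrame with ``snp, a1, a2, ref_eaf`` (a1 = the allele
    the dosage counts). ``dosages``: float array (n_variants, n_samples),
    entries in [0, 2], NaN = missing. ``samples``: one row per sample,
    aligned to the dosage columns, keyed by ``sample_id``.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        nv, ns = self.dosages.shape
        if nv != len(self.variants):
            raise ValidationError(
                f"dosage rows ({nv}) != variant rows ({len(self.variants)})"
            )
        if ns != len(self.samples):
            raise ValidationError(
                f"dosage columns ({ns}) != sample rows ({len(self.samples)})"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0,2] at variant {self.variants['snp'].iloc[i]!r}, "
                f"sample {self.samples['sample_id'].iloc[j]!r}: "
                f"{self.dosages[i, j]}"
            )
        if self.samples["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        if self.variants["snp"].duplicated().any():
            raise ValidationError("duplicate snp_id in dosage matrix")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape


def _detect_sep(path) -> str:
    """Tab or comma, judged from the header line (the csv sniffer cannot
    handle single-column files)."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header or "," not in header else ","


def read_table(path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table with a header row."""
    return pd.read_csv(path, sep=_detect_sep(path))


def _read_sample_sheet(path) -> pd.DataFrame:
    sheet = read_table(path)
    if "sample_id" not in sheet.columns:
        raise FormatError(f"{path}: sample sheet must have a 'sample_id' column")
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id in sample sheet")
    return sheet


def _read_vcf_dosages(path):
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    rows, meta = [], []
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            raise ValidationError(f"{path}: variant {rec.id} is not biallelic")
        ds = []
        for s in sample_ids:
            v = rec.samples[s].get("DS")
            ds.append(np.nan if v is None else float(v))
        af = rec.info.get("AF")
        ref_eaf = float(af[0]) if af is not None else np.nan
        meta.append(
            {"snp": rec.id, "a1": str(alts[0]).upper(),
             "a2": str(rec.ref).upper(), "ref_eaf": ref_eaf}
        )
        rows.append(ds)
    variants = pd.DataFrame(meta)
    dosages = np.asarray(rows, dtype=float)
    return variants, dosages, sample_ids


def _read_matrix_dosages(path):
    df = read_table(path)
    df = df.rename(
        columns={c: SUMSTAT_COLUMNS.get(c.upper(), c) for c in df.columns}
    )
    for col in ("snp", "a1", "a2"):
        if col not in df.columns:
            raise FormatError(f"{path}: dosage matrix missing column {col!r}")
    id_cols = [c for c in ("snp", "a1", "a2", "eaf") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in id_cols]
    if not sample_cols:
        raise FormatError(f"{path}: dosage matrix has no sample columns")
    variants = pd.DataFrame(
        {
            "snp": df["snp"].astype(str),
            "a1": df["a1"].astype(str).str.upper(),
            "a2": df["a2"].astype(str).str.upper(),
            "ref_eaf": pd.to_numeric(df["eaf"], errors="coerce")
            if "eaf" in df.columns else np.nan,
        }
    )
    dos = df[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    return variants, dos, [str(c) for c in sample_cols]


def read_dosages(path, sample_sheet) -> DosageDataset:
    """Read a dosage matrix (TSV with SNP rows / sample columns, or VCF with
    FORMAT/DS) together with its sample sheet.

    The returned dataset is ordered by the sample sheet (restricted to
    samples present in the matrix); samples present in the matrix but absent
    from the sheet raise, listing the orphan ids. Missing ref_eaf is filled
    from the observed mean dosage / 2.
    """
    if str(path).endswith((".vcf", ".vcf.gz")):
        variants, dos, matrix_ids = _read_vcf_dosages(path)
    else:
        variants, dos, matrix_ids = _read_matrix_dosages(path)
    sheet = _read_sample_sheet(sample_sheet)

    orphans = [s for s in matrix_ids if s not in set(sheet["sample_id"])]
    if orphans:
        raise ValidationError(
            f"samples in dosage matrix but not in sample sheet: {orphans[:10]}"
        )
    keep = sheet[sheet["sample_id"].isin(set(matrix_ids))].reset_index(drop=True)
    dropped = len(sheet) - len(keep)
    if dropped:
        logger.warning("sample sheet has %d sample(s) without dosages; dropped",
                       dropped)
    order = [matrix_ids.index(s) for s in keep["sample_id"]]
    dos = dos[:, order]
    missing_eaf = variants["ref_eaf"].isna()
    if missing_eaf.any():
        with np.errstate(invalid="ignore"):
            est = np.nanmean(dos, axis=1) / 2.0
        variants.loc[missing_eaf, "ref_eaf"] = est[missing_eaf.to_numpy()]
    return DosageDataset(variants=variants, dosages=dos, samples=keep)


# ---------------------------------------------------------------------------
# result serialization

def write_results(obj, path) -> None:
    """Serialize an AssocResult, MetaResult or MRResult to delimited text.

    Fixed column order, empty field for missing values; floats printed with
    12 significant digits so that read_results reproduces the object to that
    precision.
    """
    frame = obj.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="")


def read_results(path, kind: str):
    """Read a results table written by :func:`write_results`.

    ``kind`` is one of ``assoc``, ``meta``, ``mr``.
    """
    from . import assoc, meta, mr  # local import to avoid cycles

    classes = {"assoc": assoc.AssocResult, "meta": meta.MetaResult,
               "mr": mr.MRResult}
    if kind not in classes:
        raise ValueError(f"unknown results kind {kind!r}")
    frame = pd.read_csv(path, sep="\t")
    return classes[kind].from_frame(frame)
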