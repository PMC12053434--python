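"""Readers and writers for the tabular and genomic formats used by the pipeline.

Conventions
-----------
* Methylation matrices are TSV, UTF-8, tab-delimited; the first column is
  named ``site`` and holds ``chrom:pos`` keys with a 1-based position
  (per-cytosine, CGmap style).  Values are methylation fractions in [0, 1],
  written with 6 decimal places.
* Sample metadata is TSV with documented column names; booleans are written
  ``yes``/``no``; categorical fields are matched case-insensitively.
* Region sets are standard BED6 (0-based, half-open); site keys are converted
  on export so that a site at 1-based position ``p`` spans ``[p-1, p)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "validate_methylation_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "validate_sample_metadata",
    "read_regions_bed",
    "write_regions_bed",
    "parse_site_key",
    "site_key",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# --------------------------------------------------------------------------
# site keys
# --------------------------------------------------------------------------

def site_key(chrom: str, pos: int) -> str:
    """Build a ``chrom:pos`` site key (1-based position)."""
    return f"{chrom}:{int(pos)}"


def parse_site_key(key: str) -> tuple[str, int]:
    """Split a ``chrom:pos`` key into (chrom, 1-based position)."""
    chrom, _, pos = key.rpartition(":")
    if not chrom or not pos:
        raise ValidationError(f"malformed site key {key!r}; expected 'chrom:pos'")
    try:
        p = int(pos)
    except ValueError as exc:
        raise ValidationError(f"malformed site key {key!r}; position not an integer") from exc
    if p < 1:
        raise ValidationError(f"site key {key!r} has non-positive position (keys are 1-based)")
    return chrom, p


# --------------------------------------------------------------------------
# methylation matrix
# --------------------------------------------------------------------------

def validate_methylation_matrix(df: pd.DataFrame, allow_incomplete: bool = False) -> pd.DataFrame:
    """Validate a site x sample methylation-fraction matrix.

    Parameters
    ----------
    df : DataFrame
        Rows indexed by ``chrom:pos`` site keys, columns are sample ids.
    allow_incomplete : bool
        If True, rows containing missing values are dropped (count reported
        in a warning) instead of raising.  The default enforces completeness.

    Returns
    -------
    DataFrame
        The validated (possibly row-filtered) matrix, values as float64.
    """
    if df.shape[0] == 0:
        raise ValidationError("no sites: methylation matrix has an empty data section")
    if df.shape[1] == 0:
        raise ValidationError("no samples: methylation matrix has no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate site key {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    for key in df.index:
        parse_site_key(str(key))

    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric methylation value: {exc}") from exc

    missing = ~np.isfinite(values) & np.isnan(values)
    if missing.any():
        if allow_incomplete:
            bad_rows = missing.any(axis=1)
            warnings.warn(
                f"dropping {int(bad_rows.sum())} incomplete site(s) "
                f"of {df.shape[0]} (allow_incomplete=True)",
                stacklevel=2,
            )
            df = df.loc[~bad_rows]
            values = df.to_numpy(dtype=float)
            if df.shape[0] == 0:
                raise ValidationError("no sites remain after dropping incomplete rows")
        else:
            i, j = np.argwhere(missing)[0]
            raise ValidationError(
                f"missing methylation value at site {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    out_of_range = ~np.isfinite(values) | (values < 0.0) | (values > 1.0)
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise ValidationError(
            f"methylation value {values[i, j]!r} out of [0, 1] at site "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(float)


def read_methylation_matrix(path, allow_incomplete: bool = False) -> pd.DataFrame:
    """Read a TSV methylation matrix (first column ``site``, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return validate_methylation_matrix(df, allow_incomplete=allow_incomplete)


def write_methylation_matrix(df: pd.DataFrame, path) -> None:
    """Write a methylation matrix as TSV with 6 decimal places."""
    out = df.copy()
    out.index.name = "site"
    out.to_csv(path, sep="\t", float_format="%.6f")


# --------------------------------------------------------------------------
# sample metadata
# --------------------------------------------------------------------------

_CATEGORICAL = {
    "sex": {"m": "M", "f": "F"},
    "cmv": {"positive": "positive", "negative": "negative", "pos": "positive", "neg": "negative"},
    "transplant": {"pre": "pre", "post": "post"},
    "atg": {"yes": "yes", "no": "no"},
    "infection_risk": {"yes": "yes", "no": "no"},
    "event_observed": {"yes": "yes", "no": "no", "true": "yes", "false": "no"},
}

REQUIRED_METADATA_COLUMNS = (
    "subject_id",
    "sample_id",
    "age",
    "sex",
    "cmv",
    "transplant",
    "atg",
    "infection_risk",
)


def validate_sample_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample metadata table.

    Categorical fields are mapped case-insensitively onto their canonical
    vocabularies; ancestry PCs are any columns named ``ancestry_pc*``.
    """
    df = df.copy()
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing required column(s): {missing_cols}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")

    for col, vocab in _CATEGORICAL.items():
        if col not in df.columns:
            continue
        raw = df[col]
        mapped = []
        for sample, val in zip(df["sample_id"], raw):
            if pd.isna(val):
                mapped.append(np.nan)
                continue
            k = str(val).strip().lower()
            if k not in vocab:
                allowed = sorted(set(vocab.values()))
                raise ValidationError(
                    f"unknown value {val!r} for {col!r} (sample {sample!r}); "
                    f"allowed: {allowed}"
                )
            mapped.append(vocab[k])
        df[col] = mapped

    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any():
        bad = df.loc[ages.isna() | (ages < 0), "sample_id"].iloc[0]
        raise ValidationError(f"age must be a nonnegative number (sample {bad!r})")
    df["age"] = ages.astype(float)

    counts = df.groupby("subject_id")["sample_id"].count()
    if (counts > 2).any():
        raise ValidationError(
            f"subject {counts.idxmax()!r} contributes {counts.max()} samples (max 2: pre/post)"
        )

    if "days_to_infection" in df.columns:
        days = pd.to_numeric(df["days_to_infection"], errors="coerce")
        if ((days < 0) & days.notna()).any():
            raise ValidationError("days_to_infection must be nonnegative")
        df["days_to_infection"] = days
        if "event_observed" in df.columns:
            ev = df["event_observed"] == "yes"
            no_time = ev & days.isna()
            if no_time.any():
                bad = df.loc[no_time, "sample_id"].iloc[0]
                raise ValidationError(
                    f"event_observed is true but days_to_infection missing (sample {bad!r})"
                )
    return df


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a TSV sample metadata table and validate it."""
    return validate_sample_metadata(pd.read_csv(path, sep="\t", dtype={"subject_id": str, "sample_id": str}))


def write_sample_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def join_metadata(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Align metadata rows to matrix sample columns.

    Samples present in the metadata but absent from the matrix are allowed
    (warned); samples in the matrix without metadata are an error.
    """
    meta = metadata.set_index("sample_id", drop=False)
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"sample(s) in matrix absent from metadata: {missing[:5]}")
    extra = [s for s in meta.index if s not in matrix.columns]
    if extra:
        warnings.warn(f"{len(extra)} metadata sample(s) not in matrix (ignored)", stacklevel=2)
    return meta.loc[list(matrix.columns)]


# --------------------------------------------------------------------------
# regions (BED6)
# --------------------------------------------------------------------------

REGION_COLUMNS = ("chrom", "start", "end", "label", "score")


def _validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValidationError(f"region table missing column(s): {missing}")
    bad = regions["start"] >= regions["end"]
    if bad.any():
        row = regions.loc[bad].iloc[0]
        raise ValidationError(
            f"region {row['chrom']}:{row['start']}-{row['end']} has start >= end"
        )
    return regions


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write a region table as BED6 (0-based half-open; score col 5, label col 4)."""
    regions = _validate_regions(regions)
    with open(path, "w", encoding="utf-8") as fh:
        for row in regions.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.label}\t{row.score:g}\t.\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    """Read a BED file into a (chrom, start, end, label, score) table."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            rows.append((chrom, start, end, label, score))
    df = pd.DataFrame(rows, columns=list(REGION_COLUMNS))
    if len(df):
        _validate_regions(df)
    return df
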