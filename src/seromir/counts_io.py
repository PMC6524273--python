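"""Count-matrix and sample-metadata I/O plus the expression filter.

The pipeline starts from a quantified miRNA x sample read-count matrix
(rows = miRBase-style miRNA names, columns = sample IDs) and a metadata
table with one row per sample (group, age, gender, BMI).  Upstream read
processing (trimming, alignment, quantification) is out of scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Study groups: pancreatic cancer, biliary tract cancer, healthy control.
DEFAULT_GROUPS: tuple[str, ...] = ("PC", "BTC", "HC")

#: Required metadata columns (besides the sample_id index).
METADATA_COLUMNS: tuple[str, ...] = ("group", "age", "gender", "bmi")

GENDERS: tuple[str, ...] = ("M", "F")


class ValidationError(ValueError):
    """Raised when a count matrix or metadata table violates its contract."""


@dataclasses.dataclass
class CountMatrix:
    """Raw integer read counts (miRNA x sample) with per-sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, index = miRNA IDs, columns = sample IDs.
    metadata
        DataFrame indexed by sample ID with columns ``group``, ``age``,
        ``gender`` and ``bmi``.  ``age``/``bmi`` may be missing (NaN) only
        if downstream models are run without them; counts may not.
    allowed_groups
        Label set the ``group`` column must be drawn from.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    allowed_groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.metadata = pd.DataFrame(self.metadata)
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate miRNA IDs: {dup}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                bad = self._first_bad_cell(lambda v: not _is_integral(v))
                raise ValidationError(f"non-integer count at {bad}")
            if np.isnan(values.astype(float)).any():
                bad = self._first_bad_cell(lambda v: pd.isna(v))
                raise ValidationError(f"missing count value at {bad}")
            if (values < 0).any():
                bad = self._first_bad_cell(lambda v: v < 0)
                raise ValidationError(f"negative count at {bad}")
            if not np.allclose(values, np.round(values.astype(float))):
                bad = self._first_bad_cell(lambda v: not _is_integral(v))
                raise ValidationError(f"non-integer count at {bad}")
        self.counts = counts.astype(np.int64)

        missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {missing_cols}")
        if meta.index.duplicated().any():
            dup = meta.index[meta.index.duplicated()].tolist()
            raise ValidationError(f"duplicate metadata sample IDs: {dup}")
        absent = [s for s in counts.columns if s not in meta.index]
        if absent:
            raise ValidationError(f"samples without metadata: {absent}")
        # align metadata to count-matrix sample order
        self.metadata = meta.loc[list(counts.columns)]
        bad_groups = sorted(
            set(self.metadata["group"]) - set(self.allowed_groups)
        )
        if bad_groups:
            raise ValidationError(
                f"unknown group labels {bad_groups}; "
                f"allowed: {list(self.allowed_groups)}"
            )
        bad_gender = sorted(
            set(self.metadata["gender"].dropna()) - set(GENDERS)
        )
        if bad_gender:
            raise ValidationError(f"unknown gender codes {bad_gender}")

    def _first_bad_cell(self, predicate) -> str:
        for mirna, row in self.counts.iterrows():
            for sample, v in row.items():
                try:
                    if predicate(v):
                        return f"(miRNA={mirna!r}, sample={sample!r})"
                except TypeError:
                    return f"(miRNA={mirna!r}, sample={sample!r})"
        return "(unknown)"

    # -- convenience ------------------------------------------------------
    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_mirnas(self, ids: Sequence[str]) -> "CountMatrix":
        missing = [i for i in ids if i not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown miRNA IDs: {missing}")
        return CountMatrix(
            self.counts.loc[list(ids)], self.metadata, self.allowed_groups
        )


def read_counts(
    counts_path: str | Path,
    metadata_path: str | Path,
    allowed_groups: tuple[str, ...] = DEFAULT_GROUPS,
) -> CountMatrix:
    """Read a counts TSV and metadata TSV into a validated :class:`CountMatrix`.

    The counts file is tab-separated with the miRNA ID in the first column
    and sample IDs in the header; the metadata file has a ``sample_id``
    column plus ``group``, ``age``, ``gender``, ``bmi``.  Sample order is
    taken from the counts header; metadata is joined by sample ID.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate metadata sample IDs: {dup}")
    meta = meta.set_index("sample_id")
    return CountMatrix(counts, meta, allowed_groups)


def write_counts(
    cm: CountMatrix,
    counts_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write counts (and optionally metadata) back to TSV."""
    cm.counts.to_csv(counts_path, sep="\t", index_label="mirna_id")
    if metadata_path is not None:
        cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def filter_expressed(
    cm: CountMatrix, min_reads: int = 10, min_samples: int = 2
) -> CountMatrix:
    """Keep miRNAs expressed (> ``min_reads`` reads) in >= ``min_samples`` samples.

    The comparison is strict: a count must exceed ``min_reads`` to qualify.
    Sample set and the order of retained miRNAs are unchanged; an empty
    result is valid.
    """
    if min_reads < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    expressed = (cm.counts > min_reads).sum(axis=1) >= min_samples
    return CountMatrix(
        cm.counts.loc[expressed], cm.metadata, cm.allowed_groups
    )


def _is_integral(v) -> bool:
    try:
        return float(v) == int(v) and not pd.isna(v)
    except (TypeError, ValueError):
        return False
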