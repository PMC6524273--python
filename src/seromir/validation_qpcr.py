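"""Independent-cohort validation by per-miRNA two-group t tests.

Consumes an already-normalized expression table (e.g. qRT-PCR derived;
Ct-to-expression preprocessing is out of scope) and compares cancer vs
control levels per miRNA with a two-sided Welch unequal-variance t test
(Student's pooled-variance variant selectable).  No multiplicity
correction is applied: the module reports raw p-values for a handful of
pre-selected candidates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def ttest_per_mirna(
    expr_table: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    positive: str = "cancer",
    variant: str = "welch",
) -> pd.DataFrame:
    """Two-sided two-sample t test per miRNA (columns of ``expr_table``).

    ``expr_table`` is samples x miRNAs; ``labels`` assigns each sample to
    one of exactly two groups, ``positive`` (default "cancer") and the
    other (control).  Missing values are dropped per miRNA; a miRNA with
    fewer than 2 usable values in either group is flagged untested.
    Direction is "up"/"down" in the positive group by the sign of the
    mean difference.
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    if isinstance(labels, pd.Series) and set(expr_table.index).issubset(
        labels.index
    ):
        labels = labels.reindex(expr_table.index)
    else:
        if len(labels) != len(expr_table):
            raise ValueError("labels length does not match the sample count")
        labels = pd.Series(np.asarray(labels), index=expr_table.index)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    if positive not in groups:
        raise ValueError(f"positive group {positive!r} not among {groups}")
    negative = next(g for g in groups if g != positive)

    rows = []
    for mirna in expr_table.columns:
        a = expr_table.loc[labels == positive, mirna].dropna()
        b = expr_table.loc[labels == negative, mirna].dropna()
        rec = {
            "mirna_id": mirna,
            "n_positive": len(a),
            "n_negative": len(b),
            "mean_positive": float(a.mean()) if len(a) else np.nan,
            "mean_negative": float(b.mean()) if len(b) else np.nan,
        }
        if len(a) < 2 or len(b) < 2:
            rec.update(
                t_statistic=np.nan, p_value=np.nan, mean_difference=np.nan,
                direction="", tested=False,
            )
        else:
            res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
            diff = float(a.mean() - b.mean())
            rec.update(
                t_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                mean_difference=diff,
                direction="up" if diff > 0 else ("down" if diff < 0 else ""),
                tested=True,
            )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("mirna_id")
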