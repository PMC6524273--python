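"""Between-sample normalization: TMM scaling factors and log2-CPM.

TMM (trimmed mean of M-values) estimates one scaling factor per sample
from doubly trimmed, precision-weighted log-ratios against a reference
sample, so that compositional shifts (a few very abundant miRNAs) do not
masquerade as depth differences.  All downstream modules (PCA, clustering,
KNN) consume log2 counts-per-million computed on the TMM-effective
library sizes with a pseudocount.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counts_io import CountMatrix


@dataclasses.dataclass
class NormalizedExpression:
    """log2-CPM expression matrix plus the TMM factors that produced it.

    Invariants: TMM factors are positive with geometric mean 1; the
    log2-CPM matrix is finite everywhere.
    """

    log2cpm: pd.DataFrame          # miRNA x sample
    tmm_factors: pd.Series         # per sample, geometric mean 1
    library_sizes: pd.Series       # per sample raw column sums

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = float(np.mean(np.log(self.tmm_factors.to_numpy())))
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")
        if not np.isfinite(self.log2cpm.to_numpy()).all():
            raise ValueError("log2-CPM must be finite everywhere")

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log2cpm.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.log2cpm.index)


def tmm_factors(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM scaling factors.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean of those fractions.  For each sample, M-values
    (log2 ratio of count fractions vs the reference) and A-values (mean
    log2 abundance) are computed over miRNAs nonzero in both samples,
    doubly trimmed two-sided (``trim_m`` of the M distribution, ``trim_a``
    of the A distribution), and the factor is 2**(precision-weighted mean
    of the remaining M-values), with inverse asymptotic binomial variances
    as weights.  Factors are rescaled to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    zero_lib = [s for s, n in zip(cm.sample_ids, lib) if n <= 0]
    if zero_lib:
        raise ValueError(f"samples with zero library size: {zero_lib}")

    f75 = np.percentile(counts, 75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.empty(counts.shape[1])
    for s in range(counts.shape[1]):
        log_factors[s] = _pairwise_log2_factor(
            counts[:, s], counts[:, ref], lib[s], lib[ref],
            trim_m, trim_a, cm.sample_ids[s],
        )
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=cm.sample_ids, name="tmm_factor")


def _pairwise_log2_factor(
    y: np.ndarray, y_ref: np.ndarray, n: float, n_ref: float,
    trim_m: float, trim_a: float, sample_id: str,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    both = (y > 0) & (y_ref > 0)
    if not both.any():
        raise ValueError(
            f"sample {sample_id!r} shares no nonzero miRNA with the reference"
        )
    ys, yr = y[both], y_ref[both]
    ps, pr = ys / n, yr / n_ref
    m = np.log2(ps / pr)
    a = 0.5 * np.log2(ps * pr)
    # asymptotic variance of M (delta method on two binomial proportions)
    var = (n - ys) / (n * ys) + (n_ref - yr) / (n_ref * yr)

    k = m.size
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    lo_m, hi_m = np.floor(k * trim_m) + 1, k - np.floor(k * trim_m)
    lo_a, hi_a = np.floor(k * trim_a) + 1, k - np.floor(k * trim_a)
    keep = (
        (rank_m >= lo_m) & (rank_m <= hi_m)
        & (rank_a >= lo_a) & (rank_a <= hi_a)
    )
    if not keep.any():
        return 0.0
    w = 1.0 / np.maximum(var[keep], 1e-12)
    return float(np.sum(w * m[keep]) / np.sum(w))


def log2cpm(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> NormalizedExpression:
    """log2( count * 1e6 / (library_size * tmm_factor) + pseudocount ).

    With ``factors=None`` the TMM factors are computed first.  A zero
    count with pseudocount 1 maps to 0.
    """
    if factors is None:
        factors = tmm_factors(cm)
    factors = pd.Series(factors).reindex(cm.sample_ids)
    if factors.isna().any():
        missing = factors.index[factors.isna()].tolist()
        raise ValueError(f"factors missing for samples: {missing}")
    if (factors <= 0).any():
        raise ValueError("factors must be positive")
    lib = cm.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        zero = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {zero}")
    eff = lib * factors
    cpm = cm.counts.to_numpy(dtype=float) * 1e6 / eff.to_numpy()
    expr = pd.DataFrame(
        np.log2(cpm + pseudocount),
        index=cm.counts.index,
        columns=cm.counts.columns,
    )
    return NormalizedExpression(
        log2cpm=expr,
        tmm_factors=factors.rename("tmm_factor"),
        library_sizes=lib.astype(int).rename("library_size"),
    )
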