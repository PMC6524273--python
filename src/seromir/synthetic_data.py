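"""Synthetic serum-miRNA cohorts with planted ground truth.

The study this pipeline targets profiled sera from 24 pancreatic-cancer
(PC), 10 biliary-tract-cancer (BTC) and 21 healthy-control (HC) donors,
with ~677 expressed miRNAs of which 42 were group-dysregulated, and that
raw data was never deposited.  This module generates count matrices with
the same statistical structure — NB-distributed counts over heavy-tailed
baseline abundances, unequal library sizes, deliberate covariate
imbalance (cancer donors ~19 years older than controls, group-specific
gender/BMI mixes) and a planted differential-expression signal that is
largely shared between the two cancers — plus a ground-truth record, so
every downstream stage can be tested quantitatively without downloads.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix

#: Cohort demographics: (n, age mean, age sd, male fraction, bmi mean, bmi sd)
GROUP_PROFILES = {
    "PC": dict(age_mean=62.8, age_sd=11.1, male_frac=11 / 24,
               bmi_mean=21.7, bmi_sd=2.9),
    "BTC": dict(age_mean=62.8, age_sd=7.8, male_frac=7 / 10,
                bmi_mean=23.2, bmi_sd=3.9),
    "HC": dict(age_mean=43.9, age_sd=11.8, male_frac=15 / 21,
               bmi_mean=23.8, bmi_sd=3.8),
}

#: Baseline abundance: log-normal CPM, median 100, heavy tail.
BASELINE_LOG_CPM_MEDIAN = np.log(100.0)
BASELINE_LOG_CPM_SIGMA = 1.3
#: DE effects are planted only on miRNAs at or above this baseline CPM so
#: the expression filter cannot remove planted truth.
DE_MIN_BASELINE_CPM = 25.0


def nb_sample(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with mean ``mu`` and variance mu + dispersion * mu**2.

    ``dispersion`` is the NB overdispersion (squared biological CV);
    dispersion 0 degenerates to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion > 0:
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))
    return rng.poisson(mu)


@dataclasses.dataclass
class CovariateSpec:
    """Which fraction of miRNAs responds to each covariate, and how much.

    Continuous effects are log2 units per covariate standard deviation;
    the gender effect is log2 units for male vs female.  Nonzero defaults
    make the covariate-adjusted test meaningfully different from the
    unadjusted one under the age-confounded design.
    """

    age_fraction: float = 0.10
    age_log2_per_sd: float = 0.3
    gender_fraction: float = 0.05
    gender_log2: float = 0.4
    bmi_fraction: float = 0.05
    bmi_log2_per_sd: float = 0.2


@dataclasses.dataclass
class SimTruth:
    """Ground truth sufficient to regenerate the dataset from the seed."""

    de_ids: list[str]
    effects: pd.DataFrame          # de miRNAs x (log2fc_PC, log2fc_BTC)
    baseline_cpm: pd.Series        # all miRNAs
    dispersion: float
    library_sizes: pd.Series       # per sample
    covariate_effects: pd.DataFrame  # all miRNAs x (age, gender, bmi) log2 coefs
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_ids": self.de_ids,
            "effects": self.effects.round(10).to_dict(orient="index"),
            "baseline_cpm": self.baseline_cpm.round(6).to_dict(),
            "dispersion": self.dispersion,
            "library_sizes": self.library_sizes.to_dict(),
            "covariate_effects": self.covariate_effects.round(10).to_dict(
                orient="index"
            ),
            "seed": self.seed,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_cohort(
    n_pc: int = 24,
    n_btc: int = 10,
    n_hc: int = 21,
    n_mirna: int = 677,
    n_de: int = 42,
    log2fc: float = 1.0,
    shared_cancer_effect_fraction: float = 0.8,
    dispersion: float = 0.2,
    libsize_range: tuple[float, float] = (5e5, 2e6),
    covariate_spec: CovariateSpec | None = None,
    n_outliers: int = 0,
    confound: bool = True,
    seed: int | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """NB count matrix + metadata emulating the three-group serum cohort.

    A fraction ``shared_cancer_effect_fraction`` of the ``n_de`` planted
    miRNAs carries the same log2 effect (random sign, magnitude
    ``log2fc``) in both cancer groups — emulating the near-identical
    PC/BTC profiles — while the rest are dysregulated in only one cancer.
    Ages are drawn so controls average ~44 years and cancer donors ~63
    (deliberate confounding; ``confound=False`` draws all ages from the
    HC distribution).  ``n_outliers`` healthy controls (N01, N02, ...)
    can be given cancer-like expression.  Deterministic under ``seed``.
    """
    if n_de > n_mirna:
        raise ValueError("n_de cannot exceed n_mirna")
    if min(n_pc, n_btc, n_hc) < 2:
        raise ValueError("each group needs at least 2 samples")
    if not 0.0 <= shared_cancer_effect_fraction <= 1.0:
        raise ValueError("shared_cancer_effect_fraction must be in [0, 1]")
    if n_outliers > n_hc:
        raise ValueError("more outliers than healthy controls")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    spec = covariate_spec or CovariateSpec()
    rng = np.random.default_rng(seed)

    sample_ids = (
        [f"P{i + 1:02d}" for i in range(n_pc)]
        + [f"B{i + 1:02d}" for i in range(n_btc)]
        + [f"N{i + 1:02d}" for i in range(n_hc)]
    )
    groups = ["PC"] * n_pc + ["BTC"] * n_btc + ["HC"] * n_hc
    meta_rows = []
    for sid, grp in zip(sample_ids, groups):
        prof = GROUP_PROFILES[grp]
        age_prof = prof if confound else GROUP_PROFILES["HC"]
        age = float(
            np.clip(rng.normal(age_prof["age_mean"], age_prof["age_sd"]), 20, 90)
        )
        gender = "M" if rng.random() < prof["male_frac"] else "F"
        bmi = float(np.clip(rng.normal(prof["bmi_mean"], prof["bmi_sd"]), 15, 40))
        meta_rows.append(
            dict(sample_id=sid, group=grp, age=round(age, 1),
                 gender=gender, bmi=round(bmi, 1))
        )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    mirna_ids = [f"sim-mir-{i + 1:04d}" for i in range(n_mirna)]
    baseline_cpm = pd.Series(
        np.exp(rng.normal(BASELINE_LOG_CPM_MEDIAN, BASELINE_LOG_CPM_SIGMA,
                          n_mirna)),
        index=mirna_ids,
        name="baseline_cpm",
    )

    # planted group effects, restricted to reliably expressed miRNAs
    eligible = np.flatnonzero(baseline_cpm.to_numpy() >= DE_MIN_BASELINE_CPM)
    if eligible.size < n_de:
        eligible = np.argsort(baseline_cpm.to_numpy())[-n_de:]
    de_idx = np.sort(rng.choice(eligible, size=n_de, replace=False))
    de_ids = [mirna_ids[i] for i in de_idx]
    n_shared = int(round(shared_cancer_effect_fraction * n_de))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    fc_pc = np.zeros(n_mirna)
    fc_btc = np.zeros(n_mirna)
    which_cancer = rng.random(n_de) < 0.5  # for non-shared effects
    for j, idx in enumerate(de_idx):
        eff = signs[j] * log2fc
        if j < n_shared:
            fc_pc[idx] = eff
            fc_btc[idx] = eff
        elif which_cancer[j]:
            fc_pc[idx] = eff
        else:
            fc_btc[idx] = eff

    # covariate response coefficients (log2 scale)
    cov_coefs = pd.DataFrame(
        0.0, index=mirna_ids, columns=["age", "gender", "bmi"]
    )
    for col, frac, size in (
        ("age", spec.age_fraction, spec.age_log2_per_sd),
        ("gender", spec.gender_fraction, spec.gender_log2),
        ("bmi", spec.bmi_fraction, spec.bmi_log2_per_sd),
    ):
        n_aff = int(round(frac * n_mirna))
        if n_aff:
            affected = rng.choice(n_mirna, size=n_aff, replace=False)
            cov_coefs.iloc[affected, cov_coefs.columns.get_loc(col)] = (
                rng.choice([-1.0, 1.0], size=n_aff) * size
            )

    lib = rng.integers(int(libsize_range[0]), int(libsize_range[1]) + 1,
                       size=len(sample_ids)).astype(float)

    age_z = (metadata["age"] - metadata["age"].mean()) / metadata["age"].std(ddof=0)
    bmi_z = (metadata["bmi"] - metadata["bmi"].mean()) / metadata["bmi"].std(ddof=0)
    male = (metadata["gender"] == "M").astype(float)

    group_fc = np.zeros((n_mirna, len(sample_ids)))
    for s, grp in enumerate(groups):
        if grp == "PC":
            group_fc[:, s] = fc_pc
        elif grp == "BTC":
            group_fc[:, s] = fc_btc
    # cancer-like outliers among the first HC samples
    for s in range(n_pc + n_btc, n_pc + n_btc + n_outliers):
        group_fc[:, s] = fc_pc

    log2_mult = (
        group_fc
        + np.outer(cov_coefs["age"].to_numpy(), age_z.to_numpy())
        + np.outer(cov_coefs["gender"].to_numpy(), male.to_numpy())
        + np.outer(cov_coefs["bmi"].to_numpy(), bmi_z.to_numpy())
    )
    mu = (
        baseline_cpm.to_numpy()[:, None] / 1e6 * lib[None, :]
        * 2.0 ** log2_mult
    )
    counts_df = pd.DataFrame(
        nb_sample(rng, mu, dispersion), index=mirna_ids, columns=sample_ids
    )

    truth = SimTruth(
        de_ids=de_ids,
        effects=pd.DataFrame(
            {"log2fc_PC": fc_pc[de_idx], "log2fc_BTC": fc_btc[de_idx]},
            index=pd.Index(de_ids, name="mirna_id"),
        ),
        baseline_cpm=baseline_cpm,
        dispersion=dispersion,
        library_sizes=pd.Series(lib.astype(int), index=sample_ids,
                                name="library_size"),
        covariate_effects=cov_coefs,
        seed=-1 if seed is None else int(seed),
        params=dict(
            n_pc=n_pc, n_btc=n_btc, n_hc=n_hc, n_mirna=n_mirna, n_de=n_de,
            log2fc=log2fc,
            shared_cancer_effect_fraction=shared_cancer_effect_fraction,
            dispersion=dispersion, libsize_range=list(libsize_range),
            n_outliers=n_outliers, confound=confound,
        ),
    )
    return CountMatrix(counts_df, metadata), truth


def simulate_qpcr(
    n_cancer: int = 34,
    n_control: int = 19,
    mirnas: Sequence[str] = ("mir-128-3p", "mir-409-3p", "mir-744-5p"),
    effect_sizes: Sequence[float] = (1.5, -0.8, -0.6),
    sd: float = 1.0,
    baseline: float = 5.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Gaussian qPCR-style expression table with group shifts.

    Returns (table samples x miRNAs, labels, truth dict); cancer samples
    are shifted by ``effect_sizes`` (in the units of ``sd``-scaled
    expression).  Deterministic under ``seed``.
    """
    if len(mirnas) != len(effect_sizes):
        raise ValueError("effect_sizes must align with mirnas")
    if min(n_cancer, n_control) < 2:
        raise ValueError("each group needs at least 2 samples")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    sample_ids = [f"V{i + 1:02d}" for i in range(n_cancer + n_control)]
    labels = pd.Series(
        ["cancer"] * n_cancer + ["control"] * n_control,
        index=sample_ids, name="group",
    )
    values = rng.normal(
        baseline, sd, size=(n_cancer + n_control, len(mirnas))
    )
    values[:n_cancer] += np.asarray(effect_sizes, dtype=float) * sd
    table = pd.DataFrame(values, index=sample_ids, columns=list(mirnas))
    truth = dict(
        mirnas=list(mirnas),
        effect_sizes=[float(e) for e in effect_sizes],
        sd=float(sd),
        baseline=float(baseline),
        seed=-1 if seed is None else int(seed),
    )
    return table, labels, truth
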