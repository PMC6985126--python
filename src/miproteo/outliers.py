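"""Outlier Z-score analysis against a pCR reference distribution.

Each feature's reference distribution (mean, SD) is estimated from the
pre-treatment cores of patients with a pathological complete response.
Features with low reference variance (< 1.5 on the log2 scale) or whose
reference values reject normality by the Shapiro-Wilk test are ineligible
and yield no Z-score.  Z-scores for non-pCR query cores are the number of
reference SDs by which the core's value deviates from the reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import QuantMatrix

VARIANCE_THRESHOLD = 1.5


@dataclass
class ReferenceDistribution:
    """Per-feature reference statistics from pre-treatment pCR cores."""

    stats: pd.DataFrame  # columns: mean, sd, variance, shapiro_p, eligible
    samples: list[str]
    alpha: float
    variance_threshold: float

    @property
    def eligible(self) -> pd.Series:
        return self.stats["eligible"]


@dataclass
class OutlierResult:
    """Feature x query-sample Z-scores (NaN where ineligible/missing)."""

    z: pd.DataFrame
    eligible: pd.Series
    level: str


def build_reference(
    m: QuantMatrix,
    pcr_baseline_samples: list[str],
    alpha: float = 0.05,
    variance_threshold: float = VARIANCE_THRESHOLD,
    require_normality: bool = True,
) -> ReferenceDistribution:
    """Estimate per-feature reference mean/SD over the pCR baseline cores.

    A feature is eligible when its reference variance is >= the threshold
    and (by default) the Shapiro-Wilk test does not reject normality at
    ``alpha``; ``require_normality=False`` keeps only the variance gate.
    SDs use the n-1 (sample) convention.
    """
    if len(pcr_baseline_samples) < 3:
        raise ValueError("need at least 3 reference samples for Shapiro-Wilk")
    ref = m.subset_samples(pcr_baseline_samples).data
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    variance = sd**2
    shapiro_p = pd.Series(np.nan, index=ref.index)
    for feat, row in ref.iterrows():
        vals = row.dropna().to_numpy(float)
        if len(vals) >= 3 and np.ptp(vals) > 0:
            shapiro_p[feat] = stats.shapiro(vals).pvalue
    eligible = variance >= variance_threshold
    if require_normality:
        eligible &= shapiro_p >= alpha
    table = pd.DataFrame(
        {"mean": mean, "sd": sd, "variance": variance, "shapiro_p": shapiro_p,
         "eligible": eligible.fillna(False)}
    )
    return ReferenceDistribution(table, list(pcr_baseline_samples), alpha, variance_threshold)


def zscore_outliers(
    m: QuantMatrix,
    ref: ReferenceDistribution,
    query_samples: list[str],
    allow_reference_overlap: bool = False,
) -> OutlierResult:
    """Z = (x - mean_ref) / sd_ref for eligible features in query cores.

    Scoring a sample that is part of the reference set is information
    leakage and raises unless ``allow_reference_overlap`` is set (used
    only to verify the reference's own calibration).
    """
    overlap = set(query_samples) & set(ref.samples)
    if overlap and not allow_reference_overlap:
        raise ValueError(f"query samples present in reference set: {sorted(overlap)}")
    q = m.subset_samples(query_samples).data
    mu = ref.stats["mean"]
    sd = ref.stats["sd"].where(ref.stats["sd"] > 0)
    z = q.sub(mu, axis=0).div(sd, axis=0)
    z = z.where(ref.eligible, np.nan)
    return OutlierResult(z=z, eligible=ref.eligible, level=m.level)


def rollup_phosphoprotein(
    site_matrix: QuantMatrix, site_to_protein: pd.Series | None = None
) -> QuantMatrix:
    """Phosphoprotein level: per protein and sample, the mean over the
    protein's phosphosites' non-missing values.

    The site-to-protein mapping defaults to the matrix's ``feature_meta``
    ``gene`` column; sites without a mapping raise with their ids listed.
    """
    if site_to_protein is None:
        if site_matrix.feature_meta is None or "gene" not in site_matrix.feature_meta.columns:
            raise ValueError("no site-to-protein mapping available")
        site_to_protein = site_matrix.feature_meta["gene"]
    mapping = site_to_protein.reindex(site_matrix.features)
    unmapped = mapping.index[mapping.isna()].tolist()
    if unmapped:
        raise ValueError(f"sites without protein mapping: {unmapped[:10]}")
    data = site_matrix.data.groupby(mapping).mean()
    data.index.name = None
    return QuantMatrix(data, "phosphoprotein")
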