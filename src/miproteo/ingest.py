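"""PSM filtering, rollup to common-reference ratios, normalization and QC.

Quantification follows the TMT common-reference design: every reporter
channel is divided by the plex's common-reference (CR) channel, PSM-level
ratios are rolled up to protein/phosphosite level by the median, the
result is log2-transformed, and each sample column is median-centered
and MAD-scaled.  RNA counts are upper-quartile normalized with zeros
treated as missing.  QC gates reproduce the study thresholds: PSMs
without a TMT label, with precursor purity below 50% or a negative delta
forward-reverse score are excluded; plexes must show >99% partial and
>94% full labeling with channel mixing within +/-15% of the CR; cores
need an average tumor content of at least 50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import QuantMatrix

logger = logging.getLogger(__name__)

#: consistency constant making the scaled MAD estimate the SD under normality
MAD_CONSTANT = 1.4826

PSM_ATTR_COLUMNS = ["label_state", "precursor_purity", "delta_fr_score"]


# ------------------------------------------------------------------ filtering

def filter_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Drop PSMs lacking a TMT label, with precursor purity < 50%, or with
    a negative delta forward-reverse score.

    Boundary values (purity exactly 0.5, delta exactly 0) are retained:
    only strict violations are excluded.
    """
    missing = [c for c in PSM_ATTR_COLUMNS if c not in psms.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    keep = (
        (psms["label_state"] != "none")
        & (psms["precursor_purity"] >= 0.5)
        & (psms["delta_fr_score"] >= 0)
    )
    return psms.loc[keep].copy()


# ------------------------------------------------------------------ rollup

def reference_normalize(intensity: float, cr_intensity: float) -> float:
    """log2 ratio of a channel intensity to the common reference.

    Zero or missing intensities never produce +/-inf: they come back NaN
    (with a logged warning for a non-positive CR).
    """
    if cr_intensity is None or not np.isfinite(cr_intensity) or cr_intensity <= 0:
        logger.warning("non-positive or missing CR intensity; emitting missing value")
        return float("nan")
    if intensity is None or not np.isfinite(intensity) or intensity <= 0:
        return float("nan")
    return float(np.log2(intensity / cr_intensity))


def rollup_psms(
    psms: pd.DataFrame,
    manifest: pd.DataFrame,
    level: str = "protein",
) -> QuantMatrix:
    """Roll filtered PSMs up to feature x core log2 CR-ratios.

    Per feature and channel the value is the median over PSMs of the
    linear-scale channel/CR intensity ratio, log2-transformed afterwards
    (medians commute with monotone transforms only when taken on the same
    scale; the linear-then-log order is fixed here and regression-tested).
    A feature with no PSMs in a plex is missing for that plex's cores.
    """
    required = {"plex", "feature_id"}
    if not required.issubset(psms.columns):
        raise ValueError(f"PSM table missing columns: {sorted(required - set(psms.columns))}")
    values: dict[str, pd.Series] = {}
    for plex, grp in manifest.groupby("plex", sort=True):
        plex_psms = psms[psms["plex"] == plex]
        cr_channel = grp["cr_channel"].iloc[0]
        cr = plex_psms[f"intensity_{cr_channel}"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            for core, channel in zip(grp["core_id"], grp["channel"]):
                col = f"intensity_{channel}"
                if col not in plex_psms.columns:
                    raise ValueError(f"PSM table has no column {col!r} for plex {plex}")
                ratio = plex_psms[col].to_numpy(float) / np.where(cr > 0, cr, np.nan)
                ratio[~np.isfinite(ratio)] = np.nan
                med = (
                    pd.Series(ratio, index=plex_psms["feature_id"].values)
                    .groupby(level=0)
                    .median()
                )
                values[core] = np.log2(med.where(med > 0))
    data = pd.DataFrame(values)
    data = data.reindex(sorted(data.index))
    return QuantMatrix(data, level)


# ------------------------------------------------------------------ scaling

def center_scale(m: QuantMatrix) -> QuantMatrix:
    """Median-center and MAD-scale every sample column (missing preserved).

    The MAD is multiplied by 1.4826 so the scale matches the SD under
    normality; after the op each column has median 0 and scaled MAD 1.
    """
    data = m.data.copy()
    for col in data.columns:
        x = data[col]
        if x.notna().sum() < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 non-missing values")
        med = x.median()
        mad = MAD_CONSTANT * (x - med).abs().median()
        if mad == 0 or not np.isfinite(mad):
            raise ValueError(f"sample {col!r} has zero MAD; cannot scale")
        data[col] = (x - med) / mad
    return QuantMatrix(data, m.level, m.feature_meta)


def upper_quartile_normalize(counts: pd.DataFrame, scale: float = 1000.0) -> QuantMatrix:
    """Upper-quartile normalize an RNA count table, returning log2 values.

    Zeros are treated as missing; genes with zero counts in every sample
    are removed; each column is divided by the 75th percentile of its
    non-zero values and rescaled by a fixed constant before log2.  No
    pseudocount is needed because zeros are already missing.
    """
    if (counts.to_numpy(float) < 0).any():
        raise ValueError("counts must be non-negative")
    x = counts.astype(float).where(counts > 0)
    x = x.dropna(how="all")
    normed = {}
    for col in x.columns:
        nz = x[col].dropna()
        if nz.empty:
            raise ValueError(f"sample {col!r} has no non-zero counts")
        uq = np.percentile(nz, 75)
        normed[col] = np.log2(x[col] / uq * scale)
    return QuantMatrix(pd.DataFrame(normed), "rna")


# ------------------------------------------------------------------ QC gates

def gate_tumor_content(slide_tcs: list[float]) -> tuple[float, bool]:
    """Average the per-slide tumor-content percentages of one core and gate
    at 50% (an average of exactly 50 passes; only <50% fails)."""
    if len(slide_tcs) == 0:
        raise ValueError("no slide tumor-content values provided")
    arr = np.asarray(slide_tcs, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise ValueError("tumor content percentages must be in [0, 100]")
    avg = float(arr.mean())
    return avg, avg >= 50.0


@dataclass
class QcReport:
    """Labeling-efficiency and mixing QC for one plex."""

    plex: str
    partial_label_pct: float
    full_label_pct: float
    mixing_deviation_pct: dict[str, float]
    partial_pass: bool
    full_pass: bool
    mixing_pass: bool
    failing_channels: list[str]

    @property
    def passed(self) -> bool:
        return self.partial_pass and self.full_pass and self.mixing_pass


def check_labeling_qc(
    psms: pd.DataFrame,
    manifest: pd.DataFrame,
    partial_threshold: float = 99.0,
    full_threshold: float = 94.0,
    mixing_threshold: float = 15.0,
) -> list[QcReport]:
    """Per-plex labeling and mixing QC.

    Partial labeling % is the fraction of PSMs with at least a partial
    label; full labeling % the fraction fully labeled; both thresholds are
    strict ("over 99%" / "over 94%").  Mixing deviation per channel is
    |median channel/CR ratio - 1|·100 and must stay within +/-15%.
    """
    if psms.empty:
        raise ValueError("PSM table is empty")
    reports = []
    for plex, grp in manifest.groupby("plex", sort=True):
        plex_psms = psms[psms["plex"] == plex]
        if plex_psms.empty:
            raise ValueError(f"no PSMs for plex {plex}")
        n = len(plex_psms)
        partial_pct = 100.0 * (plex_psms["label_state"] != "none").sum() / n
        full_pct = 100.0 * (plex_psms["label_state"] == "full").sum() / n
        cr_channel = grp["cr_channel"].iloc[0]
        cr = plex_psms[f"intensity_{cr_channel}"].to_numpy(float)
        deviations: dict[str, float] = {}
        failing = []
        for channel in grp["channel"]:
            ratio = plex_psms[f"intensity_{channel}"].to_numpy(float) / np.where(cr > 0, cr, np.nan)
            dev = float(abs(np.nanmedian(ratio) - 1.0) * 100.0)
            deviations[channel] = dev
            if dev > mixing_threshold:
                failing.append(channel)
        reports.append(
            QcReport(
                plex=str(plex),
                partial_label_pct=partial_pct,
                full_label_pct=full_pct,
                mixing_deviation_pct=deviations,
                partial_pass=partial_pct > partial_threshold,
                full_pass=full_pct > full_threshold,
                mixing_pass=not failing,
                failing_channels=failing,
            )
        )
    return reports
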