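"""ERBB2-amplicon status, amplicon-mean group tests, mucin outliers and
offline literature-association tallying.

A tumor is called *false ERBB2+* when the locus shows no copy-number gain
and ERBB2 protein is low relative to the pCR reference; *pseudo ERBB2+*
when the locus is gained but ERBB2 (or the mean of the flanking amplicon
genes STARD3/PGAP3/GRB7) protein stays low; otherwise *true ERBB2+*.
The numeric cut-offs (copy-number gain >= 0.3 log2, protein Z below -2)
are package defaults — the acceptance surface is recovery of generator
ground truth, not any specific patient labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AMPLICON_GENES, CitationRecord
from .matrix import QuantMatrix
from .outliers import OutlierResult, ReferenceDistribution

DEFAULT_CN_GAIN_MIN = 0.3
DEFAULT_Z_LOW = -2.0
FLANKING_GENES = [g for g in AMPLICON_GENES if g != "ERBB2"]


@dataclass
class AmpliconProfile:
    """Per-patient multi-omic evidence at the ERBB2 locus."""

    patient_id: str
    cn_log2: dict[str, float]  # gene -> copy-number log2
    protein_z: dict[str, float]  # gene -> protein Z vs pCR reference


@dataclass
class Erbb2Call:
    patient_id: str
    amplicon_class: str  # true_pos | pseudo_pos | false_pos
    evidence: list[str] = field(default_factory=list)


def classify_erbb2_status(
    profile: AmpliconProfile,
    cn_gain_min: float = DEFAULT_CN_GAIN_MIN,
    z_low: float = DEFAULT_Z_LOW,
) -> Erbb2Call:
    """Assign exactly one amplicon class from CN gain and protein Z-scores."""
    cn = profile.cn_log2.get("ERBB2")
    z = profile.protein_z.get("ERBB2")
    if cn is None or z is None or not np.isfinite(cn) or not np.isfinite(z):
        raise ValueError(f"patient {profile.patient_id}: missing ERBB2 CN or protein Z")
    flank = [
        profile.protein_z[g]
        for g in FLANKING_GENES
        if g in profile.protein_z and np.isfinite(profile.protein_z[g])
    ]
    flank_mean = float(np.mean(flank)) if flank else np.nan
    evidence = [
        f"ERBB2 CN log2 = {cn:.3f} (gain threshold {cn_gain_min})",
        f"ERBB2 protein Z = {z:.2f} (low threshold {z_low})",
        f"flanking-gene mean protein Z = {flank_mean:.2f}",
    ]
    gained = cn >= cn_gain_min
    low_protein = z < z_low
    low_flank = np.isfinite(flank_mean) and flank_mean < z_low
    if not gained and low_protein:
        cls = "false_pos"
        evidence.append("no amplification and low ERBB2 protein")
    elif gained and (low_protein or low_flank):
        cls = "pseudo_pos"
        evidence.append("copy gain without focal protein overexpression")
    else:
        cls = "true_pos"
        evidence.append("copy gain with retained protein expression")
    return Erbb2Call(profile.patient_id, cls, evidence)


def build_amplicon_profiles(
    cn: QuantMatrix,
    protein: QuantMatrix,
    reference: ReferenceDistribution,
    manifest: pd.DataFrame,
) -> dict[str, AmpliconProfile]:
    """Targeted locus profiles for every patient.

    Protein Z-scores use the pCR reference mean/SD directly, *without* the
    transcriptome-wide variance/normality eligibility gate: for a targeted
    four-gene query the discovery-stage filter would only censor the locus
    at random.  Multiple pre-treatment cores are averaged per patient.
    """
    pre = manifest[manifest["timepoint"] == "pre"]
    profiles = {}
    for patient, grp in pre.groupby("patient_id", sort=True):
        cores = [c for c in grp["core_id"] if c in protein.samples]
        cn_vals = {}
        z_vals = {}
        for g in AMPLICON_GENES:
            if g in cn.features and patient in cn.samples:
                cn_vals[g] = float(cn.data.at[g, patient])
            if g in protein.features and cores:
                x = float(protein.data.loc[g, cores].mean())
                mu = reference.stats.at[g, "mean"]
                sd = reference.stats.at[g, "sd"]
                if np.isfinite(mu) and np.isfinite(sd) and sd > 0:
                    z_vals[g] = (x - mu) / sd
        profiles[patient] = AmpliconProfile(patient, cn_vals, z_vals)
    return profiles


def amplicon_group_test(
    protein: QuantMatrix,
    group_a: list[str],
    group_b: list[str],
    genes: list[str] = ("STARD3", "ERBB2", "GRB7"),
) -> pd.DataFrame:
    """Welch two-sample t-tests on the amplicon genes and their per-sample
    arithmetic mean, group A vs group B.

    Returns one row per gene plus a ``mean(...)`` row with t, df and p.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    genes = list(genes)
    missing = [g for g in genes if g not in protein.features]
    if missing:
        raise ValueError(f"genes absent from protein matrix: {missing}")
    sub_a = protein.data.loc[genes, group_a]
    sub_b = protein.data.loc[genes, group_b]
    rows = []

    def welch(xa: np.ndarray, xb: np.ndarray, label: str) -> None:
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        if np.allclose(xa.var(ddof=1) + xb.var(ddof=1), 0.0) and xa.mean() == xb.mean():
            rows.append({"feature": label, "t": 0.0, "df": float(len(xa) + len(xb) - 2), "pval": 1.0})
            return
        res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"feature": label, "t": float(res.statistic), "df": float(res.df),
                     "pval": float(res.pvalue)})

    for g in genes:
        welch(sub_a.loc[g].to_numpy(float), sub_b.loc[g].to_numpy(float), g)
    welch(
        sub_a.mean(axis=0).to_numpy(float),
        sub_b.mean(axis=0).to_numpy(float),
        f"mean({'+'.join(genes)})",
    )
    return pd.DataFrame(rows).set_index("feature")


def mucin_panel(
    z: OutlierResult,
    manifest: pd.DataFrame,
    panel: list[str],
    z_high: float = 2.0,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Flag patients with coordinated high-expression outliers across a
    mucin gene panel.

    A patient is flagged when at least ``min_genes`` panel genes reach
    Z >= z_high in any of the patient's scored cores.
    """
    if not panel:
        raise ValueError("empty mucin panel")
    present = [g for g in panel if g in z.z.index]
    if not present:
        raise ValueError(f"no panel genes present in Z matrix: {panel}")
    mapping = manifest.set_index("core_id")["patient_id"]
    rows = []
    cores_by_patient: dict[str, list[str]] = {}
    for core in z.z.columns:
        cores_by_patient.setdefault(mapping.get(core, core), []).append(core)
    for patient, cores in sorted(cores_by_patient.items()):
        sub = z.z.loc[present, cores]
        high = sub.max(axis=1) >= z_high
        hit_genes = sorted(high.index[high])
        rows.append(
            {
                "patient_id": patient,
                "n_high": len(hit_genes),
                "genes": ";".join(hit_genes),
                "flagged": len(hit_genes) >= min_genes,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def literature_tally(
    citations: list[CitationRecord],
    genes: list[str],
    max_gene_associations: int = 100,
) -> pd.Series:
    """Count qualifying publications per queried gene.

    A publication qualifies iff its text contains ("resist" OR "recur")
    AND "breast cancer", all case-insensitive substring matches, AND it is
    associated with at most ``max_gene_associations`` genes (exactly 100
    is retained; only >100 is excluded).  Each qualifying publication
    increments every associated queried gene once.
    """
    counts = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    queried = set(genes)
    for rec in citations:
        text = rec.text_blob.lower()
        if not (("resist" in text or "recur" in text) and "breast cancer" in text):
            continue
        if len(rec.gene_symbols) > max_gene_associations:
            continue
        for g in rec.gene_symbols & queried:
            counts[g] += 1
    return counts
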