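"""Pre/on-treatment differential statistics and cohort concordance.

Small-cohort comparisons use exact Wilcoxon tests (paired signed-rank for
on- vs pre-treatment within a group, rank-sum for pCR vs non-pCR log2
fold changes).  Cohort-wide differential expression uses a per-feature
linear model with group and plex (batch) coefficients and an empirical
Bayes moderated t-statistic: residual variances are shrunk toward a prior
s0^2 with prior degrees of freedom d0 estimated by matching moments of
the log residual-variance distribution, and the moderated t is referred
to a t distribution on d0 + residual df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import QuantMatrix

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ consensus

def consensus_per_patient(m: QuantMatrix, manifest: pd.DataFrame) -> QuantMatrix:
    """Average replicate cores to one value per patient and timepoint.

    Output columns are ``patient|timepoint``; unmapped cores raise.
    """
    mapping = manifest.set_index("core_id")[["patient_id", "timepoint"]]
    unmapped = [c for c in m.samples if c not in mapping.index]
    if unmapped:
        raise ValueError(f"cores missing from manifest: {unmapped[:10]}")
    keys = [
        f"{mapping.at[c, 'patient_id']}|{mapping.at[c, 'timepoint']}" for c in m.samples
    ]
    data = m.data.T.groupby(pd.Index(keys, name="patient_tp")).mean().T
    return QuantMatrix(data, m.level, m.feature_meta)


# ------------------------------------------------------------------ exact tests

def paired_signed_rank(differences) -> float:
    """Exact two-sided Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped (classical convention, count logged);
    needs n >= 3 after dropping.  Exact null enumeration for n <= 25 with
    tie-free |differences|, otherwise the normal approximation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    n_zero = int(np.sum(d == 0))
    if n_zero:
        logger.info("dropping %d zero difference(s) before signed-rank test", n_zero)
        d = d[d != 0]
    if d.size < 3:
        raise ValueError("need at least 3 non-zero paired differences")
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    if method == "approx":
        logger.info("ties or large n: falling back to normal approximation")
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def rank_sum(group_a, group_b) -> float:
    """Exact two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled values are tie-free; with cross-group
    ties it falls back to the mid-rank normal approximation with a logged
    notice.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "asymptotic" if ties else "exact"
    if ties:
        logger.info("ties across groups: mid-rank normal approximation used")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ------------------------------------------------------------------ moderated t

@dataclass
class ModeratedTResult:
    """Per-feature moderated-t statistics for each contrast."""

    tables: dict[str, pd.DataFrame]  # contrast -> DataFrame(log2fc, t, pval, adj_pval, df)
    prior_df: float
    prior_var: float
    posterior_var: pd.Series


def _fit_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match d0 and s0^2 from log residual variances (Smyth-style:
    the log of a scaled F variate has known digamma/trigamma moments)."""
    ok = (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = np.inf
        s02 = float(np.exp(emean))
        return d0, s02
    # invert trigamma(d0/2) = evar by Newton iteration
    y = 0.5 + 1.0 / evar
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (tri - evar) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = float(2.0 * y)
    s02 = float(np.exp(emean + special.digamma(y) - np.log(y)))
    return d0, s02


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """One-hot group means (no intercept) plus plex dummies (first dropped)."""
    groups = pd.get_dummies(design["group"], prefix="", prefix_sep="").astype(float)
    cols = list(groups.columns)
    x = [groups.to_numpy(float)]
    if "plex" in design.columns and design["plex"].nunique() > 1:
        plex = pd.get_dummies(design["plex"], drop_first=True).astype(float)
        cols += [f"plex:{c}" for c in plex.columns]
        x.append(plex.to_numpy(float))
    return np.hstack(x), cols


def moderated_t(
    m: QuantMatrix,
    design: pd.DataFrame,
    contrasts: dict[str, dict[str, float]],
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated t-tests on a group+plex linear model.

    ``design`` is indexed by sample id with columns ``group`` (the four
    group/timepoint cells, or any grouping) and optionally ``plex``.
    ``contrasts`` maps a contrast name to {group coefficient: weight}.
    Features are fit on their complete cases; the fit is skipped (NaN row)
    when the design loses full rank on that missingness pattern.
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t).
    """
    design = design.loc[list(m.samples)]
    x_full, cols = _design_matrix(design)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError(f"rank-deficient design: columns {cols} are confounded")
    y = m.data.to_numpy(float)
    n_feat = y.shape[0]
    coefs = np.full((n_feat, len(cols)), np.nan)
    s2 = np.full(n_feat, np.nan)
    dfres = np.zeros(n_feat)
    cov_unscaled = [None] * n_feat
    for i in range(n_feat):
        mask = ~np.isnan(y[i])
        xi = x_full[mask]
        if mask.sum() <= x_full.shape[1] or np.linalg.matrix_rank(xi) < xi.shape[1]:
            continue
        yi = y[i, mask]
        xtx_inv = np.linalg.inv(xi.T @ xi)
        beta = xtx_inv @ xi.T @ yi
        resid = yi - xi @ beta
        df_i = mask.sum() - xi.shape[1]
        coefs[i] = beta
        dfres[i] = df_i
        s2[i] = float(resid @ resid / df_i) if df_i > 0 else np.nan
        cov_unscaled[i] = xtx_inv

    if prior_df is None:
        d0, s02 = _fit_prior(s2[~np.isnan(s2)], dfres[~np.isnan(s2)])
    else:
        d0 = float(prior_df)
        _, s02 = _fit_prior(s2[~np.isnan(s2)], dfres[~np.isnan(s2)])
    with np.errstate(invalid="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        elif d0 == 0:
            s2_post = s2.copy()
        else:
            s2_post = (d0 * s02 + dfres * np.where(np.isnan(s2), 0.0, s2)) / (d0 + dfres)
            s2_post[np.isnan(s2) & (dfres == 0)] = s02  # zero residual df inherits prior

    col_idx = {c: j for j, c in enumerate(cols)}
    tables = {}
    for name, weights in contrasts.items():
        unknown = [g for g in weights if g not in col_idx]
        if unknown:
            raise ValueError(f"contrast {name!r} references unknown coefficients {unknown}")
        cvec = np.zeros(len(cols))
        for g, w in weights.items():
            cvec[col_idx[g]] = w
        fc = np.full(n_feat, np.nan)
        tstat = np.full(n_feat, np.nan)
        pval = np.full(n_feat, np.nan)
        dof = np.full(n_feat, np.nan)
        for i in range(n_feat):
            if cov_unscaled[i] is None or np.isnan(s2_post[i]):
                continue
            se2 = float(cvec @ cov_unscaled[i] @ cvec)
            if se2 <= 0:
                continue
            fc[i] = float(coefs[i] @ cvec)
            denom = np.sqrt(s2_post[i] * se2)
            if denom == 0:
                continue
            tstat[i] = fc[i] / denom
            dof[i] = np.inf if np.isinf(d0) else dfres[i] + d0
            if np.isinf(d0):
                pval[i] = 2.0 * stats.norm.sf(abs(tstat[i]))
            else:
                pval[i] = 2.0 * stats.t.sf(abs(tstat[i]), dfres[i] + d0)
        adj = np.full(n_feat, np.nan)
        ok = ~np.isnan(pval)
        if ok.any():
            adj[ok] = multipletests(pval[ok], method="fdr_bh")[1]
        tables[name] = pd.DataFrame(
            {"log2fc": fc, "t": tstat, "pval": pval, "adj_pval": adj, "df": dof},
            index=m.features,
        )
    return ModeratedTResult(
        tables=tables,
        prior_df=d0,
        prior_var=s02,
        posterior_var=pd.Series(s2_post, index=m.features),
    )


# ------------------------------------------------------------------ BH

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ concordance

def mrna_protein_corr(rna: QuantMatrix, protein: QuantMatrix, min_samples: int = 3):
    """Per-gene Spearman correlation of mRNA and protein over shared
    samples, plus the cohort median.

    Returns (Series of per-gene rho, median rho)."""
    shared_genes = rna.features.intersection(protein.features)
    if shared_genes.empty:
        raise ValueError("no shared genes between RNA and protein matrices")
    shared_samples = rna.samples.intersection(protein.samples)
    r = rna.data.loc[shared_genes, shared_samples]
    p = protein.data.loc[shared_genes, shared_samples]
    rhos = {}
    for g in shared_genes:
        x, y = r.loc[g], p.loc[g]
        mask = x.notna() & y.notna()
        if mask.sum() >= min_samples:
            rho = stats.spearmanr(x[mask], y[mask]).statistic
            if np.isfinite(rho):
                rhos[g] = float(rho)
    per_gene = pd.Series(rhos)
    if per_gene.empty:
        raise ValueError(f"no gene has >= {min_samples} shared samples")
    return per_gene, float(per_gene.median())


def variable_gene_cluster(m: QuantMatrix, manifest: pd.DataFrame, k: int = 500):
    """Average-linkage hierarchical clustering of samples on correlation
    distance over the top-k most variable features, with a replicate-
    adjacency report.

    A replicate pair (same patient and timepoint) "joins cleanly" when the
    first merged cluster containing both holds no core from any other
    patient/timepoint.  Returns (linkage matrix, report DataFrame).
    """
    from scipy.cluster import hierarchy

    if m.data.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    variances = m.data.var(axis=1, skipna=True)
    if k > len(variances):
        logger.info("k=%d exceeds feature count %d; using all features", k, len(variances))
        k = len(variances)
    top = variances.nlargest(k).index
    sub = m.data.loc[top].fillna(m.data.loc[top].mean(axis=1).mean())
    corr = np.corrcoef(sub.T.to_numpy(float))
    dist = 1.0 - corr[np.triu_indices(corr.shape[0], 1)]
    link = hierarchy.linkage(dist, method="average")

    samples = list(m.samples)
    mapping = manifest.set_index("core_id")[["patient_id", "timepoint"]]
    labels = {
        s: (mapping.at[s, "patient_id"], mapping.at[s, "timepoint"]) for s in samples
    }
    # walk the merge tree, tracking member sets
    clusters: dict[int, set[int]] = {i: {i} for i in range(len(samples))}
    merged_at: dict[frozenset[int], set[int]] = {}
    for step, (a, b, _, _) in enumerate(link):
        new = clusters[int(a)] | clusters[int(b)]
        clusters[len(samples) + step] = new
        merged_at.setdefault(frozenset(new), new)
    rows = []
    by_label: dict[tuple, list[int]] = {}
    for i, s in enumerate(samples):
        by_label.setdefault(labels[s], []).append(i)
    for label, members in sorted(by_label.items()):
        if len(members) < 2:
            continue
        for i_pos in range(len(members)):
            for j_pos in range(i_pos + 1, len(members)):
                i, j = members[i_pos], members[j_pos]
                first = None
                for cid in range(len(samples), len(samples) + len(link)):
                    if i in clusters[cid] and j in clusters[cid]:
                        first = clusters[cid]
                        break
                clean = first is not None and all(labels[samples[x]] == label for x in first)
                rows.append(
                    {
                        "patient_id": label[0],
                        "timepoint": label[1],
                        "core_a": samples[i],
                        "core_b": samples[j],
                        "joins_cleanly": clean,
                    }
                )
    report = pd.DataFrame(rows)
    return link, report
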