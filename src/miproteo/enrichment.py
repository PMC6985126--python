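"""Single-sample weighted-KS enrichment for gene sets and PTM signatures.

The statistic is the ssGSEA-style running sum over a descending ranking
of signed scores: hits increment by |score|^w normalized within the set,
misses decrement by 1/(N - m), and the enrichment score (ES) is the area
variant — the sum of the running-sum values divided by N.  A permutation
null over identifier labels yields NES (ES divided by the mean |null ES|
of matching sign), a nominal tail p-value, and Benjamini-Hochberg FDR
across sets.

PTM signatures key phosphosites by the 15-mer sequence window flanking
the modified residue by 7 amino acids on both sides (fully localized
sites only); members tagged ``;d`` (down) contribute with inverted score
sign, ``;u`` (up) members as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 0.75
DEFAULT_MIN_SIZE = 5
P_FLOOR = 1e-15
FDR_REPORTING_THRESHOLD = 0.25


# ------------------------------------------------------------------ ranking

def signed_logp(p: float, sign: float) -> float:
    """sign * (-log10 p) with p floored at 1e-15 so p=0 stays finite."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return float(np.sign(sign) * -np.log10(max(p, P_FLOOR)))


def collapse_gene_centric(
    scores: pd.Series, feature_to_gene: pd.Series
) -> tuple[pd.Series, list[str]]:
    """Collapse feature-level signed scores to one score per gene symbol,
    keeping the score of maximal magnitude (the most significant p-value).

    Ties in |score| are broken by lexicographic feature id; genes whose
    tie spans opposite signs are returned in the flagged list.
    """
    genes = feature_to_gene.reindex(scores.index)
    if genes.isna().any():
        raise ValueError("every feature must map to a gene symbol")
    out: dict[str, float] = {}
    flagged: list[str] = []
    frame = pd.DataFrame({"score": scores, "gene": genes})
    frame["absscore"] = frame["score"].abs()
    frame = frame.sort_values(["gene", "absscore", "score"], ascending=[True, False, True])
    for gene, grp in frame.groupby("gene", sort=True):
        top = grp["absscore"].iloc[0]
        best = grp[grp["absscore"] == top].sort_index()
        out[gene] = float(best["score"].iloc[0])
        if best["score"].nunique() > 1:
            flagged.append(gene)
    return pd.Series(out), flagged


# ------------------------------------------------------------------ ES

def _es_from_sorted(values: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Area-variant ES on an already descending-sorted score vector."""
    n = values.size
    m = int(hit_mask.sum())
    if m == 0 or m == n:
        raise ValueError("set must be a proper non-empty subset of the ranked identifiers")
    inc = np.where(hit_mask, np.abs(values) ** weight, 0.0)
    total = inc.sum()
    if total == 0:
        inc = hit_mask.astype(float)
        total = float(m)
    steps = inc / total - (~hit_mask).astype(float) / (n - m)
    return float(np.cumsum(steps).sum() / n)


def ssgsea_es(scores: pd.Series, members, weight: float = DEFAULT_WEIGHT) -> float:
    """Enrichment score of one identifier set against one ranked score
    vector (higher scores rank first; ties broken by identifier)."""
    if scores.index.has_duplicates:
        raise ValueError("duplicate identifiers in score vector")
    if not np.isfinite(scores.to_numpy(float)).all():
        raise ValueError("scores must be finite")
    order = sorted(scores.index, key=lambda k: (-scores[k], str(k)))
    values = scores.loc[order].to_numpy(float)
    hit = np.array([k in set(members) for k in order])
    return _es_from_sorted(values, hit, weight)


# ------------------------------------------------------------------ NES/FDR

@dataclass
class EnrichmentResult:
    """Per-set enrichment table: ES, NES, nominal p, FDR, overlap size."""

    table: pd.DataFrame  # index: set name
    n_permutations: int
    weight: float

    def significant(self, fdr: float = FDR_REPORTING_THRESHOLD) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]


def _prepare_sets(
    scores: pd.Series, sets: dict[str, list[str]], min_size: int
) -> dict[str, np.ndarray]:
    """Map each usable set to a boolean hit mask over the score index."""
    idx = {k: i for i, k in enumerate(scores.index)}
    masks = {}
    for name, members in sets.items():
        present = [m for m in dict.fromkeys(members) if m in idx]
        if len(present) < min_size:
            logger.info("set %s skipped: overlap %d < min_size %d", name, len(present), min_size)
            continue
        mask = np.zeros(len(scores), dtype=bool)
        mask[[idx[m] for m in present]] = True
        masks[name] = mask
    return masks


def nes_fdr(
    scores: pd.Series,
    sets: dict[str, list[str]],
    weight: float = DEFAULT_WEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """ES, permutation NES, nominal p and BH FDR for a collection of sets.

    The null shuffles identifier labels (equivalently, permutes the score
    vector) ``n_permutations`` times with a seeded generator.  NES is
    ES / mean(|null ES| of the matching sign); nominal p is the tail
    fraction of same-signed null ES at least as extreme.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    order = sorted(scores.index, key=lambda k: (-scores[k], str(k)))
    sorted_scores = scores.loc[order]
    masks = _prepare_sets(sorted_scores, sets, min_size)
    if not masks:
        return EnrichmentResult(pd.DataFrame(
            columns=["es", "nes", "pval", "fdr", "overlap"]), n_permutations, weight)
    values = sorted_scores.to_numpy(float)
    es = {name: _es_from_sorted(values, mask, weight) for name, mask in masks.items()}

    null = {name: np.empty(n_permutations) for name in masks}
    n = len(values)
    for b in range(n_permutations):
        perm_mask_source = rng.permutation(n)
        for name, mask in masks.items():
            null[name][b] = _es_from_sorted(values, mask[perm_mask_source], weight)

    rows = []
    for name, mask in masks.items():
        obs = es[name]
        nulls = null[name]
        same_sign = nulls[np.sign(nulls) == np.sign(obs)] if obs != 0 else nulls
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(nulls).mean()
        nes = obs / denom if denom > 0 else 0.0
        if obs >= 0:
            pos = nulls[nulls >= 0]
            p = (np.sum(pos >= obs) + 1) / (pos.size + 1)
        else:
            neg = nulls[nulls < 0]
            p = (np.sum(neg <= obs) + 1) / (neg.size + 1)
        rows.append({"set": name, "es": obs, "nes": nes, "pval": float(p),
                     "overlap": int(mask.sum())})
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = multipletests(table["pval"].values, method="fdr_bh")[1]
    table["significant"] = table["fdr"] < FDR_REPORTING_THRESHOLD
    return EnrichmentResult(table, n_permutations, weight)


# ------------------------------------------------------------------ PTM-SEA

def _directed_es(
    values: np.ndarray, up_mask: np.ndarray, down_mask: np.ndarray, weight: float
) -> float:
    """Directed signature ES: the up component is the ordinary ES; the
    down component is the ES computed on the negated score vector, so
    re-tagging every member up->down exactly negates the total."""
    es = 0.0
    for vals, mask in ((values, up_mask), (-values, down_mask)):
        if not mask.any():
            continue
        order = np.argsort(-vals, kind="stable")
        es += _es_from_sorted(vals[order], mask[order], weight)
    return es


def ptm_sea(
    site_scores: pd.Series,
    signatures: dict[str, list[str]],
    weight: float = DEFAULT_WEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """PTM-signature enrichment on flanking-window-keyed site scores.

    Site identifiers must be 15-mer windows (the modified residue +/- 7
    amino acids).  Signature members carry ``;u`` / ``;d`` direction
    suffixes; the signature ES is the up-member ES plus the down-member ES
    evaluated on the sign-inverted score vector, so down sites at the
    bottom ranks score positive and re-tagging all members flips the sign.
    """
    from statsmodels.stats.multitest import multipletests

    from .io import parse_directed_members

    bad = [k for k in site_scores.index if len(str(k)) != 15]
    if bad:
        raise ValueError(f"malformed flanking windows (length != 15): {bad[:10]}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    values = site_scores.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    idx = {k: i for i, k in enumerate(site_scores.index)}
    masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, members in signatures.items():
        directed = parse_directed_members(members)
        present = {k: d for k, d in directed.items() if k in idx}
        if len(present) < min_size:
            logger.info("signature %s skipped: overlap %d < min_size %d",
                        name, len(present), min_size)
            continue
        up = np.zeros(len(values), dtype=bool)
        down = np.zeros(len(values), dtype=bool)
        for k, d in present.items():
            (up if d > 0 else down)[idx[k]] = True
        masks[name] = (up, down)
    if not masks:
        return EnrichmentResult(pd.DataFrame(
            columns=["es", "nes", "pval", "fdr", "overlap"]), n_permutations, weight)

    es = {name: _directed_es(values, up, down, weight) for name, (up, down) in masks.items()}
    rng = np.random.default_rng(seed)
    null = {name: np.empty(n_permutations) for name in masks}
    for b in range(n_permutations):
        perm = rng.permutation(len(values))
        for name, (up, down) in masks.items():
            null[name][b] = _directed_es(values, up[perm], down[perm], weight)

    rows = []
    for name, (up, down) in masks.items():
        obs, nulls = es[name], null[name]
        same_sign = nulls[np.sign(nulls) == np.sign(obs)] if obs != 0 else nulls
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(nulls).mean()
        nes = obs / denom if denom > 0 else 0.0
        if obs >= 0:
            pos = nulls[nulls >= 0]
            p = (np.sum(pos >= obs) + 1) / (pos.size + 1)
        else:
            neg = nulls[nulls < 0]
            p = (np.sum(neg <= obs) + 1) / (neg.size + 1)
        rows.append({"set": name, "es": obs, "nes": nes, "pval": float(p),
                     "overlap": int(up.sum() + down.sum())})
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = multipletests(table["pval"].values, method="fdr_bh")[1]
    table["significant"] = table["fdr"] < FDR_REPORTING_THRESHOLD
    return EnrichmentResult(table, n_permutations, weight)
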