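"""Gene-level copy number, chromosome instability, calls and mutations.

Copy-number segments arrive as SEG-style tables (sample, chrom, start,
end, log2_ratio; internal coordinates 0-based half-open).  Gene-level
values are overlap-length-weighted means of intersecting segments.  The
chromosome instability score is the length-weighted sum of absolute
segment log2 ratios per chromosome; the genome-wide index sums the 22
autosomes only.  Aberration calls apply the stringent +/-2 threshold to
externally computed integer calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import QuantMatrix

AUTOSOMES = [str(c) for c in range(1, 23)]
VALID_CHROMS = set(AUTOSOMES) | {"X", "Y"}

SNV_KEEP = {"non-synonymous SNV", "nonsynonymous SNV", "stopgain", "stoploss", "splicing"}


def _validate_segments(segments: pd.DataFrame) -> None:
    required = {"sample", "chrom", "start", "end", "log2_ratio"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    bad = segments.index[segments["start"] >= segments["end"]]
    if len(bad):
        raise ValueError(f"malformed interval(s) at row index {list(bad[:5])}: start >= end")
    unknown = set(segments["chrom"].astype(str)) - VALID_CHROMS
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")


def gene_copy_number(segments: pd.DataFrame, genes: pd.DataFrame) -> QuantMatrix:
    """Gene x sample log2 copy-number matrix by segment overlap.

    Per gene and sample: the overlap-length-weighted mean of the log2
    ratios of all intersecting segments; genes with no overlapping
    segment are missing.
    """
    _validate_segments(segments)
    if not {"gene", "chrom", "start", "end"}.issubset(genes.columns):
        raise ValueError("gene model table needs columns gene, chrom, start, end")
    samples = sorted(segments["sample"].unique())
    out = pd.DataFrame(np.nan, index=genes["gene"].tolist(), columns=samples)
    seg_by = {k: g for k, g in segments.groupby(["sample", "chrom"], sort=False)}
    for row in genes.itertuples():
        for sample in samples:
            seg = seg_by.get((sample, str(row.chrom)))
            if seg is None:
                continue
            ov = np.minimum(seg["end"].values, row.end) - np.maximum(seg["start"].values, row.start)
            mask = ov > 0
            if mask.any():
                w = ov[mask].astype(float)
                out.at[row.gene, sample] = float(
                    np.average(seg["log2_ratio"].values[mask], weights=w)
                )
    return QuantMatrix(out, "cna-gene")


def chromosome_instability(
    segments: pd.DataFrame, normalize: bool = True
) -> tuple[pd.Series, float]:
    """Per-chromosome instability scores and the genome-wide index for one
    sample's segments.

    score_c = sum_i |log2 r_i| * w_i over the chromosome's segments, with
    w_i the segment length fraction of the chromosome when ``normalize``
    is true (sample-comparable; the default) or the raw length otherwise.
    The genome-wide index sums the scores of autosomes 1-22 only.
    """
    if segments.empty:
        raise ValueError("need at least one segment")
    _validate_segments(segments)
    if segments["sample"].nunique() > 1:
        raise ValueError("chromosome_instability expects segments of a single sample")
    scores = {}
    for chrom, grp in segments.groupby("chrom", sort=False):
        lengths = (grp["end"] - grp["start"]).to_numpy(float)
        weights = lengths / lengths.sum() if normalize else lengths
        scores[str(chrom)] = float(np.sum(np.abs(grp["log2_ratio"].to_numpy(float)) * weights))
    per_chrom = pd.Series(scores, dtype=float)
    index = float(per_chrom.reindex(AUTOSOMES).fillna(0.0).sum())
    return per_chrom, index


def call_aberrant_genes(integer_calls: pd.DataFrame, threshold: int = 2) -> pd.DataFrame:
    """Boolean aberration calls from GISTIC-style integer calls: aberrant
    iff the call is >= threshold (amplified) or <= -threshold (deleted)."""
    values = integer_calls.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.asarray(values, float) == np.asarray(values, float).astype(int)):
            raise ValueError("integer call matrix contains non-integer values")
        values = values.astype(int)
    return pd.DataFrame(
        (values >= threshold) | (values <= -threshold),
        index=integer_calls.index,
        columns=integer_calls.columns,
    )


def filter_coding_mutations(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep protein-affecting variants and tabulate them per patient.

    SNVs are retained when annotated non-synonymous / stopgain / stoploss /
    splicing; INDELs when exonic.  Returns (unique-mutation x patient
    table, mutated-gene x patient table) as 0/1 count matrices.
    """
    required = {"patient", "gene", "variant_type", "annotation"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if variants.empty:
        empty = pd.DataFrame()
        return empty, empty.copy()
    is_snv = variants["variant_type"].str.upper() == "SNV"
    keep_snv = is_snv & variants["annotation"].isin(SNV_KEEP)
    keep_indel = ~is_snv & variants["annotation"].str.contains("exonic", case=False, na=False)
    kept = variants.loc[keep_snv | keep_indel].copy()
    if kept.empty:
        empty = pd.DataFrame()
        return empty, empty.copy()
    if "mutation_id" not in kept.columns:
        kept["mutation_id"] = (
            kept["gene"].astype(str) + ":" + kept["annotation"].astype(str)
            + ":" + kept.groupby(["gene", "annotation"]).cumcount().astype(str)
        )
    mut_by_patient = (
        kept.assign(present=1)
        .pivot_table(index="mutation_id", columns="patient", values="present", aggfunc="max", fill_value=0)
    )
    gene_by_patient = (
        kept.assign(present=1)
        .pivot_table(index="gene", columns="patient", values="present", aggfunc="max", fill_value=0)
    )
    return mut_by_patient, gene_by_patient
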