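"""Synthetic multi-omic cohort generator.

Emulates the structure of a neoadjuvant anti-ERBB2 core-biopsy study:
~14 patients split into pathological-complete-response (pCR) and non-pCR
groups, pre- and on-treatment replicate cores, TMT plexes with a common
reference (CR) channel, and coherent protein / phosphosite / RNA /
copy-number layers carrying known ground truth:

* ERBB2-amplicon classes (true / pseudo / false positive) expressed
  consistently across CNA, RNA and protein for ERBB2 and its flanking
  genes STARD3, PGAP3 and GRB7;
* pCR-specific on-treatment downregulation of ERBB2 protein, ERBB2
  phosphosites and mTOR-target phosphosites;
* a patient-specific mucin outlier panel;
* a configurable per-gene mRNA-protein Spearman correlation.

Every spiked effect is recorded in ``bundle.truth`` so downstream
recovery tests never re-derive truth from the data.

The generative model: per-gene baseline log2 abundance ~ Normal; a core's
value = baseline + patient effect + treatment effect + per-plex batch
effect + noise.  Spiked effects *replace* the random patient effect for
the targeted gene/patient so that ground truth is deterministic; the pCR
reference patients keep their random effects, preserving the reference
variance that the outlier stage estimates.  RNA counts are drawn
negative-binomially around a latent log2 value correlated with protein
through a Gaussian copula whose Pearson coefficient is chosen so the
implied Spearman correlation hits the configured target
(rho_pearson = 2·sin(pi·rho_spearman/6)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import QuantMatrix
from . import io as mio

# ERBB2 amplicon core + neighbours (chr17q12), dimerization partners, drivers
AMPLICON_GENES = ["ERBB2", "STARD3", "PGAP3", "GRB7"]
PARTNER_GENES = ["EGFR", "ERBB3", "ERBB4"]
MUCIN_GENES = ["MUC1", "MUC4", "MUC5AC", "MUC6", "MUC16"]
MTOR_TARGET_GENES = ["RPS6", "EIF4EBP1", "AKT1S1", "ULK1", "RPS6KB1"]
TOP2A = "TOP2A"

SPECIAL_GENES = AMPLICON_GENES + PARTNER_GENES + [TOP2A] + MUCIN_GENES + MTOR_TARGET_GENES

AMPLICON_CLASSES = ("true_pos", "pseudo_pos", "false_pos")

#: TMT 11-plex reporter channels; 131N carries the common reference pool
TMT11_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N", "131C"]
TMT10_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def default_effect_sizes() -> dict[str, float]:
    return {
        # log2 segment ratio of the amplicon in true/pseudo ERBB2+ genomes
        "cn_gain": 1.0,
        # protein/RNA shift of amplicon genes in amplified, expressing tumors
        "amplicon_expr_high": 2.5,
        # deterministic low level of amplicon genes in pseudo/false ERBB2+
        "amplicon_expr_low": -6.0,
        # on-treatment log2 change, pCR patients only
        "erbb2_protein_on_tx_pcr": -1.0,
        "erbb2_phospho_on_tx_pcr": -1.5,
        "mtor_phospho_on_tx_pcr": -1.5,
        # deterministic mucin-panel deviation (3.5 patient-SD at default SD 2)
        "mucin_outlier": 7.0,
    }


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort."""

    n_patients: int = 14
    pcr_fraction: float = 9 / 14
    n_genes: int = 2500
    n_phosphosites: int = 1500
    plex_size: int = 11
    replicate_plan: dict[str, dict[str, int]] | None = None
    amplicon_class_map: dict[str, str] | None = None
    effect_sizes: dict[str, float] = field(default_factory=default_effect_sizes)
    mrna_protein_rho: float = 0.38
    noise_sd: float = 0.3
    patient_sd: float = 2.0
    plex_sd: float = 0.3
    site_sd: float = 0.5
    mucin_patient: str | None = None  # default: last non-pCR patient
    n_psm_features: int = 300
    psm_violation_rates: dict[str, float] = field(
        default_factory=lambda: {"unlabeled": 0.002, "low_purity": 0.02, "negative_delta": 0.02}
    )
    full_label_rate: float = 0.97
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise ValueError("pcr_fraction must be in [0, 1]")
        if self.plex_size not in (10, 11):
            raise ValueError("plex_size must be 10 or 11")
        for name in ("noise_sd", "patient_sd", "plex_sd", "site_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_genes < len(SPECIAL_GENES):
            raise ValueError(f"n_genes must be >= {len(SPECIAL_GENES)}")
        patients = set(self.patient_ids())
        if self.amplicon_class_map is not None:
            for pat, cls in self.amplicon_class_map.items():
                if pat not in patients:
                    raise ValueError(f"amplicon_class_map patient {pat!r} does not exist")
                if cls not in AMPLICON_CLASSES:
                    raise ValueError(f"unknown amplicon class {cls!r} for {pat!r}")
        if self.replicate_plan is not None:
            for pat in self.replicate_plan:
                if pat not in patients:
                    raise ValueError(f"replicate_plan patient {pat!r} does not exist")

    # -- derived design ----------------------------------------------------
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]

    def n_pcr(self) -> int:
        return int(round(self.n_patients * self.pcr_fraction))

    def pcr_ids(self) -> list[str]:
        return self.patient_ids()[: self.n_pcr()]

    def nonpcr_ids(self) -> list[str]:
        return self.patient_ids()[self.n_pcr():]


def default_replicate_plan(pcr_ids: list[str], nonpcr_ids: list[str]) -> dict[str, dict[str, int]]:
    """Core counts per patient and timepoint.

    Every patient gets a pre-treatment core; on-treatment cores in up to
    7 pCR and 3 non-pCR patients; duplicated pre+on cores in four
    patients and a triplicate pre-treatment series in one (35 cores at
    the default 9 pCR / 5 non-pCR design).
    """
    plan: dict[str, dict[str, int]] = {p: {"pre": 1, "on": 0} for p in pcr_ids + nonpcr_ids}
    for p in pcr_ids[:7]:
        plan[p]["on"] = 1
    for p in nonpcr_ids[:3]:
        plan[p]["on"] = 1
    dup = pcr_ids[:2] + nonpcr_ids[:2]
    for p in dup:
        plan[p]["pre"] += 1
        if plan[p]["on"]:
            plan[p]["on"] += 1
    if len(nonpcr_ids) >= 3:
        trip = nonpcr_ids[2]
        plan[trip]["pre"] = 3
        if plan[trip]["on"]:
            plan[trip]["on"] += 1
    return plan


def default_amplicon_class_map(pcr_ids: list[str], nonpcr_ids: list[str]) -> dict[str, str]:
    """All pCR patients true ERBB2+; among non-pCR one false positive,
    two pseudo positives, remainder true positives."""
    mapping = {p: "true_pos" for p in pcr_ids}
    for i, p in enumerate(nonpcr_ids):
        if i == 0:
            mapping[p] = "false_pos"
        elif i in (1, 2):
            mapping[p] = "pseudo_pos"
        else:
            mapping[p] = "true_pos"
    return mapping


# --------------------------------------------------------------------------
# PDX tumor volume
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PdxMeasurement:
    """Caliper measurement of a xenograft tumor, in mm."""

    length: float
    width: float


def tumor_volume(m: PdxMeasurement) -> float:
    """Ellipsoid tumor volume in mm^3: V = 4/3·pi·(L/2)²·(W/2)."""
    if m.length <= 0 or m.width <= 0:
        raise ValueError("tumor dimensions must be positive")
    return (4.0 / 3.0) * math.pi * (m.length / 2.0) ** 2 * (m.width / 2.0)


# --------------------------------------------------------------------------
# Citation fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CitationRecord:
    """One publication: concatenated title/abstract/keywords plus the gene
    symbols it is associated with."""

    pub_id: str
    text_blob: str
    gene_symbols: frozenset[str]


_RESIST_WORDS = ["resistance", "Resistant", "resist", "chemoresistance"]
_RECUR_WORDS = ["recurrence", "Recurrent", "recur"]
_DISEASE = ["breast cancer", "Breast Cancer", "BREAST CANCER"]
_OTHER_DISEASE = ["lung cancer", "ovarian cancer", "melanoma"]


def generate_citation_fixture(
    n_pubs: int, gene_universe: list[str], seed: int
) -> tuple[list[CitationRecord], dict[str, int]]:
    """Deterministic offline stand-in for a PubMed crawl.

    Returns the records plus the truth tally: for each gene, the number of
    qualifying publications (text containing "resist" or "recur" together
    with "breast cancer", case-insensitively, and <=100 gene associations)
    associated with it.
    """
    if n_pubs < 0:
        raise ValueError("n_pubs must be >= 0")
    if n_pubs > 0 and not gene_universe:
        raise ValueError("gene_universe must be non-empty when n_pubs > 0")
    rng = np.random.default_rng(seed)
    records: list[CitationRecord] = []
    truth: dict[str, int] = {g: 0 for g in gene_universe}
    for i in range(n_pubs):
        has_resist = rng.random() < 0.45
        has_recur = rng.random() < 0.35
        right_disease = rng.random() < 0.6
        big = rng.random() < 0.10 and len(gene_universe) > 100
        parts = ["A study of tumor biology."]
        if has_resist:
            parts.append(f"Therapy {rng.choice(_RESIST_WORDS)} was observed.")
        if has_recur:
            parts.append(f"Disease {rng.choice(_RECUR_WORDS)} after surgery.")
        parts.append(
            f"Cohort of patients with {rng.choice(_DISEASE) if right_disease else rng.choice(_OTHER_DISEASE)}."
        )
        text = " ".join(parts)
        if big:
            n_genes = int(rng.integers(101, min(len(gene_universe), 200) + 1))
        else:
            n_genes = int(rng.integers(1, min(6, len(gene_universe) + 1)))
        genes = frozenset(rng.choice(gene_universe, size=n_genes, replace=False).tolist())
        records.append(CitationRecord(f"PUB{i + 1:05d}", text, genes))
        qualifies = (has_resist or has_recur) and right_disease and n_genes <= 100
        if qualifies:
            for g in genes:
                truth[g] += 1
    return records, truth


def citations_to_frame(records: list[CitationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pub_id": [r.pub_id for r in records],
            "text_blob": [r.text_blob for r in records],
            "gene_symbols": [";".join(sorted(r.gene_symbols)) for r in records],
        }
    )


def citations_from_frame(df: pd.DataFrame) -> list[CitationRecord]:
    return [
        CitationRecord(row.pub_id, row.text_blob, frozenset(str(row.gene_symbols).split(";")))
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# Bundle
# --------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Everything one synthetic study produces, plus its ground truth."""

    config: CohortConfig
    manifest: pd.DataFrame
    protein: QuantMatrix
    phosphosite: QuantMatrix
    rna: QuantMatrix
    rna_counts: pd.DataFrame
    segments: pd.DataFrame
    gene_models: pd.DataFrame
    cn_genes: QuantMatrix
    integer_calls: pd.DataFrame
    psms: pd.DataFrame
    slides: pd.DataFrame
    citations: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_tsv(self.manifest, out / "manifest.tsv")
        mio.write_gct(self.protein, out / "protein.gct")
        mio.write_gct(self.phosphosite, out / "phosphosite.gct")
        mio.write_gct(self.rna, out / "rna.gct")
        mio.write_tsv(self.rna_counts, out / "rna_counts.tsv", index=True)
        mio.write_seg(self.segments, out / "segments.seg")
        mio.write_tsv(self.gene_models, out / "gene_models.tsv")
        mio.write_gct(self.cn_genes, out / "cn_genes.gct")
        mio.write_tsv(self.integer_calls, out / "integer_calls.tsv", index=True)
        mio.write_tsv(self.psms, out / "psms.tsv")
        mio.write_tsv(self.slides, out / "slides.tsv")
        mio.write_tsv(self.citations, out / "citations.tsv")
        if self.phosphosite.feature_meta is not None:
            mio.write_tsv(self.phosphosite.feature_meta, out / "site_annotations.tsv", index=True)
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _gene_universe(n_genes: int) -> list[str]:
    fillers = [f"G{i + 1:05d}" for i in range(n_genes - len(SPECIAL_GENES))]
    return SPECIAL_GENES + fillers


def _gene_models(genes: list[str]) -> pd.DataFrame:
    """Synthetic gene coordinates: amplicon genes contiguous on chr17,
    TOP2A just distal, everything else laid out round-robin on 1..22,X."""
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    rows = []
    fixed = {
        "STARD3": ("17", 39_620_000, 39_650_000),
        "PGAP3": ("17", 39_660_000, 39_690_000),
        "ERBB2": ("17", 39_700_000, 39_740_000),
        "GRB7": ("17", 39_750_000, 39_780_000),
        TOP2A: ("17", 40_400_000, 40_430_000),
    }
    others = [g for g in genes if g not in fixed]
    for i, g in enumerate(others):
        chrom = chroms[i % len(chroms)]
        start = 1_000_000 + (i // len(chroms)) * 60_000
        rows.append((g, chrom, start, start + 30_000))
    for g, (c, s, e) in fixed.items():
        rows.append((g, c, s, e))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return df.set_index("gene").loc[genes].reset_index()


def _build_manifest(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    pcr, nonpcr = config.pcr_ids(), config.nonpcr_ids()
    plan = config.replicate_plan or default_replicate_plan(pcr, nonpcr)
    rows = []
    for pat in config.patient_ids():
        counts = plan.get(pat, {"pre": 1, "on": 0})
        for tp in ("pre", "on"):
            for k in range(counts.get(tp, 0)):
                rows.append(
                    {
                        "core_id": f"{pat}_{tp}{k + 1}",
                        "patient_id": pat,
                        "timepoint": tp,
                        "group": "pCR" if pat in pcr else "non-pCR",
                        "replicate": k + 1,
                    }
                )
    manifest = pd.DataFrame(rows)
    # randomized plex layout: members fill plexes of (plex_size - 2) cores,
    # the remaining two channels carry the common references
    channels = TMT11_CHANNELS if config.plex_size == 11 else TMT10_CHANNELS
    n_members = config.plex_size - 2
    order = rng.permutation(len(manifest))
    plex, channel = [""] * len(manifest), [""] * len(manifest)
    for slot, idx in enumerate(order):
        plex[idx] = f"plex{slot // n_members + 1}"
        channel[idx] = channels[slot % n_members]
    manifest["plex"] = plex
    manifest["channel"] = channel
    manifest["cr_channel"] = "131N"  # the pool of all patients
    return manifest


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a complete synthetic study bundle, fully determined by
    ``config.seed``."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    eff = {**default_effect_sizes(), **config.effect_sizes}
    pcr, nonpcr = config.pcr_ids(), config.nonpcr_ids()
    class_map = config.amplicon_class_map or default_amplicon_class_map(pcr, nonpcr)
    class_map = {**{p: "true_pos" for p in config.patient_ids()}, **class_map}
    mucin_patient = config.mucin_patient or (nonpcr[-1] if nonpcr else pcr[-1])

    manifest = _build_manifest(config, rng)
    genes = _gene_universe(config.n_genes)
    cores = manifest["core_id"].tolist()
    core_patient = manifest.set_index("core_id")["patient_id"]
    core_tp = manifest.set_index("core_id")["timepoint"]
    core_plex = manifest.set_index("core_id")["plex"]
    plexes = sorted(manifest["plex"].unique())

    n_g, n_c = len(genes), len(cores)
    gi = {g: i for i, g in enumerate(genes)}
    pat_list = config.patient_ids()
    pi = {p: i for i, p in enumerate(pat_list)}

    mu = rng.normal(0.0, 0.3, size=n_g)
    patient_eff = rng.normal(0.0, config.patient_sd, size=(n_g, len(pat_list)))
    plex_eff = rng.normal(0.0, config.plex_sd, size=(n_g, len(plexes)))
    plex_idx = {b: j for j, b in enumerate(plexes)}

    spikes: list[dict] = []  # truth bookkeeping

    def spike(gene: str, patient: str, value: float, note: str) -> None:
        patient_eff[gi[gene], pi[patient]] = value
        spikes.append(
            {
                "gene": gene,
                "patient": patient,
                "level": "protein",
                "deviation": float(value),
                "sigma_units": float(value) / config.patient_sd,
                "note": note,
            }
        )

    # amplicon expression classes
    for pat in pat_list:
        cls = class_map[pat]
        for g in AMPLICON_GENES:
            if pat in pcr:
                # reference patients: shifted but still random
                patient_eff[gi[g], pi[pat]] += eff["amplicon_expr_high"]
            elif cls == "true_pos":
                spike(g, pat, eff["amplicon_expr_high"], "amplicon true_pos")
            else:
                spike(g, pat, eff["amplicon_expr_low"], f"amplicon {cls}")
    # mucin outlier panel
    for g in MUCIN_GENES[:4]:
        spike(g, mucin_patient, eff["mucin_outlier"], "mucin outlier panel")

    # protein matrix
    prot = np.empty((n_g, n_c))
    tx = np.zeros((n_g, n_c))
    erbb2_row = gi["ERBB2"]
    for j, c in enumerate(cores):
        p, t, b = core_patient[c], core_tp[c], core_plex[c]
        col = mu + patient_eff[:, pi[p]] + plex_eff[:, plex_idx[b]]
        if t == "on" and p in pcr:
            tx[erbb2_row, j] = eff["erbb2_protein_on_tx_pcr"]
        prot[:, j] = col + tx[:, j]
    prot += rng.normal(0.0, config.noise_sd, size=prot.shape)
    protein = QuantMatrix(pd.DataFrame(prot, index=genes, columns=cores), "protein")

    # phosphosites: sites ride on their protein's value plus a fixed
    # per-site offset and site-level treatment effects
    site_rows = []
    for k in range(8):
        site_rows.append(("ERBB2", f"ERBB2_s{k + 1}"))
    for g in MTOR_TARGET_GENES:
        for k in range(3):
            site_rows.append((g, f"{g}_s{k + 1}"))
    host_pool = [g for g in genes if g not in {r[0] for r in site_rows}]
    counts_per_host: dict[str, int] = {}
    while len(site_rows) < config.n_phosphosites:
        g = host_pool[int(rng.integers(0, len(host_pool)))]
        counts_per_host[g] = counts_per_host.get(g, 0) + 1
        site_rows.append((g, f"{g}_s{counts_per_host[g]}"))
    site_genes = [g for g, _ in site_rows]
    site_ids = [s for _, s in site_rows]
    windows = []
    for _ in site_ids:
        w = rng.choice(list(AA_ALPHABET), size=15)
        w[7] = rng.choice(list("STY"))
        windows.append("".join(w))
    site_offset = rng.normal(0.0, config.site_sd, size=len(site_ids))
    site_vals = prot[[gi[g] for g in site_genes], :] + site_offset[:, None]
    for j, c in enumerate(cores):
        p, t = core_patient[c], core_tp[c]
        if t == "on" and p in pcr:
            for i, g in enumerate(site_genes):
                if g == "ERBB2":
                    site_vals[i, j] += eff["erbb2_phospho_on_tx_pcr"]
                elif g in MTOR_TARGET_GENES:
                    site_vals[i, j] += eff["mtor_phospho_on_tx_pcr"]
    site_vals += rng.normal(0.0, config.noise_sd, size=site_vals.shape)
    site_meta = pd.DataFrame(
        {"gene": site_genes, "window": windows, "localized": True}, index=site_ids
    )
    phosphosite = QuantMatrix(
        pd.DataFrame(site_vals, index=site_ids, columns=cores), "phosphosite", site_meta
    )

    # RNA: Gaussian copula with protein, then negative-binomial counts
    rho_s = config.mrna_protein_rho
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    prot_z = (prot - prot.mean(axis=1, keepdims=True)) / prot.std(axis=1, keepdims=True)
    rna_latent = rho_p * prot_z + math.sqrt(1.0 - rho_p**2) * rng.normal(size=prot.shape)
    rna_log2 = rna_latent * 2.0 + rng.normal(0.0, 0.3, size=(n_g, 1))
    depth = rng.uniform(5.0, 11.0, size=(n_g, 1))
    mean_counts = np.exp2(np.clip(rna_log2 + depth, None, 24.0))
    size_par = 50.0
    counts = rng.negative_binomial(size_par, size_par / (size_par + mean_counts))
    rna_counts = pd.DataFrame(counts, index=genes, columns=cores)
    from .ingest import upper_quartile_normalize  # deferred: avoids import cycle

    rna = upper_quartile_normalize(rna_counts)

    # copy-number segments (one tumor genome per patient)
    seg_rows = []
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    chrom_len = 100_000_000
    amp_lo, amp_hi = 39_500_000, 40_100_000
    for pat in pat_list:
        cls = class_map[pat]
        for chrom in chroms:
            cuts = sorted(rng.integers(1_000_000, chrom_len - 1_000_000, size=2).tolist())
            bounds = [0, *cuts, chrom_len]
            pieces = [(bounds[i], bounds[i + 1]) for i in range(3) if bounds[i] < bounds[i + 1]]
            if chrom == "17":
                flat: list[tuple[int, int]] = [(0, amp_lo), (amp_hi, chrom_len)]
                gain = eff["cn_gain"] if cls in ("true_pos", "pseudo_pos") else 0.0
                for s, e in flat:
                    seg_rows.append((pat, chrom, s, e, rng.normal(0.0, 0.1)))
                seg_rows.append((pat, chrom, amp_lo, amp_hi, gain + rng.normal(0.0, 0.05)))
            else:
                for s, e in pieces:
                    seg_rows.append((pat, chrom, s, e, rng.normal(0.0, 0.1)))
    segments = pd.DataFrame(seg_rows, columns=mio.SEG_COLUMNS)
    gene_models = _gene_models(genes)

    from .genomics import gene_copy_number  # deferred: avoids import cycle

    cn_genes = gene_copy_number(segments, gene_models)
    calls = np.select(
        [cn_genes.data.values >= 0.9, cn_genes.data.values >= 0.3,
         cn_genes.data.values <= -0.9, cn_genes.data.values <= -0.3],
        [2, 1, -2, -1],
        default=0,
    )
    integer_calls = pd.DataFrame(calls, index=cn_genes.data.index, columns=cn_genes.data.columns)

    psms = _generate_psms(config, manifest, protein, rng)

    slides = pd.DataFrame(
        {
            "core_id": cores,
            **{f"tc{k + 1}": np.round(rng.uniform(55, 90, size=n_c), 1) for k in range(4)},
        }
    )

    cite_records, cite_truth = generate_citation_fixture(
        60, genes[: min(200, n_g)], seed=int(rng.integers(0, 2**31 - 1))
    )
    citations = citations_to_frame(cite_records)

    truth = {
        "pcr_status": {p: (p in pcr) for p in pat_list},
        "amplicon_class": {p: class_map[p] for p in pat_list},
        "mucin_patient": mucin_patient,
        "mucin_genes": MUCIN_GENES[:4],
        "mtor_target_genes": MTOR_TARGET_GENES,
        "spiked_outliers": spikes,
        "treatment_effects": {
            "erbb2_protein_on_tx_pcr": eff["erbb2_protein_on_tx_pcr"],
            "erbb2_phospho_on_tx_pcr": eff["erbb2_phospho_on_tx_pcr"],
            "mtor_phospho_on_tx_pcr": eff["mtor_phospho_on_tx_pcr"],
        },
        "effect_sizes": {k: float(v) for k, v in eff.items()},
        "citation_counts": cite_truth,
        "mrna_protein_rho": rho_s,
    }

    return CohortBundle(
        config=config,
        manifest=manifest,
        protein=protein,
        phosphosite=phosphosite,
        rna=rna,
        rna_counts=rna_counts,
        segments=segments,
        gene_models=gene_models,
        cn_genes=cn_genes,
        integer_calls=integer_calls,
        psms=psms,
        slides=slides,
        citations=citations,
        truth=truth,
    )


def spike_amplicon_class(bundle: CohortBundle, patient: str, amplicon_class: str) -> CohortBundle:
    """Regenerate a bundle with one patient's ERBB2-amplicon class changed.

    The new class is expressed coherently across the CNA, RNA and protein
    layers at the configured effect magnitudes; everything else about the
    study design (and the seed) is preserved.
    """
    from dataclasses import replace

    if amplicon_class not in AMPLICON_CLASSES:
        raise ValueError(f"unknown amplicon class {amplicon_class!r}; expected {AMPLICON_CLASSES}")
    if patient not in bundle.config.patient_ids():
        raise KeyError(f"patient {patient!r} not in cohort")
    new_map = {**bundle.truth["amplicon_class"], patient: amplicon_class}
    return generate_cohort(replace(bundle.config, amplicon_class_map=new_map))


def _generate_psms(
    config: CohortConfig,
    manifest: pd.DataFrame,
    protein: QuantMatrix,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """PSM-level reporter intensities consistent with the protein matrix.

    For each plex the common-reference channel is the mean of the member
    channels' linear abundances (the CR pool holds an equal share of every
    sample).  Label state, precursor purity and delta forward-reverse score
    are drawn from mixtures with the configured violation rates.
    """
    channels = TMT11_CHANNELS if config.plex_size == 11 else TMT10_CHANNELS
    cr_channel = "131N"
    rates = config.psm_violation_rates
    feats = protein.features[: config.n_psm_features]
    rows = []
    counter = 0
    for plex, grp in manifest.groupby("plex", sort=True):
        member_cores = grp["core_id"].tolist()
        member_channels = grp["channel"].tolist()
        lin = np.exp2(protein.data.loc[feats, member_cores].values)  # linear CR-ratio scale
        cr = lin.mean(axis=1)
        for i, f in enumerate(feats):
            n_psm = 1 + rng.poisson(1.0)
            for _ in range(n_psm):
                counter += 1
                scale = float(np.exp(rng.normal(np.log(1e5), 0.5)))
                noise = np.exp(rng.normal(0.0, 0.05, size=len(member_cores)))
                u = rng.random()
                if u < rates["unlabeled"]:
                    label = "none"
                elif rng.random() < config.full_label_rate:
                    label = "full"
                else:
                    label = "partial"
                purity = (
                    float(rng.uniform(0.0, 0.5))
                    if rng.random() < rates["low_purity"]
                    else float(rng.uniform(0.5, 1.0))
                )
                delta = float(abs(rng.normal(1.0, 0.5)))
                if rng.random() < rates["negative_delta"]:
                    delta = -delta
                row = {
                    "psm_id": f"PSM{counter:07d}",
                    "plex": plex,
                    "feature_id": f,
                    "label_state": label,
                    "precursor_purity": purity,
                    "delta_fr_score": delta,
                    f"intensity_{cr_channel}": scale * float(cr[i]),
                }
                for ch, val in zip(member_channels, lin[i] * noise):
                    row[f"intensity_{ch}"] = scale * float(val)
                rows.append(row)
    id_cols = ["psm_id", "plex", "feature_id", "label_state", "precursor_purity", "delta_fr_score"]
    if not rows:
        return pd.DataFrame(columns=id_cols)
    df = pd.DataFrame(rows)
    # emulate mixing: samples within a plex are re-balanced so each member
    # channel's median ratio to the CR is 1 (equal amounts per channel)
    for plex in df["plex"].unique():
        mask = df["plex"] == plex
        cr = df.loc[mask, f"intensity_{cr_channel}"].to_numpy(float)
        for ch in channels:
            col = f"intensity_{ch}"
            if ch == cr_channel or col not in df.columns:
                continue
            vals = df.loc[mask, col].to_numpy(float)
            ratios = vals / cr
            if not np.isfinite(ratios).any():
                continue
            med = np.nanmedian(ratios)
            if np.isfinite(med) and med > 0:
                df.loc[mask, col] = vals / med
    # stable column order: ids/attrs first, then channels in reporter order
    chan_cols = [f"intensity_{c}" for c in channels if f"intensity_{c}" in df.columns]
    return df[id_cols + chan_cols]
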