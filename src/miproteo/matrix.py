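"""Feature-by-sample quantification matrices.

The whole pipeline moves data around as :class:`QuantMatrix`: a pandas
DataFrame of features (rows) by samples (columns) tagged with the
measurement level it carries.  Protein and phosphosite values are log2
ratios to the plex common reference; RNA values are log2 upper-quartile
normalized abundances; ``cna-gene`` values are gene-level copy-number
log2 ratios.  Missing measurements are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: measurement levels a QuantMatrix may carry
LEVELS = ("protein", "phosphosite", "phosphoprotein", "rna", "cna-gene")


@dataclass
class QuantMatrix:
    """A features x samples matrix with a measurement-level tag.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index and sample ids as columns.
        Missing values are NaN.
    level:
        One of :data:`LEVELS`.
    feature_meta:
        Optional per-feature annotation (e.g. phosphosite -> gene symbol,
        flanking window) aligned to ``data.index``.
    """

    data: pd.DataFrame
    level: str
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in QuantMatrix columns")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids in QuantMatrix index")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset_samples(self, samples) -> "QuantMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return QuantMatrix(self.data.loc[:, list(samples)].copy(), self.level, self.feature_meta)

    def copy(self) -> "QuantMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return QuantMatrix(self.data.copy(), self.level, meta)
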