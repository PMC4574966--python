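"""Genotype containers and the plain-text genotype matrix dialect.

Genotypes of bi-allelic SNPs are coded by minor-allele count: 0 (aa),
1 (aA/Aa), 2 (AA).  Missing genotypes carry the sentinel :data:`MISSING`
(-1).  The same container doubles as the generic polytomous item-response
matrix used by the Partial Credit Model, so per-item maxima other than 2
are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype in integer matrices.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs integer response matrix.

    Parameters
    ----------
    values
        ``(n_subjects, n_items)`` integer array with entries in
        ``{0, ..., m_i}`` per item or :data:`MISSING`.
    item_ids
        SNP (item) identifiers, one per column.
    subject_ids
        Sample identifiers, one per row.
    """

    values: np.ndarray
    item_ids: list[str] = field(default=None)  # type: ignore[assignment]
    subject_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                raise ValueError("genotype entries must be integers")
            self.values = self.values.astype(np.int16)
        n, m = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if m < 1:
            raise ValueError("need at least 1 item")
        if self.item_ids is None:
            self.item_ids = [f"snp{j}" for j in range(m)]
        if self.subject_ids is None:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if len(self.item_ids) != m or len(self.subject_ids) != n:
            raise ValueError("id lists do not match matrix shape")
        obs = self.values[self.values != MISSING]
        if obs.size and obs.min() < 0:
            raise ValueError("negative genotype code that is not the missing sentinel")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.any(self.values == MISSING))

    def item_max(self) -> np.ndarray:
        """Observed maximum category per item (missing ignored)."""
        v = np.where(self.values == MISSING, 0, self.values)
        return v.max(axis=0)

    def subset_items(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            [self.item_ids[j] for j in idx],
            list(self.subject_ids),
        )

    def minor_allele_freq(self) -> np.ndarray:
        """Allele frequency of the counted allele per SNP (missing ignored)."""
        v = np.ma.masked_equal(self.values, MISSING)
        return np.asarray(v.mean(axis=0) / 2.0)


def write_geno_text(path, data: GenotypeMatrix) -> None:
    """Write the tab-separated text dialect: header of SNP ids, first column
    subject id, entries 0/1/2 or NA."""
    df = pd.DataFrame(
        np.where(data.values == MISSING, np.nan, data.values),
        index=data.subject_ids,
        columns=data.item_ids,
    )
    df.to_csv(path, sep="\t", na_rep="NA", index_label="subject")


def read_geno_text(path) -> GenotypeMatrix:
    """Read the tab-separated text dialect written by :func:`write_geno_text`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    out = np.where(np.isnan(vals), MISSING, vals).astype(np.int16)
    return GenotypeMatrix(out, list(df.columns), [str(s) for s in df.index])
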