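"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on four aligned tables: a genotype dosage matrix, a
gene expression matrix, a covariate table and a survival table.  Samples are
keyed by string IDs and every stage aligns on those IDs explicitly; no stage
relies on positional correspondence across containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VARIANT_COLS = ["id", "chrom", "pos", "ref", "alt"]
GENE_COLS = ["id", "chrom", "start", "end"]

#: survival cause labels
CAUSE_PRIMARY = "primary"
CAUSE_COMPETING = "competing"
CAUSE_CENSORED = "censored"
CAUSES = (CAUSE_PRIMARY, CAUSE_COMPETING, CAUSE_CENSORED)


class StratwasError(ValueError):
    """Base class for user-facing pipeline errors."""


class InvalidConfigError(StratwasError):
    pass


class FormatError(StratwasError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Dosages are expected counts of the alternative allele in [0, 2];
    fractional values (from imputation) are preserved, never rounded.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_variants)
    variants : DataFrame with columns id, chrom, pos (1-based), ref, alt
    samples : list of sample IDs, order matching ``dosages`` rows
    stratum : optional label of the ancestry stratum this panel belongs to
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    stratum: str | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = list(self.samples)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise FormatError(
                f"dosage rows ({n}) != number of samples ({len(self.samples)})"
            )
        if m != len(self.variants):
            raise FormatError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if len(set(self.samples)) != n:
            raise FormatError("sample-ID collision in genotype panel")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicate variant ID {dup!r}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise FormatError(f"positions not sorted within chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_keys(self) -> pd.Index:
        """(chrom, pos, ref, alt) tuples used for cross-panel matching."""
        v = self.variants
        return pd.Index(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in ids]
        return replace(self, dosages=self.dosages[idx], samples=list(ids))

    def maf(self) -> np.ndarray:
        """Dosage-based minor allele frequency per variant."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class ExpressionMatrix:
    """Samples x genes continuous expression with gene coordinates."""

    values: np.ndarray
    genes: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = self.genes.reset_index(drop=True)
        self.samples = list(self.samples)
        n, g = self.values.shape
        if n != len(self.samples) or g != len(self.genes):
            raise FormatError("expression matrix shape does not match metadata")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.genes["id"].to_numpy() == gene)
        if hits.size == 0:
            raise KeyError(gene)
        return int(hits[0])

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def take_samples(self, ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in ids]
        return replace(self, values=self.values[idx], samples=list(ids))


def align_samples(*objs):
    """Restrict containers to their common samples, in first-object order.

    Accepts GenotypeMatrix / ExpressionMatrix / DataFrame (indexed by sample).
    """
    sample_sets = []
    for o in objs:
        if isinstance(o, (GenotypeMatrix, ExpressionMatrix)):
            sample_sets.append(list(o.samples))
        else:
            sample_sets.append(list(o.index))
    common = set(sample_sets[0])
    for s in sample_sets[1:]:
        common &= set(s)
    order = [s for s in sample_sets[0] if s in common]
    if not order:
        raise StratwasError("no samples in common across inputs")
    out = []
    for o in objs:
        if isinstance(o, (GenotypeMatrix, ExpressionMatrix)):
            out.append(o.take_samples(order))
        else:
            out.append(o.loc[order])
    return out
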