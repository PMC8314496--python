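"""Core data containers for multi-population SNP genotype analysis.

The central object is :class:`GenotypeDataset`: a samples-by-variants matrix
of alternate-allele dosages (0, 1, 2, or :data:`MISSING`) together with
variant coordinates, per-sample population labels, optional read depths, and
contig lengths. Every statistic in the package consumes this container.

Coordinate conventions: variant positions are 1-based (VCF convention);
genomic windows elsewhere in the package are 0-based half-open ``[start,
end)``. Conversion between the two happens only at the window/annotation
boundary (see :mod:`radpop.sweep`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype.
MISSING: int = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


class RadpopError(Exception):
    """Base class for package errors."""


class ConfigurationError(RadpopError):
    """Inconsistent inputs (e.g. VCF samples absent from the population map)."""


class ParseError(RadpopError):
    """Malformed input file."""


@dataclass(frozen=True)
class PopulationMap:
    """Ordered sample -> population assignment.

    Sample identifiers must be unique; population codes must be non-empty.
    """

    samples: tuple[str, ...]
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.populations):
            raise ConfigurationError("sample and population columns differ in length")
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if list(self.samples).count(s) > 1})
            raise ConfigurationError(f"duplicate sample ids in population map: {dupes}")
        if any(not p for p in self.populations):
            raise ConfigurationError("empty population code in population map")

    @property
    def mapping(self) -> dict[str, str]:
        return dict(zip(self.samples, self.populations))

    def population_codes(self) -> list[str]:
        """Population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)


@dataclass(frozen=True)
class GeneRecord:
    """One gene from a GFF3 annotation; coordinates 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix with population labels.

    Parameters
    ----------
    samples
        Ordered sample identifiers (VCF header order).
    populations
        Mapping sample id -> population code; must cover every sample.
    variants
        DataFrame with columns ``chrom, pos, ref, alt``, sorted by
        ``(chrom, pos)`` with no duplicate coordinates; biallelic SNPs only.
    dosages
        ``(n_samples, n_variants)`` integer matrix of alt-allele counts with
        :data:`MISSING` (= -1) for uncalled genotypes.
    depths
        Optional ``(n_samples, n_variants)`` matrix of read depths.
    contig_lengths
        Mapping chrom -> length in bp. When a chromosome is absent its length
        is taken as the maximum observed position (with a warning).
    """

    samples: list[str]
    populations: dict[str, str]
    variants: pd.DataFrame
    dosages: np.ndarray
    depths: Optional[np.ndarray] = None
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n_s, n_v = len(self.samples), len(self.variants)
        if self.dosages.shape != (n_s, n_v):
            raise ConfigurationError(
                f"dosage matrix shape {self.dosages.shape} != ({n_s}, {n_v})"
            )
        if self.depths is not None and self.depths.shape != (n_s, n_v):
            raise ConfigurationError("depth matrix shape mismatch")
        missing_labels = [s for s in self.samples if s not in self.populations]
        if missing_labels:
            raise ConfigurationError(
                f"samples without population label: {missing_labels}"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ConfigurationError(f"variants table lacks column {col!r}")
        if n_v:
            key = list(zip(self.variants["chrom"], self.variants["pos"]))
            if key != sorted(key):
                raise ConfigurationError("variants not sorted by (chrom, pos)")
            if len(set(key)) != n_v:
                raise ConfigurationError("duplicate (chrom, pos) in variants")
            if (self.variants["pos"] < 1).any():
                raise ConfigurationError("variant positions must be >= 1")
            for chrom, length in self.contig_lengths.items():
                sel = self.variants["chrom"] == chrom
                if sel.any() and self.variants.loc[sel, "pos"].max() > length:
                    raise ConfigurationError(
                        f"variant beyond contig end on {chrom} (length {length})"
                    )
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ConfigurationError("dosages must be in {0, 1, 2, MISSING}")

    # -- accessors ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def population_codes(self) -> list[str]:
        """Population codes in order of first appearance along samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=int,
        )
        if idx.size == 0:
            raise ConfigurationError(
                f"unknown population {population!r}; available: {self.population_codes()}"
            )
        return idx

    def population_dosages(self, population: str) -> np.ndarray:
        """Dosage submatrix for one population (view of member rows)."""
        return self.dosages[self.sample_indices(population)]

    def effective_contig_lengths(self) -> dict[str, int]:
        """Contig lengths from the header, falling back to max observed pos."""
        lengths = dict(self.contig_lengths)
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if chrom not in lengths:
                lengths[str(chrom)] = int(grp["pos"].max())
                logger.warning(
                    "contig %s has no header length; using max position %d",
                    chrom,
                    lengths[str(chrom)],
                )
        return lengths

    def subset_variants(self, mask: np.ndarray) -> "GenotypeDataset":
        """New dataset keeping variants where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            samples=list(self.samples),
            populations=dict(self.populations),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask].copy(),
            depths=None if self.depths is None else self.depths[:, mask].copy(),
            contig_lengths=dict(self.contig_lengths),
        )

    def copy(self) -> "GenotypeDataset":
        return replace(
            self,
            samples=list(self.samples),
            populations=dict(self.populations),
            variants=self.variants.copy(),
            dosages=self.dosages.copy(),
            depths=None if self.depths is None else self.depths.copy(),
            contig_lengths=dict(self.contig_lengths),
        )


def allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) allele counts from a dosage submatrix.

    Missing genotypes contribute no alleles.
    """
    called = dosages != MISSING
    alt = np.where(called, dosages, 0).sum(axis=0)
    ref = 2 * called.sum(axis=0) - alt
    return ref.astype(np.int64), alt.astype(np.int64)
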