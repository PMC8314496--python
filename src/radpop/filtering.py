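"""Genotype- and variant-level filters applied before any statistic.

The pipeline order mirrors standard reduced-representation SNP practice:
first mask low-depth genotype calls, then drop variants on pooled minor
allele frequency and missingness. Both variant thresholds are strict
inequalities: a site is kept only when MAF > ``maf_min`` and the missing
proportion < ``max_missing``.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import MISSING, ConfigurationError, GenotypeDataset, allele_counts

logger = logging.getLogger(__name__)


def apply_depth_mask(gd: GenotypeDataset, min_depth: int = 3) -> GenotypeDataset:
    """Mask genotypes supported by fewer than ``min_depth`` reads.

    Where the dataset carries no depth matrix this is a logged no-op. A new
    dataset is returned; the input is untouched.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    out = gd.copy()
    if gd.depths is None:
        logger.warning("apply_depth_mask: no depth matrix present; nothing masked")
        return out
    mask = out.depths < min_depth
    out.dosages[mask] = MISSING
    n = int(mask.sum())
    if n:
        logger.info("apply_depth_mask: masked %d genotypes below %dx", n, min_depth)
    return out


def filter_variants(
    gd: GenotypeDataset, maf_min: float = 0.05, max_missing: float = 0.2
) -> GenotypeDataset:
    """Keep variants with pooled MAF > ``maf_min`` and missingness < ``max_missing``.

    MAF is computed over the non-missing alleles of all samples pooled
    (the combined cohort is filtered once); the missing proportion is counted
    over all genotypes. Variant order is preserved.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if gd.n_samples == 0:
        raise ConfigurationError("cannot filter a dataset with no samples")
    if gd.n_variants == 0:
        return gd.copy()

    ref, alt = allele_counts(gd.dosages)
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    maf[total == 0] = 0.0
    miss = (gd.dosages == MISSING).mean(axis=0)
    keep = (maf > maf_min) & (miss < max_missing)
    logger.info(
        "filter_variants: kept %d / %d variants (MAF > %g, missing < %g)",
        int(keep.sum()),
        gd.n_variants,
        maf_min,
        max_missing,
    )
    return gd.subset_variants(keep)


def snp_count_per_population(gd: GenotypeDataset) -> dict[str, int]:
    """Count variants segregating within each population.

    A variant counts for a population when both alleles are observed among
    that population's non-missing genotypes.
    """
    counts: dict[str, int] = {}
    for pop in gd.population_codes():
        sub = gd.population_dosages(pop)
        if sub.size and (sub == MISSING).all():
            logger.warning("population %s has no called genotypes", pop)
            counts[pop] = 0
            continue
        ref, alt = allele_counts(sub)
        counts[pop] = int(((ref > 0) & (alt > 0)).sum())
    return counts
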