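"""Per-population diversity statistics: pi, Ho, He, F_IS.

Estimators use the small-sample (unbiased) correction ``n/(n-1)`` on both
expected heterozygosity and per-site nucleotide diversity, appropriate for
breed panels of 4-10 diploids. Per-sample inbreeding coefficients are
``F = 1 - O/E`` with O the observed heterozygote count over the sample's
non-missing polymorphic sites and E the summed unbiased expected
heterozygosity at those sites, computed from that sample's *population*
allele frequencies; the population value is the arithmetic mean over member
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, RadpopError, allele_counts
from .filtering import snp_count_per_population

logger = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    """One population's row of the summary table."""

    population: str
    n_snps: int
    pi: float
    ho: float
    he: float
    fis: float
    avg_fst: float = float("nan")


def site_pi(ref_count: int, alt_count: int) -> float:
    """Mean pairwise difference per site: ``ref*alt / C(n, 2)``.

    Equals the average number of differing allele pairs among the ``n``
    sampled alleles, i.e. the unbiased per-site nucleotide diversity.
    """
    n = ref_count + alt_count
    if n < 2:
        raise ValueError("site_pi needs at least two sampled alleles")
    return ref_count * alt_count / (n * (n - 1) / 2)


def _site_pi_array(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Vectorised :func:`site_pi`; sites with n < 2 contribute NaN."""
    n = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ref * alt / (n * (n - 1) / 2.0)
    return np.where(n >= 2, out, np.nan)


def population_pi(
    gd: GenotypeDataset,
    population: str,
    denominator: str = "callable_length",
) -> float:
    """Per-bp (or per-variant) nucleotide diversity of one population.

    ``denominator='callable_length'`` divides the summed per-site pi by the
    total contig length — the genome-scale normalisation that yields values
    of order 1e-4 for real SNP panels. ``denominator='n_variants'`` divides
    by the number of contributing sites instead (the windowed mode).
    """
    ref, alt = allele_counts(gd.population_dosages(population))
    per_site = _site_pi_array(ref, alt)
    usable = ~np.isnan(per_site)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning(
            "population_pi(%s): skipped %d sites with < 2 alleles", population, n_skipped
        )
    total = float(np.nansum(per_site))
    if denominator == "callable_length":
        denom = float(sum(gd.effective_contig_lengths().values()))
    elif denominator == "n_variants":
        denom = float(usable.sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if denom == 0:
        raise RadpopError(f"zero pi denominator for population {population}")
    return total / denom


def heterozygosity(gd: GenotypeDataset, population: str) -> tuple[float, float]:
    """(Ho, He) averaged over sites with >= 2 non-missing genotypes.

    Ho is the fraction of heterozygous genotypes; He is the unbiased
    expected heterozygosity ``2*p*q * n/(n-1)`` with n the non-missing
    allele count. Both means run over the identical site set.
    """
    sub = gd.population_dosages(population)
    called = sub != MISSING
    n_geno = called.sum(axis=0)
    include = n_geno >= 2
    if not include.any():
        raise RadpopError(f"no sites with >= 2 genotypes in population {population}")
    het = (sub == 1).sum(axis=0)
    ref, alt = allele_counts(sub)
    n_alleles = (ref + alt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
        ho_site = het / n_geno
        he_site = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
    return float(ho_site[include].mean()), float(he_site[include].mean())


def _per_sample_fis(gd: GenotypeDataset, population: str) -> dict[str, float]:
    """F for every member sample; NaN where E = 0."""
    idx = gd.sample_indices(population)
    sub = gd.dosages[idx]
    ref, alt = allele_counts(sub)
    n_alleles = (ref + alt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
        e_site = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
    polymorphic = (ref > 0) & (alt > 0) & (n_alleles >= 2)

    out: dict[str, float] = {}
    for row, i in enumerate(idx):
        use = polymorphic & (sub[row] != MISSING)
        e = float(e_site[use].sum())
        sample = gd.samples[i]
        if e == 0.0:
            logger.warning("F undefined for sample %s (E = 0); excluded", sample)
            out[sample] = float("nan")
            continue
        o = float((sub[row][use] == 1).sum())
        out[sample] = 1.0 - o / e
    return out


def fis_per_sample(gd: GenotypeDataset, sample: str) -> float:
    """Inbreeding coefficient ``1 - O/E`` for one sample (population freqs)."""
    if sample not in gd.populations:
        raise RadpopError(f"unknown sample {sample!r}")
    return _per_sample_fis(gd, gd.populations[sample])[sample]


def population_fis(gd: GenotypeDataset, population: str) -> float:
    """Mean per-sample F over the population, excluding undefined samples."""
    values = np.array(list(_per_sample_fis(gd, population).values()))
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise RadpopError(f"F undefined for every sample of {population}")
    return float(defined.mean())


def diversity_table(
    gd: GenotypeDataset, pi_denominator: str = "callable_length"
) -> pd.DataFrame:
    """Summary table: population, n_snps, pi, ho, he, fis, avg_fst.

    The ``avg_fst`` column is NaN here; the differentiation module fills it
    (see :func:`radpop.fst.average_fst`).
    """
    counts = snp_count_per_population(gd)
    rows = []
    for pop in gd.population_codes():
        ho, he = heterozygosity(gd, pop)
        rows.append(
            DiversityStats(
                population=pop,
                n_snps=counts[pop],
                pi=population_pi(gd, pop, denominator=pi_denominator),
                ho=ho,
                he=he,
                fis=population_fis(gd, pop),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["pi_denominator"] = pi_denominator
    df.attrs["fis_estimator"] = "per-sample 1 - O/E, population frequencies"
    return df
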