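"""Weir-Cockerham F_ST at site, population-pair, breed-average and window level.

The single estimator used throughout is Weir & Cockerham's (1984) theta for
two populations, combined across sites (and across sites within a window) as
a ratio of sums: ``theta = sum(a) / sum(a + b + c)`` where a, b, c are the
among-population, among-individual-within-population and within-individual
variance components. Slightly negative estimates are reported unclamped —
clamping would distort the empirical quantiles the sweep scan relies on.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, RadpopError

logger = logging.getLogger(__name__)


class FstComponents(NamedTuple):
    a: float
    b: float
    c: float


class FstEstimate(NamedTuple):
    theta: float
    n_sites: int


def wc_site_components(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> FstComponents:
    """Variance components a, b, c for one site and two populations.

    Parameters are per-population sample size in diploids (``n``), alt-allele
    frequency (``p``) and heterozygote proportion (``h``). Each population
    needs >= 2 called genotypes.
    """
    if min(n1, n2) < 2:
        raise RadpopError("wc_site_components requires >= 2 genotypes per population")
    a, b, c = _wc_components_arrays(
        np.array([n1], float),
        np.array([p1], float),
        np.array([h1], float),
        np.array([n2], float),
        np.array([p2], float),
        np.array([h2], float),
    )
    return FstComponents(float(a[0]), float(b[0]), float(c[0]))


def _wc_components_arrays(
    n1: np.ndarray,
    p1: np.ndarray,
    h1: np.ndarray,
    n2: np.ndarray,
    p2: np.ndarray,
    h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-population Weir-Cockerham components."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _site_tallies(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n diploids, alt frequency, het proportion) for one population."""
    called = sub != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = (sub == 1).sum(axis=0) / n
    return n, p, h


def site_components(
    gd: GenotypeDataset, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (a, b, c, usable) arrays over all variants.

    A site is usable when both populations have >= 2 called genotypes.
    """
    n1, p1, h1 = _site_tallies(gd.population_dosages(pop_a))
    n2, p2, h2 = _site_tallies(gd.population_dosages(pop_b))
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c = _wc_components_arrays(n1, p1, h1, n2, p2, h2)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def pairwise_fst(gd: GenotypeDataset, pop_a: str, pop_b: str) -> FstEstimate:
    """Ratio-of-sums theta over all usable sites (may be slightly negative)."""
    a, b, c, usable = site_components(gd, pop_a, pop_b)
    n_sites = int(usable.sum())
    if n_sites == 0:
        raise RadpopError(f"no usable sites for F_ST between {pop_a} and {pop_b}")
    denom = float((a + b + c).sum())
    if denom == 0.0:
        raise RadpopError(
            f"zero total variance between {pop_a} and {pop_b} (all sites monomorphic)"
        )
    return FstEstimate(theta=float(a.sum()) / denom, n_sites=n_sites)


def pairwise_fst_matrix(gd: GenotypeDataset) -> pd.DataFrame:
    """Symmetric matrix of pairwise theta over all populations."""
    pops = gd.population_codes()
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            theta = pairwise_fst(gd, pa, pb).theta
            mat.loc[pa, pb] = mat.loc[pb, pa] = theta
    return mat


def average_fst(gd: GenotypeDataset, population: str) -> float:
    """Arithmetic mean of pairwise theta versus every other population."""
    pops = gd.population_codes()
    if len(pops) < 2:
        raise RadpopError("average_fst needs at least two populations")
    others = [p for p in pops if p != population]
    if not others:
        raise RadpopError(f"unknown population {population!r}")
    failures = []
    values = []
    for other in others:
        try:
            values.append(pairwise_fst(gd, population, other).theta)
        except RadpopError as exc:
            failures.append((other, str(exc)))
    if failures:
        raise RadpopError(f"pairwise F_ST failed for pairs: {failures}")
    return float(np.mean(values))


def window_fst(
    gd: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    windows: Sequence,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Per-window ratio-of-sums theta.

    ``windows`` are 0-based half-open intervals (see
    :func:`radpop.sweep.make_windows`). Windows with fewer than ``min_snps``
    usable sites are flagged unusable; their theta is NaN.
    """
    a, b, c, usable_site = site_components(gd, pop_a, pop_b)
    chrom_arr = gd.variants["chrom"].to_numpy()
    pos0 = gd.variants["pos"].to_numpy() - 1  # to 0-based for window overlap

    rows = []
    for w in windows:
        in_w = (chrom_arr == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        sel = in_w & usable_site
        n = int(sel.sum())
        denom = float((a[sel] + b[sel] + c[sel]).sum())
        theta = float(a[sel].sum()) / denom if denom != 0.0 else float("nan")
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": n,
                "fst": theta if n >= min_snps else float("nan"),
                "usable": n >= min_snps and denom != 0.0,
            }
        )
    return pd.DataFrame(rows)
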