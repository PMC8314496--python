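"""Selective-sweep scan: windowed F_ST + pi-ratio, top-quantile candidates,
region merging, gene annotation, and over-representation statistics.

The scan slides fixed-size windows (default 100 kb, 10 kb step; 0-based
half-open coordinates) along each contig and computes, per window, the
two-population Weir-Cockerham theta and the per-bp nucleotide diversity of a
target and a control population. Windows in the top quantile (default 5%)
of BOTH the F_ST ranking and the pi-ratio ranking (``pi_control /
pi_target``, so diversity loss in the target ranks high) are candidates;
a union mode is available. Overlapping candidates merge into regions, which
are annotated with overlapping genes; gene-set over-representation uses an
upper-tail hypergeometric test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datamodel import GeneRecord, GenotypeDataset, RadpopError
from .diversity import _site_pi_array
from .datamodel import allele_counts
from .fst import site_components

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    windows: list[Window]
    max_fst: float
    max_pi_ratio: float
    gene_ids: list[str] = field(default_factory=list)


def make_windows(
    contig_lengths: Mapping[str, int], size: int = 100_000, step: int = 10_000
) -> list[Window]:
    """Full sliding windows per contig: starts 0, step, 2*step, ...

    Only windows entirely inside the contig are emitted; a contig shorter
    than ``size`` yields none (with a warning).
    """
    if not (size >= step > 0):
        raise ValueError("need size >= step > 0")
    windows: list[Window] = []
    for chrom, length in contig_lengths.items():
        if length < size:
            logger.warning("contig %s (%d bp) shorter than window size", chrom, length)
            continue
        for start in range(0, length - size + 1, step):
            windows.append(Window(chrom=chrom, start=start, end=start + size))
    return windows


def window_stats(
    gd: GenotypeDataset,
    target_pop: str,
    control_pop: str,
    windows: Sequence[Window],
    min_snps: int = 10,
) -> pd.DataFrame:
    """Per-window theta, per-bp pi for both populations, and the pi ratio.

    A window is usable when both populations have at least ``min_snps``
    contributing sites. ``pi_ratio = pi_control / pi_target`` with the
    target pi floored at the smallest positive window pi observed (floor
    logged) so sweeps that wiped out all target diversity stay finite.
    """
    a, b, c, fst_usable = site_components(gd, target_pop, control_pop)
    ref_t, alt_t = allele_counts(gd.population_dosages(target_pop))
    ref_c, alt_c = allele_counts(gd.population_dosages(control_pop))
    pi_t_site = _site_pi_array(ref_t, alt_t)
    pi_c_site = _site_pi_array(ref_c, alt_c)
    t_ok = ~np.isnan(pi_t_site)
    c_ok = ~np.isnan(pi_c_site)

    chrom_arr = gd.variants["chrom"].to_numpy()
    pos0 = gd.variants["pos"].to_numpy() - 1

    rows = []
    for w in windows:
        in_w = (chrom_arr == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        size = w.end - w.start
        n_fst = int((in_w & fst_usable).sum())
        n_t = int((in_w & t_ok).sum())
        n_c = int((in_w & c_ok).sum())
        sel = in_w & fst_usable
        denom = float((a[sel] + b[sel] + c[sel]).sum())
        theta = float(a[sel].sum()) / denom if denom != 0.0 else float("nan")
        pi_t = float(np.nansum(np.where(in_w, pi_t_site, 0.0))) / size
        pi_c = float(np.nansum(np.where(in_w, pi_c_site, 0.0))) / size
        usable = min(n_t, n_c, n_fst) >= min_snps and denom != 0.0
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps_fst": n_fst,
                "n_snps_pi": min(n_t, n_c),
                "fst": theta,
                "pi_target": pi_t,
                "pi_control": pi_c,
                "usable": usable,
            }
        )
    df = pd.DataFrame(rows)

    positive = df.loc[df["usable"] & (df["pi_target"] > 0), "pi_target"]
    floor = float(positive.min()) if len(positive) else 1e-12
    logger.info("window_stats: target-pi floor %.3g", floor)
    pi_t_floored = df["pi_target"].clip(lower=floor)
    df["pi_ratio"] = df["pi_control"] / pi_t_floored
    df["neg_log10_pi_target"] = -np.log10(pi_t_floored)
    df.loc[~df["usable"], ["fst", "pi_ratio", "neg_log10_pi_target"]] = np.nan
    df.attrs["pi_target_floor"] = floor
    return df


def _nearest_rank_threshold(values: np.ndarray, top_frac: float) -> float:
    """Value at the nearest-rank boundary of the top ``top_frac`` fraction."""
    v = np.sort(values)[::-1]
    k = max(1, math.ceil(top_frac * v.size))
    return float(v[k - 1])


def select_candidates(
    stats: pd.DataFrame, top_frac: float = 0.05, mode: str = "intersection"
) -> pd.DataFrame:
    """Windows in the top ``top_frac`` of both F_ST and pi-ratio rankings.

    Thresholds are nearest-rank empirical quantiles over usable windows;
    ties at a threshold are included. ``mode='union'`` selects windows
    passing either ranking instead. An empty intersection is a valid (logged)
    outcome.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    if mode not in {"intersection", "union"}:
        raise ValueError("mode must be 'intersection' or 'union'")
    usable = stats[stats["usable"]].copy()
    if len(usable) < 20:
        raise RadpopError(
            f"only {len(usable)} usable windows; need >= 20 for a meaningful quantile"
        )
    fst_thr = _nearest_rank_threshold(usable["fst"].to_numpy(), top_frac)
    ratio_thr = _nearest_rank_threshold(usable["pi_ratio"].to_numpy(), top_frac)
    top_fst = usable["fst"] >= fst_thr
    top_ratio = usable["pi_ratio"] >= ratio_thr
    chosen = (top_fst & top_ratio) if mode == "intersection" else (top_fst | top_ratio)
    out = usable[chosen].reset_index(drop=True)
    if out.empty:
        logger.info("select_candidates: empty intersection of top-%g sets", top_frac)
    out.attrs["fst_threshold"] = fst_thr
    out.attrs["pi_ratio_threshold"] = ratio_thr
    return out


def merge_regions(selected: pd.DataFrame, max_gap: int = 0) -> list[CandidateRegion]:
    """Merge selected windows that overlap or sit within ``max_gap`` bp."""
    regions: list[CandidateRegion] = []
    if selected.empty:
        return regions
    ordered = selected.sort_values(["chrom", "start"]).reset_index(drop=True)
    cur: CandidateRegion | None = None
    for row in ordered.itertuples():
        w = Window(chrom=row.chrom, start=int(row.start), end=int(row.end))
        if cur is not None and w.chrom == cur.chrom and w.start <= cur.end + max_gap:
            cur.end = max(cur.end, w.end)
            cur.windows.append(w)
            cur.max_fst = max(cur.max_fst, float(row.fst))
            cur.max_pi_ratio = max(cur.max_pi_ratio, float(row.pi_ratio))
        else:
            cur = CandidateRegion(
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                windows=[w],
                max_fst=float(row.fst),
                max_pi_ratio=float(row.pi_ratio),
            )
            regions.append(cur)
    return regions


def annotate_regions(
    regions: Iterable[CandidateRegion], genes: Sequence[GeneRecord]
) -> tuple[list[CandidateRegion], list[str]]:
    """Assign genes overlapping each region by >= 1 bp; return regions and the
    deduplicated gene list.

    Regions are 0-based half-open; gene records are 1-based inclusive, so a
    gene occupies ``[start-1, end)`` and overlaps a region iff
    ``start-1 < region.end and end > region.start``.
    """
    regions = list(regions)
    all_genes: dict[str, None] = {}
    for region in regions:
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == region.chrom
            and g.start - 1 < region.end
            and g.end > region.start
        ]
        region.gene_ids = hits
        for gid in hits:
            all_genes.setdefault(gid, None)
    return regions, list(all_genes)


def hypergeom_enrichment(
    selected_genes: Sequence[str],
    background_genes: Sequence[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term with Benjamini-Hochberg FDR.

    Columns: term, k (selected with term), K (background with term),
    n (selected total), N (background total), p, q, significant (q <= alpha).
    Terms with k = 0 are reported with p = 1.
    """
    background = set(background_genes)
    selected = set(selected_genes)
    strays = sorted(selected - background)
    if strays:
        raise RadpopError(f"selected genes not in background: {strays}")
    N, n = len(background), len(selected)
    rows = []
    for term, genes in term_map.items():
        term_set = set(genes) & background
        K = len(term_set)
        k = len(term_set & selected)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df
    df["q"] = _bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df.sort_values("p").reset_index(drop=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
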