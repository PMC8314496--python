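"""End-to-end orchestration: filter -> diversity -> F_ST -> LD -> structure ->
sweep scan -> annotation -> enrichment, with a reproducible output manifest.

``run_pipeline`` executes each stage in order, writing TSV/BED/newick/JSON
outputs under the configured directory. The manifest records the package
version, a hash of the canonical configuration, the seed, and a checksum per
output file, so identical configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .datamodel import GenotypeDataset, RadpopError
from . import diversity as _diversity
from . import filtering as _filtering
from . import fst as _fst
from . import io as _io
from . import ld as _ld
from . import structure as _structure
from . import sweep as _sweep

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    outdir: str
    gff: Optional[str] = None
    term_map: Optional[str] = None
    min_depth: int = 3
    maf_min: float = 0.05
    max_missing: float = 0.2
    window_size: int = 100_000
    window_step: int = 10_000
    top_frac: float = 0.05
    min_snps: int = 10
    selection_mode: str = "intersection"
    ld_max_dist: int = 500_000
    ld_bin_width: int = 5_000
    ld_max_pairs_per_bin: int = 100_000
    pca_components: int = 2
    pi_denominator: str = "callable_length"
    contrasts: list[tuple[str, str]] = field(default_factory=list)  # (control, target)
    seed: int = 0

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RadpopError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_term_map(path: str) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    out: dict[str, list[str]] = {}
    for term, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(term, []).append(gene)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return (and write) the output manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = f"radpop {__version__} config={cfg.config_hash()} seed={cfg.seed}"
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "files": {},
        "complete": False,
    }

    def emit(name: str) -> Path:
        path = outdir / name
        manifest["files"][name] = None
        return path

    def seal(name: str) -> None:
        path = outdir / name
        manifest["files"][name] = hashlib.sha256(path.read_bytes()).hexdigest()

    stage = "load"
    try:
        popmap = _io.read_popmap(cfg.popmap)
        gd = _io.read_vcf(cfg.vcf, popmap)
        pops = gd.population_codes()
        for control, target in cfg.contrasts:
            for p in (control, target):
                if p not in pops:
                    raise RadpopError(
                        f"contrast population {p!r} not in data; available: {pops}"
                    )

        stage = "filter"
        gd = _filtering.apply_depth_mask(gd, min_depth=cfg.min_depth)
        gd = _filtering.filter_variants(
            gd, maf_min=cfg.maf_min, max_missing=cfg.max_missing
        )
        if gd.n_variants == 0:
            raise RadpopError("no variants left after filtering")

        stage = "diversity"
        div = _diversity.diversity_table(gd, pi_denominator=cfg.pi_denominator)

        stage = "fst"
        mat = _fst.pairwise_fst_matrix(gd)
        div["avg_fst"] = [
            mat.loc[p, [q for q in pops if q != p]].mean() if len(pops) > 1 else float("nan")
            for p in div["population"]
        ]
        _io.write_table(div, emit("diversity.tsv"), header_comment=provenance)
        seal("diversity.tsv")
        mat_out = mat.reset_index(names="population")
        _io.write_table(mat_out, emit("fst_matrix.tsv"), header_comment=provenance)
        seal("fst_matrix.tsv")

        stage = "ld"
        ld_rows = []
        for pop in pops:
            try:
                curve = _ld.ld_decay_curve(
                    gd,
                    pop,
                    max_dist=cfg.ld_max_dist,
                    bin_width=cfg.ld_bin_width,
                    max_pairs_per_bin=cfg.ld_max_pairs_per_bin,
                    seed=cfg.seed,
                )
            except RadpopError as exc:
                logger.warning("LD curve skipped for %s: %s", pop, exc)
                continue
            b = curve.bins.copy()
            b.insert(0, "population", pop)
            ld_rows.append(b)
        if ld_rows:
            _io.write_table(
                pd.concat(ld_rows, ignore_index=True),
                emit("ld_decay.tsv"),
                header_comment=provenance,
            )
            seal("ld_decay.tsv")

        stage = "pca"
        k = min(cfg.pca_components, gd.n_samples - 1)
        pc = _structure.pca(gd, k=k)
        scores = pd.DataFrame(
            pc.coordinates, columns=[f"PC{i+1}" for i in range(pc.k)]
        )
        scores.insert(0, "population", [gd.populations[s] for s in gd.samples])
        scores.insert(0, "sample", gd.samples)
        _io.write_table(scores, emit("pca_scores.tsv"), header_comment=provenance)
        seal("pca_scores.tsv")
        varpct = pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(pc.k)],
                "variance_pct": pc.variance_pct,
            }
        )
        _io.write_table(varpct, emit("pca_variance.tsv"), header_comment=provenance)
        seal("pca_variance.tsv")

        stage = "nj"
        D = _structure.allele_sharing_distance(gd)
        njt = _structure.nj_tree(D, gd.samples)
        _io.write_newick(njt.as_newick(), emit("nj_tree.nwk"))
        seal("nj_tree.nwk")

        stage = "sweep"
        genes = _io.read_gff_genes(cfg.gff) if cfg.gff else []
        term_map = _read_term_map(cfg.term_map) if cfg.term_map else None
        windows = _sweep.make_windows(
            gd.effective_contig_lengths(), size=cfg.window_size, step=cfg.window_step
        )
        for control, target in cfg.contrasts:
            tag = f"{control}_vs_{target}"
            stats = _sweep.window_stats(
                gd, target, control, windows, min_snps=cfg.min_snps
            )
            selected = _sweep.select_candidates(
                stats, top_frac=cfg.top_frac, mode=cfg.selection_mode
            )
            stats["selected"] = False
            key = set(zip(selected["chrom"], selected["start"]))
            stats.loc[
                [(c, s) in key for c, s in zip(stats["chrom"], stats["start"])],
                "selected",
            ] = True
            _io.write_table(
                stats, emit(f"windows_{tag}.tsv"), header_comment=provenance
            )
            seal(f"windows_{tag}.tsv")

            regions = _sweep.merge_regions(selected)
            regions, gene_list = _sweep.annotate_regions(regions, genes)
            reg_df = pd.DataFrame(
                [
                    {
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "n_windows": len(r.windows),
                        "max_fst": r.max_fst,
                        "max_pi_ratio": r.max_pi_ratio,
                        "genes": ",".join(r.gene_ids),
                    }
                    for r in regions
                ],
                columns=[
                    "chrom",
                    "start",
                    "end",
                    "n_windows",
                    "max_fst",
                    "max_pi_ratio",
                    "genes",
                ],
            )
            _io.write_table(
                reg_df, emit(f"regions_{tag}.tsv"), header_comment=provenance
            )
            seal(f"regions_{tag}.tsv")
            with open(emit(f"regions_{tag}.bed"), "w") as fh:
                for r in regions:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            seal(f"regions_{tag}.bed")
            with open(emit(f"genes_{tag}.txt"), "w") as fh:
                fh.write("\n".join(gene_list) + ("\n" if gene_list else ""))
            seal(f"genes_{tag}.txt")

            if term_map is not None and genes:
                background = [g.gene_id for g in genes]
                enr = _sweep.hypergeom_enrichment(gene_list, background, term_map)
                _io.write_table(
                    enr, emit(f"enrichment_{tag}.tsv"), header_comment=provenance
                )
                seal(f"enrichment_{tag}.tsv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outdir)
        raise StageError(stage, exc) from exc

    manifest["complete"] = True
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
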