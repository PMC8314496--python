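"""Readers and writers: VCF, population map TSV, GFF3 genes, newick, TSV.

VCF parsing goes through cyvcf2. Only biallelic SNP records are kept;
multiallelic sites and indels are dropped at read time with a logged count.
Half-called genotypes (e.g. ``./1``) have no defensible dosage and become
missing.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    ConfigurationError,
    GeneRecord,
    GenotypeDataset,
    ParseError,
    PopulationMap,
)

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a two-column (sample TAB population) map without header."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#", skip_blank_lines=True
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read population map {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"population map {path} needs two tab-separated columns")
    return PopulationMap(
        samples=tuple(df.iloc[:, 0]), populations=tuple(df.iloc[:, 1])
    )


def read_vcf(path: str | os.PathLike, popmap: PopulationMap) -> GenotypeDataset:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    Multiallelic and non-SNP records are dropped (count logged). Phased and
    unphased genotypes are parsed identically; ``./.`` and half-calls map to
    :data:`MISSING`. Sample order follows the VCF header. FORMAT/DP, when
    present, populates the depth matrix (missing depth stored as 0).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise OSError(f"no such VCF: {path}")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    mapping = popmap.mapping
    strays = [s for s in samples if s not in mapping]
    if strays:
        raise ConfigurationError(
            f"VCF samples absent from population map: {strays}"
        )
    contig_lengths = {
        name: int(length)
        for name, length in zip(vcf.seqnames, vcf.seqlens or [])
        if length
    }

    has_dp = "DP" in {f for f in _format_ids(vcf)}
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    n_dropped = 0
    for lineno, variant in enumerate(vcf, start=1):
        if (
            len(variant.ALT) != 1
            or variant.REF not in _BASES
            or variant.ALT[0] not in _BASES
        ):
            n_dropped += 1
            continue
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1] if len(gt) > 2 else -1
            col[i] = a + b if a >= 0 and b >= 0 else MISSING
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        dosage_cols.append(col)
        if has_dp:
            dp = variant.format("DP")
            if dp is None:
                depth_cols.append(np.zeros(len(samples), dtype=np.int32))
            else:
                dp = dp.reshape(-1).astype(np.int64)
                dp[dp < 0] = 0  # cyvcf2 encodes missing DP as a large negative
                depth_cols.append(dp.astype(np.int32))

    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depths = None
    if has_dp and depth_cols:
        depths = np.column_stack(depth_cols)
    elif has_dp:
        depths = np.empty((len(samples), 0), dtype=np.int32)

    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy())) if len(variants) else np.array([], dtype=int)
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order] if dosages.size else dosages
    if depths is not None and depths.size:
        depths = depths[:, order]

    return GenotypeDataset(
        samples=samples,
        populations={s: mapping[s] for s in samples},
        variants=variants,
        dosages=dosages,
        depths=depths,
        contig_lengths=contig_lengths,
    )


def _format_ids(vcf: VCF) -> Iterable[str]:
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            yield line.split("ID=", 1)[1].split(",", 1)[0]


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gd: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write a dataset as uncompressed VCF 4.2 (GT, plus DP when present).

    Round-trips exactly through :func:`read_vcf`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in gd.effective_contig_lengths().items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gd.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gd.samples)
            + "\n"
        )
        fmt = "GT:DP" if gd.depths is not None else "GT"
        var = gd.variants
        for j in range(gd.n_variants):
            fields = [
                str(var.at[j, "chrom"]),
                str(var.at[j, "pos"]),
                ".",
                str(var.at[j, "ref"]),
                str(var.at[j, "alt"]),
                ".",
                ".",
                ".",
                fmt,
            ]
            for i in range(gd.n_samples):
                gt = _GT_STRINGS[int(gd.dosages[i, j])]
                if gd.depths is not None:
                    gt = f"{gt}:{int(gd.depths[i, j])}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, p in zip(popmap.samples, popmap.populations):
            fh.write(f"{s}\t{p}\n")


def read_gff_genes(path: str | os.PathLike) -> list[GeneRecord]:
    """Extract ``gene`` features from a GFF3 file (1-based inclusive coords)."""
    genes: list[GeneRecord] = []
    try:
        fh = open(path)
    except OSError as exc:
        raise OSError(f"cannot read GFF3 {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            gene_id = _gff_attribute(attrs, "ID") or _gff_attribute(attrs, "gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in {"+", "-", "."} else ".",
                )
            )
    return genes


def _gff_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item.split("=", 1)[1]
    return None


def write_gff_genes(genes: Sequence[GeneRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tradpop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def write_newick(newick: str, path: str | os.PathLike) -> None:
    """Write a newick string, guaranteeing the trailing semicolon."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")


def write_table(
    records: pd.DataFrame,
    path: str | os.PathLike,
    header_comment: str | None = None,
) -> None:
    """Write a DataFrame as TSV with a header row (optional ``#`` preamble)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", index=False)
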