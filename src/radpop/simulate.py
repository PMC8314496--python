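"""Synthetic genotype data with known truth.

The generator follows the Balding-Nichols model: each site has an ancestral
alt-allele frequency drawn Uniform(0.05, 0.95) and per-population
frequencies Beta(p(1-F)/F, (1-p)(1-F)/F), so the divergence parameter F
plays the role of an expected F_ST. Within a population, haplotypes are
either drawn site-wise i.i.d. from the population frequency (independent
sites; ``founder_haplotypes=None``) or as recombination mosaics over a
finite founder-haplotype pool, which induces LD that decays with distance at
a rate set by ``recomb_rate``. Inbreeding is modelled per genotype: with
probability f the second haplotype copies the first at a site, giving each
sample an expected inbreeding coefficient of f. Selective sweeps reset the
target population's alt frequency to ``1 - fixation_eps`` inside the swept
interval before haplotypes are drawn, jointly depressing target diversity
and elevating differentiation there.

Everything is driven by a single seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import MISSING, GeneRecord, GenotypeDataset, PopulationMap, RadpopError


@dataclass(frozen=True)
class Sweep:
    """One injected sweep: interval in 0-based half-open bp on a contig."""

    population: str
    contig: str
    start: int
    end: int
    fixation_eps: float = 0.02


@dataclass
class SimConfig:
    populations: list[tuple[str, int]]
    contigs: list[tuple[str, int]]
    n_sites: int
    fst_param: float
    inbreeding: dict[str, float]
    founder_haplotypes: Optional[int]
    recomb_rate: float
    sweeps: list[Sweep]
    missing_rate: float
    depth_mean: Optional[float]
    depth_dispersion: Optional[float]
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.fst_param < 1:
            raise RadpopError("fst_param must be in [0, 1)")
        if any(not 0 <= f < 1 for f in self.inbreeding.values()):
            raise RadpopError("inbreeding coefficients must be in [0, 1)")
        if self.founder_haplotypes is not None and self.founder_haplotypes < 1:
            raise RadpopError("founder_haplotypes must be >= 1 (or None)")
        if not 0 <= self.missing_rate < 1:
            raise RadpopError("missing_rate must be in [0, 1)")
        lengths = dict(self.contigs)
        for sw in self.sweeps:
            if sw.contig not in lengths:
                raise RadpopError(f"sweep contig {sw.contig!r} not in contigs")
            if not (0 <= sw.start < sw.end <= lengths[sw.contig]):
                raise RadpopError(f"sweep interval outside contig {sw.contig}")
            if sw.population not in dict(self.populations):
                raise RadpopError(f"sweep population {sw.population!r} unknown")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [list(x) for x in self.populations]
        d["contigs"] = [list(x) for x in self.contigs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["populations"] = [tuple(x) for x in d["populations"]]
        d["contigs"] = [tuple(x) for x in d["contigs"]]
        d["sweeps"] = [Sweep(**s) if isinstance(s, dict) else s for s in d["sweeps"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Generator parameters plus the realized frequencies behind a dataset."""

    config: SimConfig
    positions: dict[str, np.ndarray]  # contig -> 1-based positions
    ancestral_freq: dict[str, np.ndarray]  # contig -> per-site p
    population_freq: dict[str, dict[str, np.ndarray]]  # contig -> pop -> p
    sweeps: list[Sweep]

    def to_json(self, path) -> None:
        payload = {
            "config": _jsonable_config(self.config),
            "positions": {c: v.tolist() for c, v in self.positions.items()},
            "ancestral_freq": {c: v.tolist() for c, v in self.ancestral_freq.items()},
            "population_freq": {
                c: {p: v.tolist() for p, v in pops.items()}
                for c, pops in self.population_freq.items()
            },
            "sweeps": [asdict(s) for s in self.sweeps],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _jsonable_config(cfg: SimConfig) -> dict:
    d = cfg.to_dict()
    d["sweeps"] = [asdict(s) for s in cfg.sweeps]
    return d


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GenotypeDataset, PopulationMap, list[GeneRecord], SimTruth]:
    """Generate a dataset, its population map, a toy gene annotation and truth.

    The toy annotation places three genes inside every injected sweep and
    twenty decoys per contig outside them, so annotation and enrichment can
    be exercised end to end against known truth.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.populations
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    for code, n in pops:
        for i in range(1, n + 1):
            s = f"{code}_{i:02d}"
            samples.append(s)
            pop_of[s] = code

    contig_lengths = dict(cfg.contigs)
    positions: dict[str, np.ndarray] = {}
    anc: dict[str, np.ndarray] = {}
    pop_freq: dict[str, dict[str, np.ndarray]] = {}
    dosage_blocks: list[np.ndarray] = []
    var_frames: list[pd.DataFrame] = []

    for contig, length in cfg.contigs:
        if cfg.n_sites > length:
            raise RadpopError(f"more sites than bp on contig {contig}")
        pos = np.sort(rng.choice(length, size=cfg.n_sites, replace=False)) + 1
        positions[contig] = pos
        p_anc = rng.uniform(0.05, 0.95, size=cfg.n_sites)
        anc[contig] = p_anc
        pop_freq[contig] = {}

        F = cfg.fst_param
        contig_dosages = np.empty((len(samples), cfg.n_sites), dtype=np.int8)
        row = 0
        for code, n in pops:
            if F > 0:
                a = p_anc * (1 - F) / F
                b = (1 - p_anc) * (1 - F) / F
                p_pop = rng.beta(a, b)
            else:
                p_pop = p_anc.copy()
            for sw in cfg.sweeps:
                if sw.population == code and sw.contig == contig:
                    in_sweep = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
                    p_pop[in_sweep] = 1.0 - sw.fixation_eps
            pop_freq[contig][code] = p_pop

            h1, h2 = _draw_haplotypes(rng, cfg, n, pos, p_pop)
            f = cfg.inbreeding.get(code, 0.0)
            if f > 0:
                copy = rng.random((n, cfg.n_sites)) < f
                h2 = np.where(copy, h1, h2)
            contig_dosages[row : row + n] = (h1 + h2).astype(np.int8)
            row += n
        dosage_blocks.append(contig_dosages)
        var_frames.append(
            pd.DataFrame(
                {
                    "chrom": contig,
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                }
            )
        )

    dosages = np.hstack(dosage_blocks)
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = MISSING
    depths = None
    if cfg.depth_mean is not None and cfg.depth_dispersion is not None:
        k, m = cfg.depth_dispersion, cfg.depth_mean
        depths = rng.negative_binomial(k, k / (k + m), size=dosages.shape).astype(
            np.int32
        )

    gd = GenotypeDataset(
        samples=samples,
        populations=pop_of,
        variants=pd.concat(var_frames, ignore_index=True),
        dosages=dosages,
        depths=depths,
        contig_lengths=contig_lengths,
    )
    popmap = PopulationMap(
        samples=tuple(samples), populations=tuple(pop_of[s] for s in samples)
    )
    genes = _toy_genes(cfg)
    truth = SimTruth(
        config=cfg,
        positions=positions,
        ancestral_freq=anc,
        population_freq=pop_freq,
        sweeps=list(cfg.sweeps),
    )
    return gd, popmap, genes, truth


def _draw_haplotypes(
    rng: np.random.Generator,
    cfg: SimConfig,
    n: int,
    pos: np.ndarray,
    p_pop: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two haplotype matrices (n x sites) for one population on one contig."""
    S = pos.size
    if cfg.founder_haplotypes is None:
        h1 = (rng.random((n, S)) < p_pop).astype(np.int8)
        h2 = (rng.random((n, S)) < p_pop).astype(np.int8)
        return h1, h2
    H = cfg.founder_haplotypes
    founders = (rng.random((H, S)) < p_pop).astype(np.int8)
    gaps = np.diff(pos).astype(float)
    # Ancestral recombination accumulates over roughly H/2 generations of a
    # pool of H haplotypes, so the effective per-bp switch rate scales with
    # the pool: larger (more diverse) pools have shorter haplotype segments
    # and faster LD decay, as in real populations (r2 ~ 1/(1 + 4*N*c*d)).
    p_switch = 1.0 - np.exp(-cfg.recomb_rate * (H / 2.0) * gaps)
    haps = []
    for _ in range(2):
        switch = np.empty((n, S), dtype=bool)
        switch[:, 0] = True
        switch[:, 1:] = rng.random((n, S - 1)) < p_switch
        choice = rng.integers(0, H, size=(n, S))
        cols = np.where(switch, np.arange(S), 0)
        filled = np.maximum.accumulate(cols, axis=1)
        founder_idx = np.take_along_axis(choice, filled, axis=1)
        haps.append(founders[founder_idx, np.arange(S)])
    return haps[0], haps[1]


def _toy_genes(cfg: SimConfig) -> list[GeneRecord]:
    """3 genes tiled inside each sweep; 20 decoys per contig outside sweeps."""
    genes: list[GeneRecord] = []
    for si, sw in enumerate(cfg.sweeps):
        span = (sw.end - sw.start) // 3
        for gi in range(3):
            start0 = sw.start + gi * span
            genes.append(
                GeneRecord(
                    gene_id=f"sweep{si}_gene{gi}",
                    chrom=sw.contig,
                    start=start0 + 1,
                    end=min(start0 + span, sw.end),
                    strand="+",
                )
            )
    for contig, length in cfg.contigs:
        sweep_ivs = [
            (s.start, s.end) for s in cfg.sweeps if s.contig == contig
        ]
        placed = 0
        step = length // 25
        pos0 = 0
        gene_len = max(1000, step // 4)
        while placed < 20 and pos0 + gene_len <= length:
            iv = (pos0, pos0 + gene_len)
            if not any(iv[0] < e and iv[1] > s for s, e in sweep_ivs):
                genes.append(
                    GeneRecord(
                        gene_id=f"{contig}_bg{placed}",
                        chrom=contig,
                        start=iv[0] + 1,
                        end=iv[1],
                        strand="-",
                    )
                )
                placed += 1
            pos0 += step
    return genes


#: Breed codes and sample sizes of the eight-population study cohort.
STANDARD_POPULATIONS: list[tuple[str, int]] = [
    ("SB", 10),   # Sichuan White
    ("XXL", 10),  # New Zealand
    ("BLS", 8),   # Belgian
    ("JYS", 10),  # Jiuyishan
    ("WZ", 10),   # Wanzai
    ("HT", 4),    # Yunnan Colourful
    ("MH", 9),    # Minxinan Black
    ("FH", 10),   # Fujian Yellow
]

#: Per-breed inbreeding levels, matching the magnitudes reported for the cohort.
STANDARD_INBREEDING: dict[str, float] = {
    "SB": 0.24,
    "XXL": 0.33,
    "BLS": 0.23,
    "JYS": 0.22,
    "WZ": 0.24,
    "HT": 0.08,
    "MH": 0.20,
    "FH": 0.27,
}

STANDARD_SEED = 20210726


def standard_scenario(seed: int = STANDARD_SEED) -> SimConfig:
    """The default study-shaped scenario: 8 populations, 71 samples.

    Two 2-Mb contigs with 5,000 sites each, divergence F = 0.12, founder
    mosaics (30 founders, base recombination 1e-6/bp, i.e. haplotype
    segments of a few tens of kb) for distance-decaying LD, per-breed
    inbreeding, 5% missingness, negative-binomial read depths (mean 20,
    dispersion 5), and one 200-kb sweep in the WZ population on contig 1.
    """
    return SimConfig(
        populations=list(STANDARD_POPULATIONS),
        contigs=[("chr1", 2_000_000), ("chr2", 2_000_000)],
        n_sites=5_000,
        fst_param=0.12,
        inbreeding=dict(STANDARD_INBREEDING),
        founder_haplotypes=30,
        recomb_rate=1e-6,
        sweeps=[Sweep(population="WZ", contig="chr1", start=900_000, end=1_100_000)],
        missing_rate=0.05,
        depth_mean=20.0,
        depth_dispersion=5.0,
        seed=seed,
    )


#: The micro-fixture genotype table (rows = samples, columns = sites at
#: positions 1000..6000 on a 10-kb contig). Frozen; every statistic on it is
#: hand-computable and the worked values live in docs/micro_fixture.md.
_MICRO_DOSAGES = np.array(
    [
        # s1 s2 s3 s4 s5 s6
        [0, 0, 0, 0, 0, 1],  # P1_1
        [0, 1, 0, 1, 0, 1],  # P1_2
        [0, 2, 1, 1, 0, 1],  # P1_3
        [0, 1, 1, 2, 0, 1],  # P1_4
        [2, 0, 2, 1, 0, 0],  # P2_1
        [2, 1, 2, 1, 0, 2],  # P2_2
        [2, 2, 1, 2, 0, 0],  # P2_3
        [2, 1, 1, 2, 1, 2],  # P2_4
    ],
    dtype=np.int8,
)


def micro_fixture() -> GenotypeDataset:
    """Deterministic 2-population, 8-sample, 6-site dataset.

    Site 1 is a fixed difference between P1 and P2; site 2 has identical
    genotype configurations in both populations; site 5 is monomorphic in P1
    and nearly so in P2; site 6 is fully heterozygous in P1.
    """
    samples = [f"P1_{i}" for i in range(1, 5)] + [f"P2_{i}" for i in range(1, 5)]
    populations = {s: s.split("_")[0] for s in samples}
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "pos": [1000, 2000, 3000, 4000, 5000, 6000],
            "ref": ["A"] * 6,
            "alt": ["G"] * 6,
        }
    )
    return GenotypeDataset(
        samples=samples,
        populations=populations,
        variants=variants,
        dosages=_MICRO_DOSAGES.copy(),
        contig_lengths={"chr1": 10_000},
    )
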