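import numpy as np
import pandas as pd
import pytest

from radpop import simulate
from radpop.datamodel import GenotypeDataset


@pytest.fixture
def micro():
    """The frozen hand-computable 2x4x6 dataset."""
    return simulate.micro_fixture()


def make_dataset(dosages, positions=None, chrom="chr1", pops=None, contig_length=None,
                 depths=None):
    """Tiny dataset builder: dosages is (samples x sites)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    samples = [f"S{i+1}" for i in range(n)]
    if pops is None:
        pops = {s: "P1" for s in samples}
    else:
        pops = {s: p for s, p in zip(samples, pops)}
    variants = pd.DataFrame(
        {"chrom": [chrom] * m, "pos": positions, "ref": ["A"] * m, "alt": ["G"] * m}
    )
    lengths = {chrom: contig_length} if contig_length else {}
    return GenotypeDataset(
        samples=samples,
        populations=pops,
        variants=variants,
        dosages=dosages,
        depths=depths,
        contig_lengths=lengths,
    )


def independent_sites_config(pop_sizes, n_sites, fst_param, seed, inbreeding=None,
                             contig_length=None, missing_rate=0.0):
    """Balding-Nichols config with i.i.d. sites (no founder pool, no LD)."""
    pops = [(f"P{i+1}", n) for i, n in enumerate(pop_sizes)]
    length = contig_length or max(n_sites * 100, 1_000_000)
    return simulate.SimConfig(
        populations=pops,
        contigs=[("chr1", length)],
        n_sites=n_sites,
        fst_param=fst_param,
        inbreeding=inbreeding or {},
        founder_haplotypes=None,
        recomb_rate=0.0,
        sweeps=[],
        missing_rate=missing_rate,
        depth_mean=None,
        depth_dispersion=None,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bn_two_pop():
    """Two populations, F = 0.15, 30 diploids each, 20,000 independent sites."""
    cfg = independent_sites_config([30, 30], 20_000, 0.15, seed=1)
    gd, _, _, _ = simulate.simulate_dataset(cfg)
    return gd


@pytest.fixture(scope="session")
def standard_run():
    """One realisation of the standard 8-population scenario, filtered."""
    from radpop import filtering

    cfg = simulate.standard_scenario()
    gd, popmap, genes, truth = simulate.simulate_dataset(cfg)
    gd = filtering.apply_depth_mask(gd)
    gd = filtering.filter_variants(gd)
    return gd, popmap, genes, truth
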