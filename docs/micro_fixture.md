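# The micro-fixture: worked values

`radpop.simulate.micro_fixture()` returns a frozen dataset of two
populations (P1, P2) with four diploid samples each and six biallelic SNPs
on one 10-kb contig (positions 1000, 2000, ..., 6000). The genotype table
(alt-allele dosages; rows = samples, columns = sites) is:

| sample | s1 | s2 | s3 | s4 | s5 | s6 |
|--------|----|----|----|----|----|----|
| P1_1   | 0  | 0  | 0  | 0  | 0  | 1  |
| P1_2   | 0  | 1  | 0  | 1  | 0  | 1  |
| P1_3   | 0  | 2  | 1  | 1  | 0  | 1  |
| P1_4   | 0  | 1  | 1  | 2  | 0  | 1  |
| P2_1   | 2  | 0  | 2  | 1  | 0  | 0  |
| P2_2   | 2  | 1  | 2  | 1  | 0  | 2  |
| P2_3   | 2  | 2  | 1  | 2  | 0  | 0  |
| P2_4   | 2  | 1  | 1  | 2  | 1  | 2  |

The table is frozen by a SHA-256 checksum test
(`tests/test_simulate.py`). All statistics below are computed longhand
from the table and asserted exactly in the test suite.

## Per-site tallies (n = 8 alleles per population, no missing data)

P1: alt counts per site (0, 4, 2, 4, 0, 4); heterozygote counts
(0, 2, 2, 2, 0, 4). P2: alt counts (8, 4, 6, 6, 1, 4); heterozygote
counts (0, 2, 2, 2, 1, 0).

## Segregating sites

P1 segregates at s2, s3, s4, s6 → **N = 4**. P2 segregates at s2, s3,
s4, s5, s6 → **N = 5**.

## Nucleotide diversity (per-site π = ref·alt / C(8,2), C(8,2) = 28)

- P1: 0 + 16/28 + 12/28 + 16/28 + 0 + 16/28 = 15/7;
  over the 10-kb contig **π(P1) = (15/7)/10000 ≈ 2.1429e-4**.
- P2: 0 + 16/28 + 12/28 + 12/28 + 7/28 + 16/28 = 9/4;
  **π(P2) = 2.25e-4**.

## Heterozygosity (all six sites have ≥ 2 genotypes and are included)

Ho is the heterozygote fraction per site; He = 2p̂q̂·(8/7).

- P1: Ho = (0 + ½ + ½ + ½ + 0 + 1)/6 = **5/12 ≈ 0.41667**;
  He = (0 + 4/7 + 3/7 + 4/7 + 0 + 4/7)/6 = **5/14 ≈ 0.35714**.
- P2: Ho = (0 + ½ + ½ + ½ + ¼ + 0)/6 = **7/24 ≈ 0.29167**;
  He = (0 + 4/7 + 3/7 + 3/7 + ¼ + 4/7)/6 = **3/8 = 0.375**.

## Per-sample inbreeding F = 1 − O/E

E sums He over the population's polymorphic sites.

- P1 (sites s2, s3, s4, s6; E = 15/7): O = 1, 3, 3, 3 for P1_1..P1_4
  → F = 8/15, −2/5, −2/5, −2/5; mean **F_IS(P1) = −1/6**.
- P2 (sites s2..s6; E = 9/4): O = 1, 2, 1, 3 → F = 5/9, 1/9, 5/9,
  −1/3; mean **F_IS(P2) = 2/9**.

## Weir–Cockerham θ between P1 and P2

Per-site components (a, b, c) with n₁ = n₂ = 4 (so n̄ = n_c = 4):

| site | a | b | c | a+b+c |
|------|---------|---------|------|-------|
| s1   | 1/2     | 0       | 0    | 1/2   |
| s2   | −1/24   | 1/24    | 1/4  | 1/4   |
| s3   | 5/48    | −1/24   | 1/4  | 5/16  |
| s4   | 0       | 0       | 1/4  | 1/4   |
| s5   | 0       | 0       | 1/16 | 1/16  |
| s6   | −1/24   | 1/24    | 1/4  | 1/4   |

Σa = 25/48, Σ(a+b+c) = 13/8, so the ratio-of-sums estimate is
**θ = 25/78 ≈ 0.32051**. Site s1 alone (a fixed difference) gives
θ_site = 1; sites s2 and s6 (identical genotype configurations in both
populations) give a < 0.
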