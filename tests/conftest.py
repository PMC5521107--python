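"""Shared fixtures: small simulated datasets and a planted-defect matrix."""

import numpy as np
import pytest

from ldne import (AnimalRecord, GenotypeMatrix, SimConfig, SnpRecord,
                  simulate_population)


@pytest.fixture(scope="session")
def tiny_population():
    """Small drift-equilibrated population (2 chromosomes, fast)."""
    cfg = SimConfig(ne_trajectory=[(50, 50)], n_chromosomes=2,
                    chromosome_length_cm=50.0, n_snps_per_chromosome=300,
                    burnin_generations=200, sample_size=60, rng_seed=7)
    haps, matrix, truth = simulate_population(cfg)
    return haps, matrix, truth


def _hwe_genotypes(rng, n_animals, freqs):
    """Dosages drawn per locus as Binomial(2, p): exact HWE sampling."""
    return rng.binomial(2, freqs[None, :], size=(n_animals, freqs.size)).astype(float)


def build_planted_qc_matrix(rng_seed: int = 0):
    """A clean HWE dataset with exactly six planted defects.

    Planted: one monomorphic SNP, one all-missing SNP, one SNP violating
    Hardy-Weinberg (every call heterozygous), one low-call-rate animal,
    one duplicated animal, and one mis-sexed male (female-like X
    heterozygosity). Returns (matrix, expected) where ``expected`` names
    each planted item.
    """
    rng = np.random.default_rng(rng_seed)
    n_animals, n_auto, n_x = 60, 55, 40
    freqs = rng.uniform(0.2, 0.8, n_auto)
    dos = _hwe_genotypes(rng, n_animals, freqs)

    snps = [SnpRecord(snp_id=f"auto_{j:03d}", chromosome=str(j % 5 + 1),
                      position_bp=1000 * (j + 1)) for j in range(n_auto)]
    # planted SNPs on chromosome 1
    dos = np.hstack([dos, np.zeros((n_animals, 1)),          # monomorphic
                     np.full((n_animals, 1), np.nan),        # all missing
                     np.ones((n_animals, 1))])               # all het: HWE fails
    snps += [SnpRecord("planted_mono", "1", 900001),
             SnpRecord("planted_missing", "1", 900002),
             SnpRecord("planted_hwe", "1", 900003)]

    # X chromosome, sex-consistent
    sexes = ["male" if i % 2 else "female" for i in range(n_animals)]
    px = rng.uniform(0.3, 0.7, n_x)
    xcols = np.empty((n_animals, n_x))
    for i, sex in enumerate(sexes):
        if sex == "female":
            xcols[i] = rng.binomial(2, px)
        else:
            xcols[i] = 2.0 * (rng.random(n_x) < px)
    # mis-sexed: animal 10 is recorded male but carries female-like X
    xcols[10] = rng.binomial(2, px)
    if (xcols[10] == 1).mean() <= 0.03:          # ensure heterozygous calls
        xcols[10][:10] = 1.0
    sexes[10] = "male"
    dos = np.hstack([dos, xcols])
    snps += [SnpRecord(f"x_{j:03d}", "X", 1000 * (j + 1)) for j in range(n_x)]

    # low-call-rate animal: 90% of its calls missing
    miss = rng.random(dos.shape[1]) < 0.9
    dos[20, miss] = np.nan

    animals = [AnimalRecord(animal_id=f"an_{i:03d}", recorded_sex=sexes[i],
                            breed_composition={"Rom": 1.0})
               for i in range(n_animals)]
    # duplicate of animal 30 appended
    animals.append(AnimalRecord(animal_id="an_dup", recorded_sex=sexes[30],
                                breed_composition={"Rom": 1.0}))
    dos = np.vstack([dos, dos[30][None, :]])

    expected = {"mono": "planted_mono", "missing": "planted_missing",
                "hwe": "planted_hwe", "low_call": "an_020",
                "dup_pair": ("an_030", "an_dup"), "missexed": "an_010",
                "x_snps": {f"x_{j:03d}" for j in range(n_x)}}
    return GenotypeMatrix(animals, snps, dos), expected


@pytest.fixture(scope="session")
def planted_qc():
    return build_planted_qc_matrix()
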