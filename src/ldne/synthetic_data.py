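"""Synthetic data with known truth for every pipeline stage.

A discrete-generation Wright-Fisher diploid simulator with recombination
generates multi-chromosome genotypes whose LD reflects a known N_e
trajectory; a map simulator produces variable-rate genetic maps with
sparse linkage-map anchors; a corruption step adds missingness, duplicate
samples and X-chromosome genotypes for sex inference. Everything is
emitted in the same text formats the pipeline reads, alongside the truth.

The simulator models drift and recombination only: random mating with
replacement (selfing allowed), crossovers Poisson on the genetic map with
no interference (Haldane), no mutation, no selection, non-overlapping
generations. Initial haplotypes are drawn independently per locus at
configured allele frequencies, so LD is built purely by drift during
burn-in. When the genotyped cohort is larger than the breeding population
(as in livestock), the sample is drawn as offspring of the final
generation rather than without replacement from it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_data import (AnimalRecord, GenotypeMatrix, SnpRecord,
                            write_ped_map)
from .genetic_map import DenseGeneticMap, LinkageMap

__all__ = [
    "MapSimConfig", "SimConfig", "SimTruth", "simulate_map",
    "simulate_population", "corrupt", "end_to_end_fixture",
]


# ---------------------------------------------------------------------------
# genetic-map simulation
# ---------------------------------------------------------------------------

@dataclass
class MapSimConfig:
    """Piecewise-constant recombination-rate profile for one chromosome."""

    rate_regimes: list[tuple[float, float]]   # (length_mb, rate_cm_per_mb)
    n_chip_snps: int = 500
    anchors_per_cm: float = 2.0
    anchor_noise_cm: float = 0.0
    chromosome: str = "1"

    def __post_init__(self):
        if any(r <= 0 for _, r in self.rate_regimes):
            raise ValueError("rates must be positive")
        if any(l <= 0 for l, _ in self.rate_regimes):
            raise ValueError("regime lengths must be positive")


def _true_cm(bp: np.ndarray, regimes) -> np.ndarray:
    """Piecewise-linear cM(bp) from (length_mb, rate) regimes."""
    edges_mb = np.concatenate([[0.0], np.cumsum([l for l, _ in regimes])])
    rates = np.array([r for _, r in regimes])
    cum_cm = np.concatenate([[0.0], np.cumsum([l * r for l, r in regimes])])
    mb = np.asarray(bp, dtype=float) / 1e6
    seg = np.clip(np.searchsorted(edges_mb, mb, side="right") - 1,
                  0, len(rates) - 1)
    return cum_cm[seg] + (mb - edges_mb[seg]) * rates[seg]


def _inverse_cm(cm: np.ndarray, regimes) -> np.ndarray:
    """bp positions at given cumulative cM (inverse of _true_cm)."""
    edges_mb = np.concatenate([[0.0], np.cumsum([l for l, _ in regimes])])
    rates = np.array([r for _, r in regimes])
    cum_cm = np.concatenate([[0.0], np.cumsum([l * r for l, r in regimes])])
    cm = np.asarray(cm, dtype=float)
    seg = np.clip(np.searchsorted(cum_cm, cm, side="right") - 1,
                  0, len(rates) - 1)
    mb = edges_mb[seg] + (cm - cum_cm[seg]) / rates[seg]
    return np.round(mb * 1e6).astype(np.int64)


def simulate_map(config: MapSimConfig, rng_seed: int = 0
                 ) -> tuple[DenseGeneticMap, LinkageMap]:
    """Simulate a chromosome map: a true dense map for uniformly placed
    chip SNPs and sparse anchors at the configured density in cM."""
    rng = np.random.default_rng(rng_seed)
    total_mb = sum(l for l, _ in config.rate_regimes)
    total_cm = sum(l * r for l, r in config.rate_regimes)
    chrom = str(config.chromosome)

    bp = np.sort(rng.choice(int(total_mb * 1e6), size=config.n_chip_snps,
                            replace=False))
    chip = pd.DataFrame({
        "snp_id": [f"chip_{chrom}_{i:05d}" for i in range(bp.size)],
        "chromosome": chrom, "position_bp": bp,
        "genetic_cm": _true_cm(bp, config.rate_regimes)})
    dense = DenseGeneticMap("truth", chip)

    n_anchor = max(2, int(round(total_cm * config.anchors_per_cm)))
    anchor_cm = np.linspace(0.0, total_cm, n_anchor)
    anchor_bp = _inverse_cm(anchor_cm, config.rate_regimes)
    if config.anchor_noise_cm > 0:
        anchor_cm = anchor_cm + rng.normal(0, config.anchor_noise_cm,
                                           n_anchor)
        anchor_cm = np.sort(anchor_cm)
    anchors = LinkageMap(pd.DataFrame({
        "snp_id": [f"anchor_{chrom}_{i:04d}" for i in range(n_anchor)],
        "chromosome": chrom, "position_bp": anchor_bp,
        "genetic_cm": anchor_cm}))
    return dense, anchors


# ---------------------------------------------------------------------------
# Wright-Fisher simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Wright-Fisher study conditions.

    ``ne_trajectory`` is piecewise constant, most recent epoch first:
    ``[(g1, N1), (g2, N2), ...]`` runs the last g1 generations at N1,
    the g2 before those at N2, and so on; burn-in happens at the oldest
    epoch's size.
    """

    ne_trajectory: list[tuple[int, int]] = field(
        default_factory=lambda: [(100, 100)])
    n_chromosomes: int = 3
    chromosome_length_cm: float = 100.0
    n_snps_per_chromosome: int = 2000
    init_maf_low: float = 0.05
    init_maf_high: float = 0.5
    burnin_generations: int = 400
    sample_size: int = 200
    rng_seed: int = 0

    def __post_init__(self):
        if any(n < 2 for _, n in self.ne_trajectory):
            raise ValueError("population size must be at least 2")
        max_n = max(n for _, n in self.ne_trajectory)
        if self.burnin_generations < 4 * max_n:
            warnings.warn(f"burn-in {self.burnin_generations} below the "
                          f"recommended 4 x N = {4 * max_n}; LD may not "
                          "have reached drift equilibrium")


@dataclass
class SimTruth:
    ne_trajectory: list[tuple[int, int]]
    maps_cm: list[np.ndarray]            # per chromosome, true cM per SNP
    allele_frequencies: np.ndarray       # realised, over all SNPs
    sample_parents: np.ndarray           # (sample, 2) indices into final gen
    rng_seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"ne_trajectory": [list(e) for e in self.ne_trajectory],
                       "rng_seed": self.rng_seed,
                       "n_chromosomes": len(self.maps_cm)}, fh, indent=2)


def _gamete(haps: np.ndarray, parent: int, cm_pos: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a diploid parent (Haldane crossovers)."""
    h0, h1 = haps[2 * parent], haps[2 * parent + 1]
    length_mor = (cm_pos[-1] - cm_pos[0]) / 100.0
    k = rng.poisson(length_mor)
    start = int(rng.integers(2))
    if k == 0:
        return (h1 if start else h0).copy()
    xo = np.sort(rng.uniform(cm_pos[0], cm_pos[-1], k))
    seg = np.searchsorted(xo, cm_pos, side="right")
    pick = (seg + start) & 1
    return np.where(pick == 1, h1, h0)


def _offspring(haps: np.ndarray, cm_pos: np.ndarray, parents: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    n_off = parents.shape[0]
    out = np.empty((2 * n_off, haps.shape[1]), dtype=haps.dtype)
    for i in range(n_off):
        out[2 * i] = _gamete(haps, parents[i, 0], cm_pos, rng)
        out[2 * i + 1] = _gamete(haps, parents[i, 1], cm_pos, rng)
    return out


def simulate_population(config: SimConfig
                        ) -> tuple[list[np.ndarray], GenotypeMatrix, SimTruth]:
    """Forward Wright-Fisher simulation under the configured N_e history.

    Returns the sampled haplotypes (one (2 x sample, L) array per
    chromosome), the genotype matrix, and the truth object. Monomorphic
    SNPs are retained (removing them is QC's job).
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.n_snps_per_chromosome
    cm_pos = [np.linspace(0.0, config.chromosome_length_cm, L)
              for _ in range(config.n_chromosomes)]

    epochs = list(reversed(config.ne_trajectory))   # oldest first
    n0 = epochs[0][1]
    if config.sample_size > config.ne_trajectory[0][1]:
        # genotyped cohort larger than the breeding population: sampled
        # individuals are offspring of the final generation
        sample_as_offspring = True
    else:
        sample_as_offspring = False

    # initial standing variation, linkage equilibrium
    freqs = rng.uniform(config.init_maf_low, config.init_maf_high,
                        size=(config.n_chromosomes, L))
    haps = [(rng.random((2 * n0, L)) < freqs[c]).astype(np.uint8)
            for c in range(config.n_chromosomes)]

    schedule = [(config.burnin_generations, n0)] + epochs
    n_cur = n0
    for gens, n_next in schedule:
        for g in range(gens):
            n_new = n_next
            parents = rng.integers(0, n_cur, size=(n_new, 2))
            haps = [_offspring(h, cm, parents, rng)
                    for h, cm in zip(haps, cm_pos)]
            n_cur = n_new

    if sample_as_offspring:
        parents = rng.integers(0, n_cur, size=(config.sample_size, 2))
        sample_haps = [_offspring(h, cm, parents, rng)
                       for h, cm in zip(haps, cm_pos)]
    else:
        chosen = rng.choice(n_cur, size=config.sample_size, replace=False)
        parents = np.stack([chosen, chosen], axis=1)   # self-identity record
        idx = np.stack([2 * chosen, 2 * chosen + 1], axis=1).ravel()
        sample_haps = [h[idx] for h in haps]

    snps, dosage_blocks = [], []
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        bp = np.round(cm_pos[c] * 1e6).astype(np.int64)  # 1 cM/Mb baseline
        for i in range(L):
            snps.append(SnpRecord(snp_id=f"snp_{chrom}_{i:05d}",
                                  chromosome=chrom, position_bp=int(bp[i])))
        h = sample_haps[c]
        dosage_blocks.append((h[0::2] + h[1::2]).astype(float))
    animals = [AnimalRecord(animal_id=f"sim_{i:04d}",
                            recorded_sex="male" if i % 2 else "female",
                            breed_composition={"Rom": 1.0})
               for i in range(config.sample_size)]
    matrix = GenotypeMatrix(animals, snps, np.hstack(dosage_blocks))

    truth = SimTruth(ne_trajectory=config.ne_trajectory, maps_cm=cm_pos,
                     allele_frequencies=np.hstack(
                         [b.mean(axis=0) / 2 for b in dosage_blocks]),
                     sample_parents=parents, rng_seed=config.rng_seed)
    return sample_haps, matrix, truth


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def corrupt(matrix: GenotypeMatrix, missing_rate: float = 0.0,
            duplicate_count: int = 0, x_chromosome: bool = False,
            n_x_snps: int = 200, x_error_rate: float = 0.005,
            rng_seed: int = 0) -> tuple[GenotypeMatrix, dict]:
    """Degrade a clean matrix the way real chip data is degraded.

    Appends exact duplicate animals, optionally adds an X chromosome with
    sex-consistent heterozygosity (females in HWE, males homozygous apart
    from an error rate), then applies missing-completely-at-random calls
    to everything (so duplicates differ in their missing patterns).
    Returns the corrupted matrix and a manifest of what was planted.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    animals = list(matrix.animals)
    dosages = matrix.dosages.copy()
    manifest: dict = {"duplicates": [], "x_snps": 0,
                      "missing_rate": missing_rate}

    if duplicate_count:
        src = rng.choice(matrix.n_animals, size=duplicate_count,
                         replace=False)
        for i in src:
            orig = matrix.animals[i]
            dup = AnimalRecord(animal_id=f"dup_{orig.animal_id}",
                               recorded_sex=orig.recorded_sex,
                               flock_id=orig.flock_id,
                               breed_composition=dict(orig.breed_composition))
            animals.append(dup)
            dosages = np.vstack([dosages, matrix.dosages[i][None, :]])
            manifest["duplicates"].append((orig.animal_id, dup.animal_id))

    snps = list(matrix.snps)
    if x_chromosome:
        px = rng.uniform(0.1, 0.5, n_x_snps)
        xcols = np.empty((len(animals), n_x_snps))
        for i, a in enumerate(animals):
            if a.recorded_sex == "female":
                xcols[i] = rng.binomial(2, px)
            else:
                xcols[i] = 2.0 * (rng.random(n_x_snps) < px)
                err = rng.random(n_x_snps) < x_error_rate
                xcols[i, err] = 1.0
        max_bp = max(s.position_bp for s in snps) + 1
        for j in range(n_x_snps):
            snps.append(SnpRecord(snp_id=f"snp_X_{j:05d}", chromosome="X",
                                  position_bp=int(max_bp + j * 1000)))
        dosages = np.hstack([dosages, xcols])
        manifest["x_snps"] = n_x_snps

    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = np.where(mask, np.nan, dosages)

    return GenotypeMatrix(animals, snps, dosages), manifest


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

PROFILES = {
    "tiny": SimConfig(ne_trajectory=[(50, 50)], n_chromosomes=2,
                      chromosome_length_cm=50.0, n_snps_per_chromosome=250,
                      burnin_generations=200, sample_size=50),
    "recovery": SimConfig(ne_trajectory=[(100, 100)], n_chromosomes=3,
                          chromosome_length_cm=100.0,
                          n_snps_per_chromosome=2000,
                          burnin_generations=400, sample_size=200),
}


def end_to_end_fixture(profile: str, outdir, rng_seed: int = 0
                       ) -> dict[str, Path]:
    """Write a complete on-disk dataset (ped/map, breed file, linkage map,
    truth) for the named profile; returns the file paths."""
    try:
        base = PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(PROFILES)}")
    cfg = SimConfig(**{**base.__dict__, "rng_seed": rng_seed})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, matrix, truth = simulate_population(cfg)

    paths = {"ped": outdir / "genotypes.ped", "map": outdir / "genotypes.map",
             "breeds": outdir / "breeds.tsv",
             "linkage_map": outdir / "linkage_map.tsv",
             "truth": outdir / "truth.json",
             "true_map": outdir / "true_map.tsv"}
    write_ped_map(matrix, paths["ped"], paths["map"])
    with open(paths["breeds"], "w") as fh:
        fh.write("animal_id\tRom\n")
        for a in matrix.animals:
            fh.write(f"{a.animal_id}\t1.0\n")

    # sparse anchors along the (uniform-rate) true map, 2 per cM
    anchors = []
    true_rows = []
    for c, cm in enumerate(truth.maps_cm):
        chrom = str(c + 1)
        bp = np.round(cm * 1e6).astype(np.int64)
        n_anchor = max(2, int(round((cm[-1] - cm[0]) * 2)))
        sel = np.unique(np.linspace(0, cm.size - 1, n_anchor).astype(int))
        for i in sel:
            anchors.append({"snp_id": f"snp_{chrom}_{i:05d}",
                            "chromosome": chrom, "position_bp": int(bp[i]),
                            "genetic_cm": float(cm[i])})
        for i in range(cm.size):
            true_rows.append({"snp_id": f"snp_{chrom}_{i:05d}",
                              "chromosome": chrom,
                              "position_bp": int(bp[i]),
                              "genetic_cm": float(cm[i])})
    LinkageMap(pd.DataFrame(anchors)).to_tsv(paths["linkage_map"])
    pd.DataFrame(true_rows).to_csv(paths["true_map"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
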