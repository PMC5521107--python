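"""Linkage-disequilibrium decay curves on a genetic-distance grid.

Per chromosome, random samples of marker pairs are scored with r² (the
squared correlation of allele counts) and a local polynomial regression of
r² on genetic distance is evaluated on a fixed grid of 2000 points between
0.5 and 50 cM. The sampling + fit is repeated (30 replicates by default)
and the replicate mean and variance are kept per grid point; chromosomes
are then combined by inverse-variance weighting, which also yields the
95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._loess import local_polynomial
from .genotype_data import GenotypeMatrix
from .genetic_map import DenseGeneticMap

__all__ = [
    "default_grid", "LdGrid", "DecayCurve", "pairwise_r2", "haplotype_r2",
    "em_haplotype_r2", "sample_pairs", "pair_r2", "fit_decay",
    "replicate_grid", "ld_grid_for_matrix", "combine_chromosomes",
]

GRID_MIN_CM = 0.5
GRID_MAX_CM = 50.0
GRID_POINTS = 2000


def default_grid(n_points: int = GRID_POINTS, lo: float = GRID_MIN_CM,
                 hi: float = GRID_MAX_CM) -> np.ndarray:
    """Equally spaced genetic distances (cM), endpoints included."""
    return np.linspace(lo, hi, n_points)


# ---------------------------------------------------------------------------
# r² estimators
# ---------------------------------------------------------------------------

def pairwise_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Composite r²: squared Pearson correlation of unphased dosage
    vectors over pairwise-complete animals. NaN when either locus is
    monomorphic in the pairwise-complete subset."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return np.nan
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return np.nan
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def haplotype_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r² from phased haplotypes: [f(AB) - f(A)f(B)]² / f(A)f(a)f(B)f(b)."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    fa, fb = a.mean(), b.mean()
    if fa in (0.0, 1.0) or fb in (0.0, 1.0):
        return np.nan
    fab = (a * b).mean()
    d = fab - fa * fb
    return float(d * d / (fa * (1 - fa) * fb * (1 - fb)))


def em_haplotype_r2(dosages_a: np.ndarray, dosages_b: np.ndarray,
                    max_iter: int = 100, tol: float = 1e-10) -> float:
    """r² via EM estimation of two-locus haplotype frequencies from
    unphased genotypes, then the haplotype-frequency formula. Only the
    double heterozygote class has ambiguous phase."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        return np.nan
    # known haplotype contributions; x = count of AB among double hets
    n_dh = int(((a == 1) & (b == 1)).sum())
    # counts of haplotypes fixed by genotype (A = allele counted by dosage)
    c_ab = float((a * b).sum()) - n_dh          # resolved AB copies
    c_aB = float((a * (2 - b)).sum()) - n_dh
    c_Ab = float(((2 - a) * b).sum()) - n_dh
    c_AB_ = float(((2 - a) * (2 - b)).sum()) - n_dh
    fa, fb = a.mean() / 2, b.mean() / 2
    if fa in (0.0, 1.0) or fb in (0.0, 1.0):
        return np.nan
    f = np.array([fa * fb, fa * (1 - fb), (1 - fa) * fb, (1 - fa) * (1 - fb)])
    for _ in range(max_iter):
        # P(double het from AB/ab vs Ab/aB)
        p_cis = f[0] * f[3]
        p_trans = f[1] * f[2]
        w = p_cis / (p_cis + p_trans) if (p_cis + p_trans) > 0 else 0.5
        # resolved copies are half the genotype products; each cis double
        # het carries one AB and one ab, each trans one Ab and one aB
        counts = np.array([c_ab / 2 + n_dh * w, c_aB / 2 + n_dh * (1 - w),
                           c_Ab / 2 + n_dh * (1 - w), c_AB_ / 2 + n_dh * w])
        new = counts / counts.sum()
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    fab = f[0]
    d = fab - fa * fb
    return float(d * d / (fa * (1 - fa) * fb * (1 - fb)))


# ---------------------------------------------------------------------------
# pair sampling and vectorised r²
# ---------------------------------------------------------------------------

def sample_pairs(n_snps: int, n_pairs: int, rng_seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Distinct unordered SNP-index pairs drawn uniformly without
    replacement; all pairs when fewer than requested exist."""
    if n_snps < 2:
        raise ValueError("need at least two SNPs")
    total = n_snps * (n_snps - 1) // 2
    rng = np.random.default_rng(rng_seed)
    if total <= n_pairs:
        codes = np.arange(total)
    else:
        codes = rng.choice(total, size=n_pairs, replace=False)
    # decode triangular index: pair (i, j), i < j
    i = (np.floor((2 * n_snps - 1 - np.sqrt((2 * n_snps - 1) ** 2
                                            - 8 * codes)) / 2)).astype(np.intp)
    first = i * (2 * n_snps - i - 1) // 2
    j = (codes - first + i + 1).astype(np.intp)
    return i, j


def pair_r2(dosages: np.ndarray, ia: np.ndarray, jb: np.ndarray
            ) -> np.ndarray:
    """Composite r² for many pairs at once.

    Fast path (no missing data): correlation of standardised columns.
    With missing data, falls back to per-pair pairwise-complete r².
    """
    d = dosages
    if not np.isnan(d).any():
        n = d.shape[0]
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (d - mu) / sd
        r = np.einsum("ij,ij->j", z[:, ia], z[:, jb]) / n
        r2 = r * r
        bad = (sd[ia] == 0) | (sd[jb] == 0)
        return np.where(bad, np.nan, r2)
    return np.array([pairwise_r2(d[:, a], d[:, b]) for a, b in zip(ia, jb)])


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def fit_decay(distance_cm: np.ndarray, r2: np.ndarray,
              grid_cm: np.ndarray | None = None, *, span: float = 0.05,
              min_pairs: int = 50, bin_threshold: int = 4000,
              n_bins: int = 1000) -> np.ndarray:
    """Local-polynomial regression of r² on genetic distance, evaluated at
    the grid; predictions clamped to [0, 1]. Pairs outside the grid range
    still inform the fit near its boundaries.

    Above ``bin_threshold`` pairs, the points are pre-aggregated into
    ``n_bins`` equal-width distance bins and the smoother runs on the bin
    means with count weights — the usual loess acceleration; the bin width
    (range / n_bins, ~0.1 cM here) is far below the smoothing bandwidth.
    """
    grid = default_grid() if grid_cm is None else np.asarray(grid_cm)
    x = np.asarray(distance_cm, dtype=float)
    y = np.asarray(r2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    inside = (x >= grid.min()) & (x <= grid.max())
    if inside.sum() < min_pairs:
        raise ValueError(f"only {int(inside.sum())} informative pairs inside "
                         f"the grid range (need {min_pairs})")
    if x.size > bin_threshold:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        counts = np.bincount(which, minlength=n_bins).astype(float)
        keep = counts > 0
        bx = np.bincount(which, weights=x, minlength=n_bins)[keep] / counts[keep]
        by = np.bincount(which, weights=y, minlength=n_bins)[keep] / counts[keep]
        pred = local_polynomial(bx, by, grid, span=span, degree=1,
                                sample_weight=counts[keep])
    else:
        pred = local_polynomial(x, y, grid, span=span, degree=1)
    return np.clip(pred, 0.0, 1.0)


@dataclass
class LdGrid:
    """Per-chromosome LD-decay curves over resampling replicates."""

    method: str
    grid_cm: np.ndarray
    mean_r2: dict[str, np.ndarray] = field(default_factory=dict)
    var_r2: dict[str, np.ndarray] = field(default_factory=dict)
    replicates: dict[str, np.ndarray] = field(default_factory=dict)
    n_replicates: int = 0

    @property
    def chromosomes(self) -> list[str]:
        return list(self.mean_r2)

    def to_tsv(self, path) -> None:
        cols = {"grid_cm": self.grid_cm}
        for c in self.chromosomes:
            cols[f"mean_r2_{c}"] = self.mean_r2[c]
            cols[f"var_r2_{c}"] = self.var_r2[c]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass
class DecayCurve:
    """Inverse-variance combination of per-chromosome decay curves."""

    method: str
    grid_cm: np.ndarray
    weighted_mean_r2: np.ndarray
    weighted_se: np.ndarray

    @property
    def ci95_low(self) -> np.ndarray:
        return self.weighted_mean_r2 - 1.96 * self.weighted_se

    @property
    def ci95_high(self) -> np.ndarray:
        return self.weighted_mean_r2 + 1.96 * self.weighted_se

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "grid_cm": self.grid_cm,
            "weighted_mean_r2": self.weighted_mean_r2,
            "weighted_se": self.weighted_se,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
        }).to_csv(path, sep="\t", index=False)


def replicate_grid(dosages: np.ndarray, positions_cm: np.ndarray,
                   grid_cm: np.ndarray | None = None, *,
                   n_pairs: int = 20000, n_reps: int = 30,
                   rng_seed: int = 0, span: float = 0.05,
                   min_pairs: int = 50
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replicate LD-decay curves for one chromosome.

    Each replicate r draws its own pair sample (seed ``rng_seed + r``),
    computes composite r² and distances, and fits the decay curve on the
    grid. Returns (mean, variance, replicate curves); the variance is the
    sample variance over replicates (NaN when n_reps == 1).
    """
    grid = default_grid() if grid_cm is None else np.asarray(grid_cm)
    pos = np.asarray(positions_cm, dtype=float)
    curves = []
    for r in range(n_reps):
        ia, jb = sample_pairs(pos.size, n_pairs, rng_seed + r)
        dist = np.abs(pos[ia] - pos[jb])
        r2 = pair_r2(dosages, ia, jb)
        curves.append(fit_decay(dist, r2, grid, span=span,
                                min_pairs=min_pairs))
    reps = np.asarray(curves)
    mean = reps.mean(axis=0)
    var = reps.var(axis=0, ddof=1) if n_reps > 1 else np.full(grid.size, np.nan)
    return mean, var, reps


def ld_grid_for_matrix(matrix: GenotypeMatrix, dense_map: DenseGeneticMap,
                       grid_cm: np.ndarray | None = None, *,
                       n_pairs: int = 20000, n_reps: int = 30,
                       rng_seed: int = 0, span: float = 0.05,
                       min_pairs: int = 50) -> LdGrid:
    """Run replicate_grid over every chromosome of a genotype matrix,
    pairing SNPs under the distances of the given dense map."""
    grid = default_grid() if grid_cm is None else np.asarray(grid_cm)
    out = LdGrid(dense_map.method, grid, n_replicates=n_reps)
    snp_pos = dict(zip(dense_map.table["snp_id"],
                       dense_map.table["genetic_cm"]))
    for chrom in dense_map.chromosomes:
        jmask = matrix.chromosome_mask(chrom)
        idx = np.flatnonzero(jmask)
        if idx.size < 2:
            continue
        ids = [matrix.snps[j].snp_id for j in idx]
        pos = np.array([snp_pos.get(s, np.nan) for s in ids])
        keep = ~np.isnan(pos)
        if keep.sum() < 2:
            continue
        dos = matrix.dosages[:, idx[keep]]
        try:
            mean, var, reps = replicate_grid(
                dos, pos[keep], grid, n_pairs=n_pairs, n_reps=n_reps,
                rng_seed=rng_seed, span=span, min_pairs=min_pairs)
        except ValueError:
            continue                       # chromosome flagged absent
        out.mean_r2[chrom] = mean
        out.var_r2[chrom] = var
        out.replicates[chrom] = reps
    return out


# ---------------------------------------------------------------------------
# cross-chromosome combination
# ---------------------------------------------------------------------------

def inverse_variance_combine(means: np.ndarray, variances: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance weighted mean and its standard error, column-wise.

    ``means``/``variances`` are (n_series, n_points). Zero variances get
    their weight capped at the largest finite weight in the same column;
    a column with a single valid series returns that series' mean with
    SE = sqrt(var).
    """
    m = np.atleast_2d(np.asarray(means, dtype=float))
    v = np.atleast_2d(np.asarray(variances, dtype=float))
    with np.errstate(divide="ignore"):
        w = 1.0 / v
    valid = np.isfinite(m) & np.isfinite(v) & (v >= 0)
    w = np.where(valid, w, 0.0)
    # cap infinite weights (zero variance) at the largest finite weight
    finite = np.isfinite(w)
    if (~finite & valid).any():
        cap = np.where(finite, w, 0.0).max(axis=0)
        cap = np.where(cap > 0, cap, 1.0)
        w = np.where(~finite & valid, cap[None, :], w)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (w * m).sum(axis=0) / wsum
        se = np.sqrt(1.0 / wsum)
    mean = np.where(wsum > 0, mean, np.nan)
    se = np.where(wsum > 0, se, np.nan)
    return mean, se


def combine_chromosomes(grid: LdGrid) -> DecayCurve:
    """Combine per-chromosome decay curves into one weighted curve with a
    95% confidence band (weights = 1 / replicate variance)."""
    chroms = grid.chromosomes
    if not chroms:
        raise ValueError("no chromosomes with fitted curves")
    m = np.stack([grid.mean_r2[c] for c in chroms])
    v = np.stack([grid.var_r2[c] for c in chroms])
    mean, se = inverse_variance_combine(m, v)
    return DecayCurve(grid.method, grid.grid_cm, mean, se)
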