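"""Historical effective population size from LD decay.

Sved's drift expectation E(r²) = 1 / (1 + 4 N_e c) links the expected r²
between markers c Morgans apart to the effective population size roughly
T = 1/(2c) generations ago. Inverting it per chromosome along the LD grid
gives an N_e trajectory from 1 generation (50 cM) back to 100 generations
(0.5 cM); chromosomes are combined by inverse-variance weighting, with
replicate-level curves supplying the variances. Supporting procedures:
a Shapiro-Wilk normality screen across chromosomes at every grid point,
generation-targeted extraction of the combined curve, and a parametric
bootstrap comparing the weighted means and variances of two map methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld_decay import LdGrid, inverse_variance_combine

__all__ = [
    "sved_ne", "generations", "NeCurve", "ne_curve",
    "extract_at_generations", "normality_screen", "bootstrap_compare",
    "ComparisonResult",
]


def sved_ne(e_r2, c_morgans, sample_n: int | None = None):
    """Effective population size from expected r² at distance c (Morgans):
    N_e = (1 / 4c) (1 / E(r²) - 1).

    ``sample_n`` applies the finite-sample correction that subtracts 1/n
    from E(r²) before inversion (off by default). Non-positive corrected
    r² yields NaN.
    """
    r2 = np.asarray(e_r2, dtype=float)
    c = np.asarray(c_morgans, dtype=float)
    if (np.asarray(c) <= 0).any():
        raise ValueError("c must be positive")
    if sample_n:
        r2 = r2 - 1.0 / sample_n
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = (1.0 / (4.0 * c)) * (1.0 / r2 - 1.0)
    ne = np.where(r2 > 0, ne, np.nan)
    return float(ne) if ne.ndim == 0 else ne


def generations(c_morgans):
    """Past generation probed by LD at distance c Morgans: T = 1/(2c)."""
    c = np.asarray(c_morgans, dtype=float)
    if (c <= 0).any():
        raise ValueError("c must be positive")
    t = 1.0 / (2.0 * c)
    return float(t) if t.ndim == 0 else t


@dataclass
class NeCurve:
    method: str
    grid_cm: np.ndarray
    c_morgans: np.ndarray
    t_generations: np.ndarray
    per_chromosome: dict[str, np.ndarray] = field(default_factory=dict)
    combined: np.ndarray | None = None
    se: np.ndarray | None = None

    @property
    def ci95_low(self) -> np.ndarray:
        return self.combined - 1.96 * self.se

    @property
    def ci95_high(self) -> np.ndarray:
        return self.combined + 1.96 * self.se

    def to_tsv(self, path) -> None:
        cols = {"t_generations": self.t_generations,
                "c_morgans": self.c_morgans, "grid_cm": self.grid_cm}
        for c, v in self.per_chromosome.items():
            cols[f"ne_{c}"] = v
        cols["ne_combined"] = self.combined
        cols["ci95_low"] = self.ci95_low
        cols["ci95_high"] = self.ci95_high
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def ne_curve(grid: LdGrid, sample_n: int | None = None) -> NeCurve:
    """Per-chromosome and combined N_e along the LD grid.

    Each chromosome's N_e comes from its replicate-mean r²; its variance
    at each grid point is the variance of N_e across the replicate-level
    curves (the same resampling that produced the r² variances). The
    combined curve is the inverse-variance weighted mean with a 95% CI.
    """
    cm = np.asarray(grid.grid_cm, dtype=float)
    c = cm / 100.0
    t = generations(c)
    out = NeCurve(grid.method, cm, c, t)
    means, variances = [], []
    for chrom in grid.chromosomes:
        ne = sved_ne(grid.mean_r2[chrom], c, sample_n)
        out.per_chromosome[chrom] = ne
        reps = grid.replicates.get(chrom)
        if reps is not None and reps.shape[0] > 1:
            ne_reps = sved_ne(reps, c[None, :], sample_n)
            n_ok = np.sum(np.isfinite(ne_reps), axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                var = np.nanvar(ne_reps, axis=0, ddof=1)
            var = np.where(n_ok > 1, var, np.nan)
        else:
            var = np.full(cm.size, np.nan)
        means.append(ne)
        variances.append(var)
    if not means:
        raise ValueError("no chromosomes in the LD grid")
    mean, se = inverse_variance_combine(np.stack(means), np.stack(variances))
    out.combined = mean
    out.se = se
    return out


def extract_at_generations(curve: NeCurve,
                           targets=(1, 5, 20, 50, 100)) -> pd.Series:
    """Combined N_e at chosen past generations, linearly interpolated on
    the t-axis, with the difference N_e(last) - N_e(first) appended."""
    t = curve.t_generations
    ne = curve.combined
    order = np.argsort(t)
    ts, nes = t[order], ne[order]
    lo, hi = ts[0], ts[-1]
    vals = {}
    for tgt in targets:
        if not (lo - 1e-9 <= tgt <= hi + 1e-9):
            raise ValueError(f"generation {tgt} outside grid range "
                             f"[{lo:.2f}, {hi:.2f}]")
        vals[f"ne_{tgt}"] = float(np.interp(tgt, ts, nes))
    first, last = targets[0], targets[-1]
    vals[f"ne_{last}_minus_ne_{first}"] = vals[f"ne_{last}"] - vals[f"ne_{first}"]
    return pd.Series(vals)


def normality_screen(values: np.ndarray, alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Shapiro-Wilk test across chromosomes at each grid point.

    ``values`` is (n_chromosomes, n_points). The Bonferroni threshold is
    alpha / n_points; ``flagged`` marks p <= threshold. Columns with
    constant values get NaN statistics.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n_chrom, n_points = v.shape
    if n_chrom < 3:
        raise ValueError("need at least 3 chromosomes")
    threshold = alpha / n_points
    stat = np.full(n_points, np.nan)
    pval = np.full(n_points, np.nan)
    for j in range(n_points):
        col = v[:, j]
        col = col[np.isfinite(col)]
        if col.size < 3 or np.ptp(col) == 0:
            continue
        res = stats.shapiro(col)
        stat[j], pval[j] = res.statistic, res.pvalue
    return pd.DataFrame({"statistic": stat, "p_value": pval,
                         "threshold": threshold,
                         "flagged": pval <= threshold})


@dataclass
class ComparisonResult:
    statistic_mean: float
    statistic_var: float
    p_mean: float
    p_var: float
    alpha: float = 0.05

    @property
    def rejected_mean(self) -> bool:
        return self.p_mean <= self.alpha

    @property
    def rejected_var(self) -> bool:
        return self.p_var <= self.alpha


def bootstrap_compare(values_m1: np.ndarray, values_m2: np.ndarray,
                      n_boot: int = 1000, rng_seed: int = 0,
                      alpha: float = 0.05) -> ComparisonResult:
    """Parametric bootstrap of mean and variance equality at a grid point.

    Mean test: studentised statistic |mean1 - mean2| / sqrt(v1/n + v2/n);
    null resamples are normal draws with the pooled mean and each sample's
    own variance, re-studentised per resample (bootstrap-t, which keeps
    the test calibrated at small chromosome counts). Variance test:
    |log(var1 / var2)| with null draws at the pooled variance keeping each
    sample's own mean. p = (1 + #{T* >= T_obs}) / (n_boot + 1).
    """
    x = np.asarray(values_m1, dtype=float)
    y = np.asarray(values_m2, dtype=float)
    if x.size != y.size:
        raise ValueError("method samples must have equal chromosome counts")
    if x.size < 3:
        raise ValueError("need at least 3 chromosomes")
    rng = np.random.default_rng(rng_seed)
    n = x.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se = np.sqrt(vx / n + vy / n)
    t_mean = abs(mx - my) / se if se > 0 else 0.0
    t_var = abs(np.log(vx / vy))
    m_pool = (mx + my) / 2.0
    v_pool = (vx + vy) / 2.0

    bx = rng.normal(m_pool, np.sqrt(vx), size=(n_boot, n))
    by = rng.normal(m_pool, np.sqrt(vy), size=(n_boot, n))
    se_boot = np.sqrt(bx.var(axis=1, ddof=1) / n + by.var(axis=1, ddof=1) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mean_boot = np.abs(bx.mean(axis=1) - by.mean(axis=1)) / se_boot

    cx = rng.normal(mx, np.sqrt(v_pool), size=(n_boot, n))
    cy = rng.normal(my, np.sqrt(v_pool), size=(n_boot, n))
    t_var_boot = np.abs(np.log(cx.var(axis=1, ddof=1)
                               / cy.var(axis=1, ddof=1)))

    p_mean = (1 + np.sum(t_mean_boot >= t_mean)) / (n_boot + 1)
    p_var = (1 + np.sum(t_var_boot >= t_var)) / (n_boot + 1)
    return ComparisonResult(t_mean, t_var, float(p_mean), float(p_var), alpha)


def compare_methods(curve_a: NeCurve, curve_b: NeCurve,
                    at_indices: np.ndarray | None = None,
                    n_boot: int = 1000, rng_seed: int = 0) -> pd.DataFrame:
    """bootstrap_compare at a set of grid indices (default: every 100th),
    using the per-chromosome N_e values of two map methods."""
    if set(curve_a.per_chromosome) != set(curve_b.per_chromosome):
        raise ValueError("curves cover different chromosomes")
    chroms = sorted(curve_a.per_chromosome)
    idx = (np.arange(0, curve_a.grid_cm.size, 100)
           if at_indices is None else np.asarray(at_indices))
    rows = []
    for k, j in enumerate(idx):
        a = np.array([curve_a.per_chromosome[c][j] for c in chroms])
        b = np.array([curve_b.per_chromosome[c][j] for c in chroms])
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            continue
        res = bootstrap_compare(a[ok], b[ok], n_boot, rng_seed + k)
        rows.append({"grid_cm": curve_a.grid_cm[j],
                     "t_generations": curve_a.t_generations[j],
                     "p_mean": res.p_mean, "p_var": res.p_var,
                     "rejected_mean": res.rejected_mean,
                     "rejected_var": res.rejected_var})
    return pd.DataFrame(rows)
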