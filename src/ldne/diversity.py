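"""Genomic diversity: heterozygosity, GRM, inbreeding, kinship, MDS.

The genomic relationship matrix follows the VanRaden form
``G = Z Z' / sum_m 2 p_m (1 - p_m)`` with ``Z`` the dosage matrix centred
at twice the allele frequency. Three centring models are available: pooled
frequencies, per-group frequencies, and per-animal expected frequencies
from a least-squares regression of dosage on breed-composition columns
(the breed-composition-adjusted variant used for multi-breed datasets).
Missing dosages contribute zero after centring, which is mean imputation
per SNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix, allele_frequency, breed_groups

__all__ = [
    "Grm", "DistanceMatrix", "MdsResult", "heterozygosity", "compute_grm",
    "inbreeding", "kinship_summary", "distance_matrix", "classical_mds",
    "flag_outliers", "diversity_summary",
]


@dataclass
class Grm:
    animal_ids: list[str]
    g: np.ndarray

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != (len(self.animal_ids),) * 2:
            raise ValueError("GRM shape does not match animal count")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.g, index=self.animal_ids,
                     columns=self.animal_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "Grm":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


@dataclass
class DistanceMatrix:
    animal_ids: list[str]
    d: np.ndarray


@dataclass
class MdsResult:
    animal_ids: list[str]
    coordinates: np.ndarray     # animals x k
    eigenvalues: np.ndarray

    def to_tsv(self, path) -> None:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, columns=[f"dim{i+1}" for i in range(k)])
        df.insert(0, "animal_id", self.animal_ids)
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------

def heterozygosity(matrix: GenotypeMatrix,
                   groups: Sequence[str] | None = None
                   ) -> tuple[pd.Series, pd.Series]:
    """Observed heterozygosity per animal and its mean per group.

    Per-animal He = heterozygous calls / non-missing calls; computed before
    any missing-genotype estimation, on the diversity-stage SNP set.
    """
    d = matrix.dosages
    het = (d == 1).sum(axis=1)
    n = (~np.isnan(d)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = het / n
    if (n == 0).any():
        warnings.warn("animals with no non-missing calls excluded from He")
    per_animal = pd.Series(he, index=matrix.animal_ids, name="He")
    if groups is None:
        groups = breed_groups(matrix)
    per_group = per_animal.groupby(np.asarray(groups)).mean()
    return per_animal, per_group


def compute_grm(matrix: GenotypeMatrix, freq_model: str = "pooled",
                groups: Sequence[str] | None = None) -> Grm:
    """VanRaden genomic relationship matrix.

    freq_model 'pooled' centres every animal at the pooled allele
    frequencies; 'group' centres each animal at its breed group's
    frequencies; 'breed_regression' regresses each SNP's dosage on the
    animals' breed-composition columns (least squares, intercept absorbed
    by an 'Other' remainder column) and centres at the fitted values.
    The denominator always uses pooled frequencies over polymorphic SNPs.
    """
    d = matrix.dosages
    present = ~np.isnan(d)
    p = allele_frequency(matrix)
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    d = d[:, poly]
    present = present[:, poly]
    p = p[poly]

    if freq_model == "pooled":
        expected = np.broadcast_to(2 * p, d.shape)
    elif freq_model == "group":
        g = np.asarray(groups if groups is not None else breed_groups(matrix))
        expected = np.empty_like(d)
        for lab in np.unique(g):
            idx = g == lab
            sub = d[idx]
            with np.errstate(invalid="ignore", divide="ignore"):
                pg = np.nansum(sub, axis=0) / (2 * np.sum(~np.isnan(sub), axis=0))
            pg = np.where(np.isnan(pg), p, pg)
            expected[idx] = 2 * pg
    elif freq_model == "breed_regression":
        X = _composition_design(matrix)
        dz = np.where(present, d, np.nan)
        col_mean = np.nanmean(dz, axis=0)
        dfill = np.where(present, d, col_mean)
        beta, *_ = np.linalg.lstsq(X, dfill, rcond=None)
        expected = X @ beta
    else:
        raise ValueError(f"unknown freq_model {freq_model!r}")

    z = np.where(present, d - expected, 0.0)
    denom = float(np.sum(2 * p * (1 - p)))
    g = (z @ z.T) / denom
    return Grm(matrix.animal_ids, g)


def _composition_design(matrix: GenotypeMatrix) -> np.ndarray:
    labels = sorted({b for a in matrix.animals for b in a.breed_composition})
    X = np.zeros((matrix.n_animals, len(labels) + 1))
    for i, a in enumerate(matrix.animals):
        total = 0.0
        for j, lab in enumerate(labels):
            X[i, j] = a.breed_composition.get(lab, 0.0)
            total += X[i, j]
        X[i, -1] = max(0.0, 1.0 - total)      # 'Other' remainder
    return X


def inbreeding(grm: Grm, group_idx: Sequence[int] | None = None) -> float:
    """Average inbreeding = mean of the GRM diagonal minus 1."""
    diag = np.diag(grm.g)
    if group_idx is not None:
        diag = diag[np.asarray(group_idx)]
    if diag.size == 0:
        raise ValueError("empty group")
    return float(diag.mean() - 1.0)


def kinship_summary(grm: Grm, groups: Sequence[str]) -> pd.DataFrame:
    """Group x group mean relationship; within-group means exclude the
    diagonal, between-group means run over all cross pairs."""
    g = np.asarray(groups)
    labs = sorted(set(g))
    out = pd.DataFrame(np.nan, index=labs, columns=labs)
    for a in labs:
        ia = np.flatnonzero(g == a)
        for b in labs:
            ib = np.flatnonzero(g == b)
            block = grm.g[np.ix_(ia, ib)]
            if a == b:
                if ia.size < 2:
                    continue
                mask = ~np.eye(ia.size, dtype=bool)
                out.loc[a, b] = block[mask].mean()
            else:
                out.loc[a, b] = block.mean()
    return out


def distance_matrix(grm: Grm) -> DistanceMatrix:
    """d_ij = 1 - g_ij off the diagonal; d_ii = 0 regardless of g_ii."""
    d = 1.0 - grm.g
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(grm.animal_ids, d)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson metric MDS of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and scales the
    top-k eigenvectors by root eigenvalues. Negative eigenvalues (the
    matrix not being Euclidean-realisable) are truncated to zero.
    """
    d = dist.d
    n = d.shape[0]
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if (w[:k] < -1e-9 * max(1.0, abs(w[0]))).any():
        warnings.warn("negative eigenvalues truncated to zero in MDS")
    pos = np.flatnonzero(w > 1e-12 * max(1.0, abs(w[0])))
    use = pos[:k]
    if use.size < k:
        warnings.warn(f"only {use.size} positive eigenvalues; "
                      f"returning {use.size} dimensions")
    coords = v[:, use] * np.sqrt(w[use])
    return MdsResult(dist.animal_ids, coords, w[use])


def flag_outliers(dist: DistanceMatrix, groups: Sequence[str],
                  fraction: float = 0.01) -> set[str]:
    """Most genetically distant animals within each group.

    Score_i = sum over group mates of d_ij**2; the ceil(fraction * size)
    highest scores are flagged (none for singleton groups); ties broken
    by animal_id.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return set()
    g = np.asarray(groups)
    ids = np.array(dist.animal_ids)
    flagged: set[str] = set()
    for lab in np.unique(g):
        idx = np.flatnonzero(g == lab)
        if idx.size < 2:
            continue
        block = dist.d[np.ix_(idx, idx)]
        scores = (block ** 2).sum(axis=1)
        n_flag = int(np.ceil(fraction * idx.size))
        order = sorted(range(idx.size), key=lambda i: (-scores[i], ids[idx[i]]))
        flagged.update(ids[idx[i]] for i in order[:n_flag])
    return flagged


def diversity_summary(matrix: GenotypeMatrix, grm: Grm,
                      groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-group He and F plus the group-by-group kinship table, shaped
    like a published per-breed diversity summary."""
    if groups is None:
        groups = breed_groups(matrix)
    g = np.asarray(groups)
    _, he = heterozygosity(matrix, g)
    kin = kinship_summary(grm, g)
    rows = kin.copy()
    f = {lab: inbreeding(grm, np.flatnonzero(g == lab)) for lab in kin.index}
    rows.loc["Inbreeding"] = [f[lab] for lab in kin.columns]
    rows.loc["Heterozygosity"] = [he.get(lab, np.nan) for lab in kin.columns]
    return rows
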