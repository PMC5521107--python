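"""Physical-to-genetic map conversion (methods M1, M2, M3).

A sparse linkage map (sex-averaged Kosambi cM positions for a subset of
chip SNPs, two anchors per cM) is turned into genetic positions for every
chip SNP in three ways:

* **M1** — a single genome-wide conversion ratio (default 1 cM/Mb).
* **M2** — a per-chromosome ratio, total linkage cM over physical Mb.
* **M3** — local polynomial (loess) regression of anchor cM on physical
  position, evaluated at every chip SNP, after trimming anchor intervals
  with extreme cM/Mb ratios (>= the genome-wide 99.9th percentile) or
  negative delta-cM; predictions are made non-decreasing by a running-max
  clamp and extended beyond the anchor range at the chromosome's M2 ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._loess import local_polynomial

__all__ = [
    "LinkageMap", "DenseGeneticMap", "SmootherConfig", "m1_positions",
    "chromosome_ratios", "m2_positions", "interval_ratios", "m3_positions",
    "recombination_profile", "map_summary", "kosambi_cm_to_r",
    "kosambi_r_to_cm", "haldane_cm_to_r", "write_ucsc_track",
    "read_ucsc_track",
]

_MAP_COLS = ["snp_id", "chromosome", "position_bp", "genetic_cm"]


@dataclass
class LinkageMap:
    """Sparse linkage map: cumulative genetic positions for anchor SNPs."""

    table: pd.DataFrame      # snp_id, chromosome, position_bp, genetic_cm

    def __post_init__(self):
        t = self.table[_MAP_COLS].copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t = t.sort_values(["chromosome", "position_bp", "snp_id"],
                          kind="stable").reset_index(drop=True)
        for chrom, sub in t.groupby("chromosome"):
            if sub["position_bp"].duplicated().any():
                raise ValueError(f"duplicate physical positions on {chrom}")
        self.table = t

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == str(chrom)]

    def genetic_length(self, chrom: str) -> float:
        sub = self.chromosome(chrom)
        if sub.empty:
            raise KeyError(f"chromosome {chrom} absent from linkage map")
        return float(sub["genetic_cm"].max() - sub["genetic_cm"].min())

    @classmethod
    def from_tsv(cls, path) -> "LinkageMap":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"chromosome": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DenseGeneticMap:
    """Genetic position for every chip SNP under one conversion method."""

    method: str
    table: pd.DataFrame      # snp_id, chromosome, position_bp, genetic_cm

    def __post_init__(self):
        t = self.table[_MAP_COLS].copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t = t.sort_values(["chromosome", "position_bp", "snp_id"],
                          kind="stable").reset_index(drop=True)
        for chrom, sub in t.groupby("chromosome"):
            if (np.diff(sub["genetic_cm"].to_numpy()) < -1e-9).any():
                raise ValueError(f"{self.method}: genetic positions decrease "
                                 f"on chromosome {chrom}")
        self.table = t

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == str(chrom)]

    def positions_cm(self, chrom: str) -> np.ndarray:
        return self.chromosome(chrom)["genetic_cm"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, method: str = "unknown") -> "DenseGeneticMap":
        return cls(method, pd.read_csv(path, sep="\t",
                                       dtype={"chromosome": str}))


@dataclass
class SmootherConfig:
    span: float = 0.3
    degree: int = 2
    min_anchors: int = 10


# ---------------------------------------------------------------------------
# M1 / M2
# ---------------------------------------------------------------------------

def m1_positions(snps: pd.DataFrame, genome_ratio: float = 1.0
                 ) -> DenseGeneticMap:
    """Constant genome-wide conversion: cM = Mb * ratio (default 1 cM/Mb)."""
    if genome_ratio <= 0:
        raise ValueError("genome_ratio must be positive")
    t = snps[["snp_id", "chromosome", "position_bp"]].copy()
    t["genetic_cm"] = t["position_bp"] / 1e6 * genome_ratio
    return DenseGeneticMap("M1", t)


def chromosome_ratios(linkage: LinkageMap,
                      physical_lengths_mb: dict[str, float]
                      ) -> dict[str, float]:
    """Per-chromosome cM/Mb: total linkage genetic length over physical
    length (in Mb, conventionally the last chip SNP's position)."""
    out = {}
    for chrom, mb in physical_lengths_mb.items():
        if mb <= 0:
            raise ValueError(f"non-positive physical length for {chrom}")
        out[str(chrom)] = linkage.genetic_length(str(chrom)) / mb
    return out


def m2_positions(snps: pd.DataFrame, ratios: dict[str, float]
                 ) -> DenseGeneticMap:
    """Per-chromosome conversion: cM = Mb * ratio(chromosome)."""
    t = snps[["snp_id", "chromosome", "position_bp"]].copy()
    t["chromosome"] = t["chromosome"].astype(str)
    missing = set(t["chromosome"]) - set(ratios)
    if missing:
        raise KeyError(f"no ratio for chromosome(s) {sorted(missing)}")
    t["genetic_cm"] = (t["position_bp"] / 1e6
                       * t["chromosome"].map(ratios).astype(float))
    return DenseGeneticMap("M2", t)


# ---------------------------------------------------------------------------
# interval trimming and M3
# ---------------------------------------------------------------------------

def interval_ratios(linkage: LinkageMap,
                    percentile: float = 99.9) -> pd.DataFrame:
    """Consecutive-anchor intervals with their cM/Mb ratio and a trim mask.

    ``removed`` marks intervals whose ratio reaches the genome-wide
    percentile (type-7 empirical quantile) and intervals with negative
    delta-cM (implying an alternative marker order).
    """
    rows = []
    for chrom in linkage.chromosomes:
        sub = linkage.chromosome(chrom)
        bp = sub["position_bp"].to_numpy(dtype=float)
        cm = sub["genetic_cm"].to_numpy(dtype=float)
        if bp.size < 2:
            continue
        dmb = np.diff(bp) / 1e6
        dcm = np.diff(cm)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dmb > 0, dcm / dmb, np.nan)
        for i in range(dmb.size):
            rows.append({"chromosome": chrom,
                         "start_bp": int(bp[i]), "end_bp": int(bp[i + 1]),
                         "delta_cm": dcm[i], "delta_mb": dmb[i],
                         "ratio": ratio[i]})
    df = pd.DataFrame(rows)
    if df.empty:
        df["removed"] = pd.Series(dtype=bool)
        return df
    ratios = df["ratio"].to_numpy()
    finite = ratios[np.isfinite(ratios)]
    q = np.quantile(finite, percentile / 100.0)
    if np.ptp(finite) <= 1e-9 * max(1.0, np.abs(finite).max()):
        # constant-ratio map up to rounding: the percentile equals every
        # ratio and trimming would delete the map; nothing is extreme
        extreme = np.zeros(len(df), dtype=bool)
    else:
        extreme = ratios >= q
    df["removed"] = extreme | (df["delta_cm"] < 0)
    return df


def _trimmed_anchors(linkage: LinkageMap, intervals: pd.DataFrame,
                     chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Anchor (bp, cM) with removed intervals contributing zero length.

    Rebuilds cumulative anchor cM from the kept intervals: a removed
    interval collapses to zero recombination, keeping every anchor
    addressable while honouring its removal.
    """
    sub = linkage.chromosome(chrom)
    bp = sub["position_bp"].to_numpy(dtype=float)
    ints = intervals[intervals["chromosome"] == chrom]
    dcm = ints["delta_cm"].to_numpy(dtype=float).copy()
    dcm[ints["removed"].to_numpy()] = 0.0
    cm = np.concatenate([[0.0], np.cumsum(dcm)])
    return bp, cm


def m3_positions(linkage: LinkageMap, snps: pd.DataFrame,
                 smoother: SmootherConfig | None = None,
                 percentile: float = 99.9) -> DenseGeneticMap:
    """Loess interpolation of the sparse linkage map onto every chip SNP.

    Per chromosome: trim extreme/negative anchor intervals, regress anchor
    cM on physical Mb with a local polynomial, evaluate at the chip SNPs,
    clamp to non-decreasing, and extrapolate past the anchor range at the
    chromosome's M2 ratio. Chromosomes with too few surviving anchors fall
    back to M2.
    """
    smoother = smoother or SmootherConfig()
    intervals = interval_ratios(linkage, percentile)
    t = snps[["snp_id", "chromosome", "position_bp"]].copy()
    t["chromosome"] = t["chromosome"].astype(str)
    pieces = []
    for chrom, chip in t.groupby("chromosome", sort=False):
        chip = chip.sort_values(["position_bp", "snp_id"], kind="stable")
        xq = chip["position_bp"].to_numpy(dtype=float) / 1e6
        phys_mb = xq.max() if xq.size else 1.0
        try:
            bp, cm = _trimmed_anchors(linkage, intervals, str(chrom))
        except KeyError:
            bp = np.array([])
            cm = np.array([])
        if bp.size >= smoother.min_anchors:
            xa = bp / 1e6
            m2_ratio = (cm[-1] - cm[0]) / phys_mb if phys_mb > 0 else 1.0
            inside = (xq >= xa[0]) & (xq <= xa[-1])
            pred = np.empty_like(xq)
            if inside.any():
                pred[inside] = local_polynomial(
                    xa, cm, xq[inside], span=smoother.span,
                    degree=smoother.degree)
            # anchor-end values from the fit itself keep extrapolation continuous
            ends = local_polynomial(xa, cm, np.array([xa[0], xa[-1]]),
                                    span=smoother.span, degree=smoother.degree)
            pred[xq < xa[0]] = ends[0] - (xa[0] - xq[xq < xa[0]]) * m2_ratio
            pred[xq > xa[-1]] = ends[1] + (xq[xq > xa[-1]] - xa[-1]) * m2_ratio
            pred = np.maximum.accumulate(pred)       # non-decreasing repair
            pred = np.maximum(pred, 0.0)             # extrapolation floor
        else:
            warnings.warn(f"chromosome {chrom}: "
                          f"{bp.size} anchors < {smoother.min_anchors}; "
                          "falling back to the per-chromosome ratio (M2)")
            try:
                ratio = linkage.genetic_length(str(chrom)) / phys_mb
            except KeyError:
                ratio = 1.0
            pred = xq * ratio
        piece = chip.copy()
        piece["genetic_cm"] = pred
        pieces.append(piece)
    return DenseGeneticMap("M3", pd.concat(pieces, ignore_index=True))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def recombination_profile(dense: DenseGeneticMap) -> pd.DataFrame:
    """cM/Mb over each consecutive chip-SNP interval (a recombination-rate
    track along the genome)."""
    rows = []
    for chrom in dense.chromosomes:
        sub = dense.chromosome(chrom)
        bp = sub["position_bp"].to_numpy(dtype=float)
        cm = sub["genetic_cm"].to_numpy(dtype=float)
        dmb = np.diff(bp) / 1e6
        dcm = np.diff(cm)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dmb > 0, dcm / dmb, np.nan)
        rows.append(pd.DataFrame({
            "chromosome": chrom, "start_bp": bp[:-1].astype(int),
            "end_bp": bp[1:].astype(int), "rate_cm_per_mb": ratio}))
    return pd.concat(rows, ignore_index=True)


def summarize_chromosomes(physical_mb: np.ndarray, n_snps: np.ndarray,
                          genetic_cm: np.ndarray,
                          chromosomes: list[str]) -> tuple[pd.DataFrame, float, float]:
    """Chromosome summary table with a TOTAL row plus the Pearson
    correlation (and its t-test p-value) of physical length vs cM/Mb.

    The TOTAL row sums Mb, SNP counts and cM, and averages the
    per-chromosome ratios (unweighted).
    """
    mb = np.asarray(physical_mb, dtype=float)
    cm = np.asarray(genetic_cm, dtype=float)
    ratio = cm / mb
    df = pd.DataFrame({"chromosome": chromosomes, "physical_mb": mb,
                       "n_snps": np.asarray(n_snps),
                       "genetic_cm": cm, "ratio_cm_per_mb": ratio})
    total = pd.DataFrame([{"chromosome": "TOTAL", "physical_mb": mb.sum(),
                           "n_snps": int(np.sum(n_snps)),
                           "genetic_cm": cm.sum(),
                           "ratio_cm_per_mb": ratio.mean()}])
    if len(mb) >= 3 and np.std(ratio) > 0 and np.std(mb) > 0:
        r, p = stats.pearsonr(mb, ratio)
    else:
        r, p = np.nan, np.nan
    return pd.concat([df, total], ignore_index=True), float(r), float(p)


def map_summary(linkage: LinkageMap, dense: DenseGeneticMap
                ) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome map statistics from a linkage map and a dense map.

    Physical length is the last chip SNP's position in Mb; genetic length
    is the linkage map's total cM; n_snps counts linkage anchors.
    """
    chroms, mb, nsnp, cm = [], [], [], []
    for chrom in dense.chromosomes:
        sub = dense.chromosome(chrom)
        chroms.append(chrom)
        mb.append(sub["position_bp"].max() / 1e6)
        anchors = linkage.chromosome(chrom)
        nsnp.append(len(anchors))
        cm.append(linkage.genetic_length(chrom) if len(anchors) else np.nan)
    return summarize_chromosomes(np.array(mb), np.array(nsnp),
                                 np.array(cm), chroms)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm_to_r(cm):
    """Kosambi map function: recombination fraction from cM."""
    d = np.asarray(cm, dtype=float) / 100.0       # Morgans
    return 0.5 * np.tanh(2.0 * d)


def kosambi_r_to_cm(r):
    """Inverse Kosambi: cM from recombination fraction in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    return 100.0 * 0.25 * np.log((1 + 2 * r) / (1 - 2 * r))


def haldane_cm_to_r(cm):
    """Haldane map function (no interference), used by the simulator."""
    d = np.asarray(cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


# ---------------------------------------------------------------------------
# UCSC custom tracks
# ---------------------------------------------------------------------------

def write_ucsc_track(table: pd.DataFrame, path, name: str,
                     value_col: str) -> None:
    """Four-column UCSC custom track: chromosome, previous marker position,
    marker position, value (genetic position or interval rate)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for _, row in table.iterrows():
            fh.write(f"{row['chromosome']}\t{int(row['start_bp'])}\t"
                     f"{int(row['end_bp'])}\t{row[value_col]:.6g}\n")


def dense_map_track(dense: DenseGeneticMap) -> pd.DataFrame:
    rows = []
    for chrom in dense.chromosomes:
        sub = dense.chromosome(chrom)
        bp = sub["position_bp"].to_numpy()
        cm = sub["genetic_cm"].to_numpy()
        rows.append(pd.DataFrame({"chromosome": chrom, "start_bp": bp[:-1],
                                  "end_bp": bp[1:], "value": cm[1:]}))
    return pd.concat(rows, ignore_index=True)


def read_ucsc_track(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("track"):
            raise ValueError("not a UCSC custom track (missing 'track' line)")
        df = pd.read_csv(fh, sep="\t", header=None,
                         names=["chromosome", "start_bp", "end_bp", "value"],
                         dtype={"chromosome": str})
    return df
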