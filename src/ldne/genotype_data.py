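"""Genotype containers, file I/O and quality control.

Genotypes are held as an animals x SNPs dosage matrix (count of the second
listed allele, 0/1/2) with ``NaN`` as the missing sentinel. Quality control
mirrors the standard SNP-chip pipeline for a multi-breed sheep dataset:
SNP call rate, MAF > 0, Hardy-Weinberg screening (per dataset, or
"failed in every breed group" when breeds are pooled), removal of
non-autosomal SNPs ahead of LD work, animal call rate, sex checking from
X-chromosome heterozygosity, and identity-by-state duplicate detection on
a random subset of autosomal markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = np.nan

#: chromosome labels treated as non-autosomal
NON_AUTOSOMES = {"X", "Y", "XY", "MT", "0"}

PURE_BREEDS = ("Rom", "Coop", "Peren", "Tex")
BREED_GROUPS = PURE_BREEDS + ("CompRCP", "CompRCPT", "Comprcp2", "unassigned")


# ---------------------------------------------------------------------------
# records and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if self.position_bp < 0:
            raise ValueError(f"negative position for {self.snp_id}")


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    recorded_sex: str = "unknown"          # male / female / unknown
    flock_id: str = "0"
    breed_composition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for breed, p in self.breed_composition.items():
            if p < 0:
                raise ValueError(f"negative proportion for {breed}")
        if sum(self.breed_composition.values()) > 1 + 1e-9:
            raise ValueError(f"breed proportions exceed 1 for {self.animal_id}")


class GenotypeMatrix:
    """Animals x SNPs dosage matrix with metadata.

    ``dosages[i, j]`` is the count (0, 1, 2) of the second allele of SNP j
    in animal i, or NaN when the call is missing. Within a chromosome SNPs
    are kept sorted by physical position (ties broken by snp_id).
    """

    def __init__(self, animals: Sequence[AnimalRecord],
                 snps: Sequence[SnpRecord], dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(animals), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(animals)} animals x {len(snps)} SNPs")
        ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.animals = list(animals)
        self.snps = list(snps)
        self.dosages = dosages
        self._sort_snps()

    def _sort_snps(self) -> None:
        key = [(s.chromosome, s.position_bp, s.snp_id) for s in self.snps]
        order = sorted(range(len(self.snps)),
                       key=lambda j: (_chrom_key(key[j][0]), key[j][1], key[j][2]))
        if order != list(range(len(self.snps))):
            self.snps = [self.snps[j] for j in order]
            self.dosages = self.dosages[:, order]

    # -- basic accessors ----------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def animal_ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": [s.snp_id for s in self.snps],
            "chromosome": [s.chromosome for s in self.snps],
            "position_bp": [s.position_bp for s in self.snps],
        })

    def autosomal_mask(self) -> np.ndarray:
        return np.array([s.chromosome not in NON_AUTOSOMES for s in self.snps])

    def chromosome_mask(self, chromosome: str) -> np.ndarray:
        return np.array([s.chromosome == str(chromosome) for s in self.snps])

    def subset(self, animal_idx: Sequence[int] | np.ndarray | None = None,
               snp_idx: Sequence[int] | np.ndarray | None = None) -> "GenotypeMatrix":
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        if ai.dtype == bool:
            ai = np.flatnonzero(ai)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        return GenotypeMatrix([self.animals[i] for i in ai],
                              [self.snps[j] for j in si],
                              self.dosages[np.ix_(ai, si)])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.animals), list(self.snps),
                              self.dosages.copy())


def _chrom_key(label: str):
    """Sort autosomes numerically, then X/Y/MT, then anything else."""
    try:
        return (0, int(label), "")
    except ValueError:
        order = {"X": 0, "XY": 1, "Y": 2, "MT": 3}
        return (1, order.get(label, 9), label)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_map(path) -> list[SnpRecord]:
    """PLINK .map: chromosome, snp_id, genetic position (ignored), bp."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            records.append(SnpRecord(snp_id=parts[1], chromosome=parts[0],
                                     position_bp=int(parts[3])))
    return records


_SEX_CODE = {"1": "male", "2": "female"}


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK-style text .ped/.map.

    Genotype columns may be allele pairs ("A B", "0 0" missing) or a single
    dosage per SNP (0/1/2, "NA"/"-9" missing). Dosage of an allele-pair file
    counts the second allele listed for that SNP (first-seen order).
    """
    snps = read_map(map_path)
    m = len(snps)
    animals: list[AnimalRecord] = []
    rows: list[np.ndarray] = []
    alleles: list[list[str]] = [[] for _ in range(m)]

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"{ped_path}:{ln}: fewer than 6 leading columns")
            fam, ind, _sire, _dam, sex, _phe = parts[:6]
            geno = parts[6:]
            if len(geno) == 2 * m:
                row = _decode_allele_pairs(geno, alleles, ped_path, ln)
            elif len(geno) == m:
                row = _decode_dosages(geno, ped_path, ln)
            else:
                raise ValueError(
                    f"{ped_path}:{ln}: {len(geno)} genotype fields for {m} "
                    f"mapped SNPs (expected {m} or {2 * m})")
            animals.append(AnimalRecord(animal_id=ind, flock_id=fam,
                                        recorded_sex=_SEX_CODE.get(sex, "unknown")))
            rows.append(row)
    snps = [replace(s, alleles=tuple(alleles[j]) if len(alleles[j]) == 2
                    else s.alleles) for j, s in enumerate(snps)]
    return GenotypeMatrix(animals, snps, np.array(rows))


def _decode_allele_pairs(geno, alleles, path, ln) -> np.ndarray:
    row = np.empty(len(geno) // 2)
    for j in range(len(row)):
        a, b = geno[2 * j], geno[2 * j + 1]
        if a == "0" or b == "0":
            row[j] = MISSING
            continue
        for al in (a, b):
            if al not in alleles[j]:
                if len(alleles[j]) == 2:
                    raise ValueError(f"{path}:{ln}: SNP {j} has >2 alleles")
                alleles[j].append(al)
        if len(alleles[j]) == 1:
            row[j] = 0.0          # may be re-polarised below if 2nd allele appears
        else:
            second = alleles[j][1]
            row[j] = float((a == second) + (b == second))
    return row


def _decode_dosages(geno, path, ln) -> np.ndarray:
    row = np.empty(len(geno))
    for j, g in enumerate(geno):
        if g in ("NA", "-9", "."):
            row[j] = MISSING
        elif g in ("0", "1", "2"):
            row[j] = float(g)
        else:
            row[j] = MISSING      # unrecognised call
    return row


def write_ped_map(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(ped_path, "w") as fh:
        for i, a in enumerate(matrix.animals):
            fields = [a.flock_id, a.animal_id, "0", "0",
                      sex_code.get(a.recorded_sex, "0"), "-9"]
            for j, s in enumerate(matrix.snps):
                d = matrix.dosages[i, j]
                a1, a2 = s.alleles
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1, a1]
                elif d == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


def read_genotype_table(path) -> GenotypeMatrix:
    """TSV dialect: header 'animal_id' + snp ids; first three data rows are
    reserved metadata rows '#chromosome' and '#position_bp' when present,
    otherwise SNPs get chromosome '1' and their column order as position."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    snp_ids = list(df.columns[1:])
    meta = {}
    body = df
    while len(body) and str(body.iloc[0, 0]).startswith("#"):
        meta[str(body.iloc[0, 0])[1:]] = list(body.iloc[0, 1:])
        body = body.iloc[1:]
    chroms = meta.get("chromosome", ["1"] * len(snp_ids))
    pos = meta.get("position_bp", [str(j) for j in range(len(snp_ids))])
    snps = [SnpRecord(snp_id=s, chromosome=c, position_bp=int(p))
            for s, c, p in zip(snp_ids, chroms, pos)]
    animals = [AnimalRecord(animal_id=a) for a in body.iloc[:, 0]]
    dos = body.iloc[:, 1:].replace("NA", np.nan).to_numpy(dtype=float)
    return GenotypeMatrix(animals, snps, dos)


def write_genotype_table(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(matrix.snp_ids) + "\n")
        fh.write("#chromosome\t" + "\t".join(s.chromosome for s in matrix.snps) + "\n")
        fh.write("#position_bp\t" + "\t".join(str(s.position_bp) for s in matrix.snps) + "\n")
        for i, a in enumerate(matrix.animals):
            vals = ["NA" if np.isnan(d) else str(int(d)) for d in matrix.dosages[i]]
            fh.write(a.animal_id + "\t" + "\t".join(vals) + "\n")


def read_breed_compositions(path) -> dict[str, dict[str, float]]:
    """TSV: animal_id + one column per breed label; values are proportions."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[str(row.iloc[0])] = {b: float(row[b]) for b in df.columns[1:]
                                 if float(row[b]) > 0}
    return out


def attach_breed_compositions(matrix: GenotypeMatrix,
                              compositions: Mapping[str, Mapping[str, float]]
                              ) -> GenotypeMatrix:
    animals = [replace(a, breed_composition=dict(compositions.get(a.animal_id, {})))
               for a in matrix.animals]
    return GenotypeMatrix(animals, matrix.snps, matrix.dosages)


# ---------------------------------------------------------------------------
# QC primitives
# ---------------------------------------------------------------------------

def call_rate(matrix: GenotypeMatrix, axis: str = "snp") -> np.ndarray:
    """Fraction of non-missing calls per SNP (axis='snp') or animal."""
    present = ~np.isnan(matrix.dosages)
    if axis == "snp":
        return present.mean(axis=0)
    if axis == "animal":
        return present.mean(axis=1)
    raise ValueError("axis must be 'snp' or 'animal'")


def allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Frequency of the counted (second) allele per SNP; NaN if no calls."""
    d = matrix.dosages
    with np.errstate(invalid="ignore"):
        return np.nansum(d, axis=0) / (2.0 * np.sum(~np.isnan(d), axis=0))


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    p = allele_frequency(matrix)
    return np.minimum(p, 1 - p)


def maf_spectrum(maf: np.ndarray,
                 bin_edges: Sequence[float] = (0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
                 ) -> pd.Series:
    """Percentage of SNPs per MAF bin.

    Bins are left-open/right-closed, ``lo < MAF <= hi``, except the first
    which also includes MAF == 0.
    """
    edges = np.asarray(bin_edges, dtype=float)
    maf = np.asarray(maf, dtype=float)
    maf = maf[~np.isnan(maf)]
    labels, counts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == edges[0]:
            mask = (maf >= lo) & (maf <= hi)
            labels.append(f"MAF <= {hi:g}")
        else:
            mask = (maf > lo) & (maf <= hi)
            labels.append(f"{lo:g} < MAF <= {hi:g}")
        counts.append(int(mask.sum()))
    total = max(sum(counts), 1)
    return pd.Series([100.0 * c / total for c in counts], index=labels)


def genotype_counts(matrix: GenotypeMatrix) -> np.ndarray:
    """(n_snps, 3) counts of dosage 0 / 1 / 2 per SNP."""
    d = matrix.dosages
    return np.stack([(d == k).sum(axis=0) for k in (0.0, 1.0, 2.0)], axis=1)


def hwe_test(counts: Sequence[int], method: str = "chisq") -> float:
    """Hardy-Weinberg p-value from genotype counts (n_AA, n_Aa, n_aa).

    method 'chisq': 1-df goodness-of-fit without continuity correction.
    method 'exact': conditional exact test (sum of heterozygote-count
    probabilities no larger than the observed one).
    """
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    if n == 0:
        return np.nan
    if method == "chisq":
        return float(_hwe_chisq_p(np.array([[n0, n1, n2]]))[0])
    if method == "exact":
        return _hwe_exact_p(n0, n1, n2)
    raise ValueError("method must be 'chisq' or 'exact'")


def _hwe_chisq_p(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2], axis=1)
        chi2 = np.where(exp > 0, (counts - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(axis=1)
    pval = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs fit HWE perfectly
    mono = (p == 0) | (p == 1)
    pval = np.where(mono, 1.0, pval)
    return np.where(n > 0, pval, np.nan)


def _hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test conditioning on allele counts."""
    n = n0 + n1 + n2
    na = n1 + 2 * n2           # minor or major; symmetric
    na = min(na, 2 * n - na)
    # heterozygote count parity is fixed by na
    hets = np.arange(na % 2, na + 1, 2)
    from scipy.special import gammaln
    nb = 2 * n - na

    def logprob(h):
        homa = (na - h) // 2
        homb = n - h - homa
        return (gammaln(n + 1) - gammaln(h + 1) - gammaln(homa + 1)
                - gammaln(homb + 1) + h * np.log(2)
                + gammaln(na + 1) + gammaln(nb + 1) - gammaln(2 * n + 1))

    lp = logprob(hets.astype(float))
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs_het = n1
    p_obs = probs[hets == obs_het][0] if (obs_het in hets) else 0.0
    return float(probs[probs <= p_obs + 1e-12].sum())


def hwe_pvalues(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorised chi-square HWE p-value per SNP."""
    return _hwe_chisq_p(genotype_counts(matrix))


def infer_sex(x_dosages: np.ndarray, het_threshold: float = 0.03) -> str:
    """Sex from X-chromosome heterozygosity: female iff the heterozygous
    fraction of non-missing X calls exceeds the threshold (strict)."""
    x = np.asarray(x_dosages, dtype=float)
    ok = ~np.isnan(x)
    if not ok.any():
        return "unknown"
    het = float((x[ok] == 1).mean())
    return "female" if het > het_threshold else "male"


def ibs_matrix(dosages: np.ndarray) -> np.ndarray:
    """Mean identity-by-state over pairwise-non-missing markers.

    IBS(i, j) = mean of (2 - |d_i - d_j|) / 2.
    """
    d = dosages
    present = ~np.isnan(d)
    dz = np.where(present, d, 0.0)
    pf = present.astype(float)
    n_shared = pf @ pf.T
    # sum |di - dj| over shared markers, expanded over dosage categories
    absdiff = np.zeros_like(n_shared)
    ind = {k: (dz == k) & present for k in (0.0, 1.0, 2.0)}
    for a in (0.0, 1.0, 2.0):
        for b in (0.0, 1.0, 2.0):
            w = abs(a - b)
            if w:
                absdiff += w * (ind[a].astype(float) @ ind[b].astype(float).T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (2.0 - absdiff / n_shared) / 2.0
    return np.where(n_shared > 0, ibs, np.nan)


def ibs_duplicates(matrix: GenotypeMatrix, threshold: float = 0.95,
                   n_markers: int = 2000, rng_seed: int = 0
                   ) -> tuple[list[tuple[str, str, float]], set[str]]:
    """Flag animal pairs with IBS >= threshold on a random autosomal subset.

    Returns the flagged pairs with their IBS and the removal set (from each
    pair the lower-call-rate member; ties broken toward the later animal_id).
    """
    auto = np.flatnonzero(matrix.autosomal_mask())
    rng = np.random.default_rng(rng_seed)
    if auto.size > n_markers:
        auto = np.sort(rng.choice(auto, size=n_markers, replace=False))
    sub = matrix.dosages[:, auto]
    ibs = ibs_matrix(sub)
    cr = call_rate(matrix, "animal")
    ids = matrix.animal_ids
    flagged, removed = [], set()
    n = matrix.n_animals
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(ibs[i, j]) or ibs[i, j] < threshold:
                continue
            flagged.append((ids[i], ids[j], float(ibs[i, j])))
            if cr[i] < cr[j]:
                removed.add(ids[i])
            elif cr[j] < cr[i]:
                removed.add(ids[j])
            else:
                removed.add(max(ids[i], ids[j]))
    return flagged, removed


# ---------------------------------------------------------------------------
# breed groups
# ---------------------------------------------------------------------------

def assign_breed_group(composition: Mapping[str, float]) -> str:
    """Breed-group label from breed proportions.

    Rules, evaluated in order: a pure group needs >= 0.75 of its breed;
    otherwise with RCP = Rom + Coop + Peren, RCP > 0.5 and Tex < 0.25 is
    CompRCP, RCP > 0.5 and Tex >= 0.25 is CompRCPT, 0.3 < RCP <= 0.5 is
    Comprcp2; anything else is unassigned.
    """
    for breed, p in composition.items():
        if p < 0:
            raise ValueError(f"negative proportion for {breed}")
    get = lambda b: float(composition.get(b, 0.0))
    for breed in PURE_BREEDS:
        if get(breed) >= 0.75:
            return breed
    rcp = get("Rom") + get("Coop") + get("Peren")
    tex = get("Tex")
    if rcp > 0.5:
        return "CompRCP" if tex < 0.25 else "CompRCPT"
    if 0.3 < rcp <= 0.5:
        return "Comprcp2"
    return "unassigned"


def breed_groups(matrix: GenotypeMatrix) -> np.ndarray:
    return np.array([assign_breed_group(a.breed_composition)
                     for a in matrix.animals])


# ---------------------------------------------------------------------------
# QC configuration / report / driver
# ---------------------------------------------------------------------------

@dataclass
class QcConfig:
    snp_call_rate_min: float = 0.95
    animal_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min_diversity: float = 0.0
    maf_min_ld: float = 0.05
    ibs_threshold: float = 0.95
    ibs_marker_count: int = 2000
    x_het_threshold: float = 0.03
    x_min_calls: int = 10                  # X calls needed for a sex call
    mode: str = "per_breed"                # per_breed | combined
    check_sex: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("snp_call_rate_min", "animal_call_rate_min", "hwe_p_min",
                     "maf_min_diversity", "maf_min_ld", "ibs_threshold",
                     "x_het_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mode not in ("per_breed", "combined"):
            raise ValueError(f"unknown QC mode {self.mode!r}")


@dataclass
class QcReport:
    snps_removed: dict[str, list[str]] = field(default_factory=dict)
    animals_removed: dict[str, list[str]] = field(default_factory=dict)
    counts_before: dict[str, int] = field(default_factory=dict)
    counts_after: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps_removed(self) -> int:
        return len({s for v in self.snps_removed.values() for s in v})

    @property
    def n_animals_removed(self) -> int:
        return len({a for v in self.animals_removed.values() for a in v})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"snps_removed": self.snps_removed,
                       "animals_removed": self.animals_removed,
                       "counts_before": self.counts_before,
                       "counts_after": self.counts_after}, fh, indent=2)

    def counts_table(self) -> pd.DataFrame:
        rows = []
        for what in ("snps", "animals"):
            rows.append({"item": what,
                         "before_qc": self.counts_before.get(what),
                         "after_qc": self.counts_after.get(what)})
        return pd.DataFrame(rows)


class EmptyResultError(RuntimeError):
    """All SNPs or all animals were removed by quality control."""


def apply_qc(matrix: GenotypeMatrix, config: QcConfig | None = None,
             groups: np.ndarray | Sequence[str] | None = None
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full QC cascade and return the filtered matrix plus report.

    Filter order: SNP call rate -> MAF > 0 -> HWE -> non-autosomal SNP
    removal -> animal call rate -> sex check -> IBS duplicates. In
    'combined' mode the HWE filter removes a SNP only when it fails within
    every breed group (groups required).
    """
    config = config or QcConfig()
    report = QcReport(counts_before={"snps": matrix.n_snps,
                                     "animals": matrix.n_animals})
    if groups is None:
        groups = breed_groups(matrix)
    groups = np.asarray(groups)

    snp_keep = np.ones(matrix.n_snps, dtype=bool)
    ids = np.array(matrix.snp_ids)

    # 1. SNP call rate
    cr = call_rate(matrix, "snp")
    bad = cr < config.snp_call_rate_min
    report.snps_removed["call_rate"] = list(ids[bad & snp_keep])
    snp_keep &= ~bad

    # 2. MAF > threshold (monomorphic removal at the default 0)
    maf = minor_allele_frequency(matrix)
    bad = ~(maf > config.maf_min_diversity)        # catches NaN (all-missing)
    # all-missing SNPs were already caught by call rate; still classify leftovers
    report.snps_removed["maf"] = list(ids[bad & snp_keep])
    snp_keep &= ~bad

    # 3. HWE — autosomal SNPs only (hemizygous males put X out of HWE
    # regardless of genotyping quality)
    autosomal = matrix.autosomal_mask()
    if config.mode == "combined":
        fail_all = np.ones(matrix.n_snps, dtype=bool)
        seen_any = False
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            if idx.size == 0 or g == "unassigned":
                continue
            seen_any = True
            pv = _hwe_chisq_p(genotype_counts(matrix.subset(animal_idx=idx)))
            fail_all &= (pv <= config.hwe_p_min)
        bad = fail_all if seen_any else np.zeros(matrix.n_snps, dtype=bool)
    else:
        pv = hwe_pvalues(matrix)
        bad = pv <= config.hwe_p_min
    bad &= autosomal
    report.snps_removed["hwe"] = list(ids[bad & snp_keep])
    snp_keep &= ~bad

    # 3b. sex check before discarding X SNPs
    animal_keep = np.ones(matrix.n_animals, dtype=bool)
    aids = np.array(matrix.animal_ids)
    if config.check_sex:
        x_idx = np.flatnonzero(matrix.chromosome_mask("X"))
        mismatched = []
        if x_idx.size:
            for i, a in enumerate(matrix.animals):
                if a.recorded_sex not in ("male", "female"):
                    continue
                x = matrix.dosages[i, x_idx]
                if np.sum(~np.isnan(x)) < config.x_min_calls:
                    continue               # too little X data for a call
                inferred = infer_sex(x, config.x_het_threshold)
                if inferred != "unknown" and inferred != a.recorded_sex:
                    mismatched.append(a.animal_id)
        report.animals_removed["sex_mismatch"] = mismatched
        animal_keep &= ~np.isin(aids, mismatched)

    # 4. non-autosomal SNPs out (downstream stages are autosomal)
    non_auto = ~matrix.autosomal_mask()
    report.snps_removed["non_autosomal"] = list(ids[non_auto & snp_keep])
    snp_keep &= ~non_auto

    stage1 = matrix.subset(snp_idx=snp_keep)

    # 5. animal call rate (<= threshold removed, per the quoted rule)
    acr = call_rate(stage1, "animal")
    bad = acr <= config.animal_call_rate_min
    report.animals_removed["call_rate"] = list(aids[bad & animal_keep])
    animal_keep &= ~bad

    # 6. IBS duplicates among surviving animals
    surv = stage1.subset(animal_idx=animal_keep)
    if surv.n_animals >= 2:
        _, removed = ibs_duplicates(surv, config.ibs_threshold,
                                    config.ibs_marker_count, config.rng_seed)
    else:
        removed = set()
    report.animals_removed["ibs_duplicate"] = sorted(removed)
    animal_keep &= ~np.isin(aids, list(removed))

    out = stage1.subset(animal_idx=animal_keep)
    if out.n_snps == 0 or out.n_animals == 0:
        raise EmptyResultError("quality control removed every SNP or animal")
    report.counts_after = {"snps": out.n_snps, "animals": out.n_animals}
    return out, report


def ld_snp_filter(matrix: GenotypeMatrix, maf_min: float = 0.05
                  ) -> GenotypeMatrix:
    """The stricter MAF filter applied only to the LD stage's input
    (SNPs with MAF lower than the threshold are removed; MAF == threshold
    is retained)."""
    maf = minor_allele_frequency(matrix)
    return matrix.subset(snp_idx=~(maf < maf_min))
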