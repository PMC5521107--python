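"""End-to-end orchestration: qc -> diversity -> map -> ld -> ne -> compare.

A YAML run configuration names the input files and parameters; each stage
writes its outputs under the run directory and is skipped on re-run when
they already exist (resume from intermediates). A JSON manifest with the
config echo, package version, stage status and output checksums is
written even when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import diversity as div
from . import genotype_data as gd
from . import genetic_map as gm
from . import ld_decay as ld
from . import ne_history as ne

log = logging.getLogger("ldne")

STAGES = ("qc", "diversity", "map", "ld", "ne", "compare")

_KNOWN_KEYS = {
    "ped", "map", "genotype_table", "breed_file", "linkage_map", "outdir",
    "seed", "methods", "mode", "qc", "ld", "ne", "bootstrap",
    "m1_ratio",
}


@dataclass
class RunConfig:
    ped: str | None = None
    map: str | None = None
    genotype_table: str | None = None
    breed_file: str | None = None
    linkage_map: str | None = None
    outdir: str = "ldne_run"
    seed: int = 0
    methods: list[str] = field(default_factory=lambda: ["M1", "M2", "M3"])
    mode: str = "combined"
    m1_ratio: float = 1.0
    qc: dict = field(default_factory=dict)
    ld: dict = field(default_factory=dict)
    ne: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.genotype_table is None and (self.ped is None or self.map is None):
            raise ValueError("config must name either genotype_table or "
                             "both ped and map")
        bad = [m for m in self.methods if m not in ("M1", "M2", "M3")]
        if bad:
            raise ValueError(f"unknown map methods: {bad}")
        if self.linkage_map is None and set(self.methods) & {"M2", "M3"}:
            raise ValueError("M2/M3 require a linkage_map")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    offsets = {s: 1000 * (i + 1) for i, s in enumerate(STAGES)}
    return (seed + offsets[stage]) % (2 ** 31)


def run_all(config: RunConfig, stages: list[str] | None = None,
            force: bool = False) -> dict:
    """Execute the requested stages in pipeline order; returns the
    manifest dict (also written to outdir/manifest.json)."""
    config.validate()
    stages = list(STAGES) if stages is None else stages
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: v for k, v in config.__dict__.items()},
                "version": __version__, "stages": {}, "outputs": {}}

    def record(stage, status, files=()):
        manifest["stages"][stage] = status
        for f in files:
            f = Path(f)
            if f.exists():
                manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            runner = globals()[f"_stage_{stage}"]
            files = runner(config, out, force)
            record(stage, "done" if files is not None else "skipped",
                   files or ())
    except Exception:
        record(stage, "failed")
        raise
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_raw(config: RunConfig) -> gd.GenotypeMatrix:
    if config.genotype_table:
        m = gd.read_genotype_table(config.genotype_table)
    else:
        m = gd.read_ped_map(config.ped, config.map)
    if config.breed_file:
        comps = gd.read_breed_compositions(config.breed_file)
        m = gd.attach_breed_compositions(m, comps)
    return m


def _load_filtered(config: RunConfig, out: Path) -> gd.GenotypeMatrix:
    path = out / "qc" / "filtered_genotypes.tsv"
    if not path.exists():
        raise FileNotFoundError("run the qc stage first")
    m = gd.read_genotype_table(path)
    if config.breed_file:
        m = gd.attach_breed_compositions(
            m, gd.read_breed_compositions(config.breed_file))
    return m


def _stage_qc(config: RunConfig, out: Path, force: bool):
    d = out / "qc"
    target = d / "filtered_genotypes.tsv"
    if target.exists() and not force:
        log.info("qc: outputs exist, skipping")
        return None
    d.mkdir(exist_ok=True)
    raw = _load_raw(config)
    qc_cfg = gd.QcConfig(mode=config.mode,
                         rng_seed=_stage_seed(config.seed, "qc"),
                         **config.qc)
    filtered, report = gd.apply_qc(raw, qc_cfg)
    gd.write_genotype_table(filtered, target)
    report.to_json(d / "qc_report.json")
    report.counts_table().to_csv(d / "qc_counts.tsv", sep="\t", index=False)
    log.info("qc: %d/%d SNPs, %d/%d animals retained",
             filtered.n_snps, raw.n_snps, filtered.n_animals, raw.n_animals)
    return [target, d / "qc_report.json", d / "qc_counts.tsv"]


def _stage_diversity(config: RunConfig, out: Path, force: bool):
    d = out / "diversity"
    target = d / "grm.tsv"
    if target.exists() and not force:
        return None
    d.mkdir(exist_ok=True)
    m = _load_filtered(config, out)
    groups = gd.breed_groups(m)
    grm = div.compute_grm(m, "pooled")
    grm.to_tsv(target)
    summary = div.diversity_summary(m, grm, groups)
    summary.to_csv(d / "diversity_summary.tsv", sep="\t")
    dist = div.distance_matrix(grm)
    mds = div.classical_mds(dist, k=min(2, m.n_animals - 1))
    mds.to_tsv(d / "mds.tsv")
    outliers = sorted(div.flag_outliers(dist, groups))
    (d / "outliers.txt").write_text("\n".join(outliers) + "\n" if outliers
                                    else "")
    spectrum = gd.maf_spectrum(gd.minor_allele_frequency(m))
    spectrum.to_csv(d / "maf_spectrum.tsv", sep="\t",
                    header=["percent"])
    return [target, d / "diversity_summary.tsv", d / "mds.tsv",
            d / "maf_spectrum.tsv"]


def _dense_map_path(out: Path, method: str) -> Path:
    return out / "map" / f"dense_map_{method}.tsv"


def _stage_map(config: RunConfig, out: Path, force: bool):
    d = out / "map"
    done = [_dense_map_path(out, m) for m in config.methods]
    if all(p.exists() for p in done) and not force:
        return None
    d.mkdir(exist_ok=True)
    matrix = _load_filtered(config, out)
    snps = matrix.snp_table()
    linkage = (gm.LinkageMap.from_tsv(config.linkage_map)
               if config.linkage_map else None)
    files = []
    lengths = {str(c): g["position_bp"].max() / 1e6
               for c, g in snps.groupby("chromosome")}
    for method in config.methods:
        if method == "M1":
            dense = gm.m1_positions(snps, config.m1_ratio)
        elif method == "M2":
            ratios = gm.chromosome_ratios(linkage, lengths)
            dense = gm.m2_positions(snps, ratios)
        else:
            dense = gm.m3_positions(linkage, snps)
        dense.method = method
        path = _dense_map_path(out, method)
        dense.to_tsv(path)
        files.append(path)
        gm.write_ucsc_track(gm.dense_map_track(dense),
                            d / f"track_map_{method}.txt",
                            f"genetic_map_{method}", "value")
        profile = gm.recombination_profile(dense)
        gm.write_ucsc_track(profile, d / f"track_rate_{method}.txt",
                            f"recombination_rate_{method}",
                            "rate_cm_per_mb")
    if linkage is not None:
        dense_ref = gm.DenseGeneticMap.from_tsv(files[-1], config.methods[-1])
        table, corr, pval = gm.map_summary(linkage, dense_ref)
        table.to_csv(d / "map_summary.tsv", sep="\t", index=False)
        (d / "map_correlation.json").write_text(
            json.dumps({"pearson_r": corr, "p_value": pval}))
        files.append(d / "map_summary.tsv")
    return files


def _stage_ld(config: RunConfig, out: Path, force: bool):
    d = out / "ld"
    done = [d / f"decay_{m}.tsv" for m in config.methods]
    if all(p.exists() for p in done) and not force:
        return None
    d.mkdir(exist_ok=True)
    matrix = _load_filtered(config, out)
    matrix = gd.ld_snp_filter(matrix, config.qc.get("maf_min_ld", 0.05))
    params = {"n_pairs": 20000, "n_reps": 30, "span": 0.05,
              "grid_points": ld.GRID_POINTS, "grid_min": ld.GRID_MIN_CM,
              "grid_max": ld.GRID_MAX_CM, "min_pairs": 50}
    params.update(config.ld)
    grid = ld.default_grid(params["grid_points"], params["grid_min"],
                           params["grid_max"])
    files = []
    for method in config.methods:
        dense = gm.DenseGeneticMap.from_tsv(_dense_map_path(out, method),
                                            method)
        lgrid = ld.ld_grid_for_matrix(
            matrix, dense, grid, n_pairs=params["n_pairs"],
            n_reps=params["n_reps"], span=params["span"],
            min_pairs=params["min_pairs"],
            rng_seed=_stage_seed(config.seed, "ld"))
        lgrid.to_tsv(d / f"ld_grid_{method}.tsv")
        np.savez(d / f"ld_replicates_{method}.npz",
                 grid_cm=lgrid.grid_cm,
                 **{c: lgrid.replicates[c] for c in lgrid.chromosomes})
        curve = ld.combine_chromosomes(lgrid)
        curve.to_tsv(d / f"decay_{method}.tsv")
        files += [d / f"ld_grid_{method}.tsv", d / f"decay_{method}.tsv"]
    return files


def _load_ld_grid(out: Path, method: str) -> ld.LdGrid:
    import pandas as pd
    table = pd.read_csv(out / "ld" / f"ld_grid_{method}.tsv", sep="\t")
    grid = ld.LdGrid(method, table["grid_cm"].to_numpy())
    with np.load(out / "ld" / f"ld_replicates_{method}.npz") as z:
        for c in z.files:
            if c == "grid_cm":
                continue
            grid.replicates[c] = z[c]
    for col in table.columns:
        if col.startswith("mean_r2_"):
            c = col[len("mean_r2_"):]
            grid.mean_r2[c] = table[col].to_numpy()
            grid.var_r2[c] = table[f"var_r2_{c}"].to_numpy()
    grid.n_replicates = next(iter(grid.replicates.values())).shape[0] \
        if grid.replicates else 0
    return grid


def _stage_ne(config: RunConfig, out: Path, force: bool):
    d = out / "ne"
    done = [d / f"ne_curve_{m}.tsv" for m in config.methods]
    if all(p.exists() for p in done) and not force:
        return None
    d.mkdir(exist_ok=True)
    files = []
    targets = tuple(config.ne.get("targets", (1, 5, 20, 50, 100)))
    rows = []
    for method in config.methods:
        grid = _load_ld_grid(out, method)
        curve = ne.ne_curve(grid, config.ne.get("sample_n"))
        curve.to_tsv(d / f"ne_curve_{method}.tsv")
        files.append(d / f"ne_curve_{method}.tsv")
        try:
            series = ne.extract_at_generations(curve, targets)
            series["method"] = method
            rows.append(series)
        except ValueError:
            log.warning("ne: target generations outside grid for %s", method)
    if rows:
        import pandas as pd
        pd.DataFrame(rows).to_csv(d / "ne_at_generations.tsv", sep="\t",
                                  index=False)
        files.append(d / "ne_at_generations.tsv")
    return files


def _stage_compare(config: RunConfig, out: Path, force: bool):
    if len(config.methods) < 2:
        raise ValueError("compare requires at least two map methods in the "
                         "config (got: %s)" % config.methods)
    d = out / "compare"
    d.mkdir(exist_ok=True)
    files = []
    n_boot = config.bootstrap.get("n_boot", 1000)
    curves = {}
    for method in config.methods:
        grid = _load_ld_grid(out, method)
        curves[method] = ne.ne_curve(grid, config.ne.get("sample_n"))
    seed = _stage_seed(config.seed, "compare")
    for i, a in enumerate(config.methods):
        for b in config.methods[i + 1:]:
            table = ne.compare_methods(curves[a], curves[b], n_boot=n_boot,
                                       rng_seed=seed)
            path = d / f"compare_{a}_vs_{b}.tsv"
            table.to_csv(path, sep="\t", index=False)
            files.append(path)
    return files
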