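"""Pipeline orchestration: staged artifacts with manifests.

Each stage reads the artifacts of its upstream stage from the run directory,
computes, writes CSV/VCF/NPZ artifacts plus a JSON manifest (parameters,
seeds, input/output checksums) sufficient for exact re-execution, and
returns its main in-memory products.  The CLI is a thin wrapper over these
functions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demo
from .barriers import DEFAULT_THETA_GRID, barrier_strengths, cluster_connectivity
from .connectivity import ConnectivityMatrix, log_transform, multigen, site_connectivity, symmetrize
from .genotypes import DemographyConfig, serial_founder_schedule, simulate_genotypes
from .grid import SeascapeGrid
from .popgen import PairwiseStatMatrix, diversity, genic_test, metric_mds, pairwise_fst
from .seastats import env_regression, ibd_regression, mantel, region_boxplot_table
from .tracking import ReleaseSchedule, ensemble_to_connectivity, run_dispersal
from .vcfio import read_site_table, write_site_table, write_vcf
from .velocity import VelocityField


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; message names the producing stage."""


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    seed: int = 42
    output_dir: str = "runs/demo"
    grid: dict = field(default_factory=lambda: {
        "nx": demo.DEMO_NX, "ny": demo.DEMO_NY, "cell_size_km": demo.DEMO_CELL_KM})
    schedule: dict = field(default_factory=lambda: {
        "particles_per_cell": 20, "pld_days": 5.0, "dt_s": 3600.0})
    analysis: dict = field(default_factory=lambda: {
        "generations": 64, "symmetrization": "mean",
        "theta_grid": list(DEFAULT_THETA_GRID), "n_perm": 999, "mds_axes": 2,
        "flagged_region": "SBO", "genic": "none"})
    demography: dict = field(default_factory=lambda: {
        "deme_size": 500, "migration_rate": 0.02, "n_loci": 1000,
        "n_generations": 140, "n_sample_per_site": 20, "missing_rate": 0.0})
    founder: dict = field(default_factory=lambda: {
        "enabled": True, "founder_size": 8, "interval": 4, "start_generation": 1})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                unknown = set(value) - set(current)
                if unknown:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        """Per-stage child seed derived from the global seed (< 2^31)."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name}: run the '{producer}' subcommand first")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_seascape(cfg: RunConfig) -> tuple[SeascapeGrid, VelocityField, pd.DataFrame, dict]:
    """Build the demo seascape, velocity field and site table; write artifacts."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = demo.build_demo_grid(**cfg.grid)
    field_seed = cfg.stage_seed("seascape")
    vel = demo.build_demo_field(grid, seed=field_seed)
    sites, site_cells = demo.demo_site_table(grid)

    np.savez(
        outdir / "seascape.npz",
        land_mask=grid.land_mask, depth_m=grid.depth_m,
        habitat_mask=grid.habitat_mask,
        salinity_psu=grid.salinity_psu, temperature_C=grid.temperature_C,
        u=vel.u, v=vel.v,
        cell_size_km=grid.cell_size_km,
        habitat_depth_limit_m=grid.habitat_depth_limit_m,
    )
    write_site_table(sites, outdir / "sites.csv")
    (outdir / "site_cells.json").write_text(json.dumps(site_cells))
    _write_manifest(outdir, "seascape", {**cfg.grid, "field_seed": field_seed},
                    [], [outdir / "seascape.npz", outdir / "sites.csv"])
    return grid, vel, sites, site_cells


def _load_seascape(outdir: Path) -> tuple[SeascapeGrid, VelocityField]:
    path = _require(outdir / "seascape.npz", "simulate-seascape")
    z = np.load(path)
    land = z["land_mask"]
    grid = SeascapeGrid(
        nx=land.shape[1], ny=land.shape[0],
        cell_size_km=float(z["cell_size_km"]),
        land_mask=land, depth_m=z["depth_m"], habitat_mask=z["habitat_mask"],
        habitat_depth_limit_m=float(z["habitat_depth_limit_m"]),
        salinity_psu=z["salinity_psu"], temperature_C=z["temperature_C"],
    )
    vel = VelocityField(u=z["u"], v=z["v"], cell_size_km=grid.cell_size_km)
    return grid, vel


def _load_sites(outdir: Path) -> tuple[pd.DataFrame, dict]:
    sites = read_site_table(_require(outdir / "sites.csv", "simulate-seascape"))
    site_cells = json.loads(_require(outdir / "site_cells.json", "simulate-seascape").read_text())
    return sites, site_cells


def stage_track(cfg: RunConfig) -> ConnectivityMatrix:
    """Release and advect particles; write ensemble + cell connectivity."""
    outdir = Path(cfg.output_dir)
    grid, vel = _load_seascape(outdir)
    schedule = ReleaseSchedule(**cfg.schedule)
    seed = cfg.stage_seed("track")
    ensemble = run_dispersal(grid, vel, schedule, seed=seed)
    conn = ensemble_to_connectivity(ensemble, grid)
    ensemble.table.to_csv(outdir / "ensemble.csv", index=False)
    conn.to_csv(outdir / "conn_cells.csv")
    _write_manifest(outdir, "track", {**cfg.schedule, "seed": seed},
                    [outdir / "seascape.npz"],
                    [outdir / "ensemble.csv", outdir / "conn_cells.csv"])
    return conn


def stage_connect(cfg: RunConfig) -> dict[str, ConnectivityMatrix]:
    """Multigeneration accumulation, site aggregation, symmetrization, log."""
    outdir = Path(cfg.output_dir)
    conn = ConnectivityMatrix.from_csv(_require(outdir / "conn_cells.csv", "track"))
    sites, site_cells = _load_sites(outdir)
    G = int(cfg.analysis["generations"])
    mode = cfg.analysis["symmetrization"]

    result = multigen(conn, G)
    sites_gen1 = site_connectivity(conn, site_cells)
    sites_multi = site_connectivity(result.capped, site_cells)
    sites_sym = symmetrize(sites_multi, mode=mode)
    sites_log = log_transform(sites_sym)

    artifacts = {
        "conn_multigen_raw": result.raw,
        "conn_multigen_capped": result.capped,
        "conn_sites_gen1": sites_gen1,
        "conn_sites_multigen": sites_multi,
        "conn_sites_sym": sites_sym,
        "conn_sites_log": sites_log,
    }
    for name, M in artifacts.items():
        M.to_csv(outdir / f"{name}.csv")
    _write_manifest(outdir, "connect", {"generations": G, "symmetrization": mode},
                    [outdir / "conn_cells.csv"],
                    [outdir / f"{n}.csv" for n in artifacts])
    return artifacts


def stage_cluster(cfg: RunConfig) -> dict[float, object]:
    """Barrier clustering of the symmetrized dispersal matrix over the θ grid."""
    outdir = Path(cfg.output_dir)
    conn = ConnectivityMatrix.from_csv(_require(outdir / "conn_cells.csv", "track"))
    sym = symmetrize(conn, mode=cfg.analysis["symmetrization"])
    outputs = []
    assignments = {}
    for theta in cfg.analysis["theta_grid"]:
        assignment = cluster_connectivity(sym, theta)
        strengths = barrier_strengths(sym, assignment)
        tag = f"{theta:g}".replace(".", "p")
        a_path = outdir / f"clusters_theta_{tag}.csv"
        s_path = outdir / f"barrier_strengths_theta_{tag}.csv"
        assignment.to_frame().to_csv(a_path, index=False)
        strengths.to_csv(s_path, index=False)
        outputs += [a_path, s_path]
        assignments[float(theta)] = assignment
    summary = pd.DataFrame({
        "theta": list(assignments),
        "n_clusters": [a.n_clusters for a in assignments.values()],
    })
    summary.to_csv(outdir / "cluster_summary.csv", index=False)
    _write_manifest(outdir, "cluster",
                    {"theta_grid": list(cfg.analysis["theta_grid"]),
                     "symmetrization": cfg.analysis["symmetrization"]},
                    [outdir / "conn_cells.csv"], outputs + [outdir / "cluster_summary.csv"])
    return assignments


def stage_genetics(cfg: RunConfig) -> dict:
    """Simulate genotypes on the site connectivity and compute statistics."""
    outdir = Path(cfg.output_dir)
    sites, _ = _load_sites(outdir)
    conn_sites = ConnectivityMatrix.from_csv(
        _require(outdir / "conn_sites_gen1.csv", "connect"))
    seed = cfg.stage_seed("genetics")

    founder_schedule = None
    if cfg.founder.get("enabled"):
        founder_schedule = serial_founder_schedule(
            demo.colonization_order(sites),
            interval=int(cfg.founder["interval"]),
            founder_size=int(cfg.founder["founder_size"]),
            start_generation=int(cfg.founder["start_generation"]),
        )
    demo_cfg = DemographyConfig(
        deme_size=int(cfg.demography["deme_size"]),
        migration_rate=float(cfg.demography["migration_rate"]),
        n_loci=int(cfg.demography["n_loci"]),
        n_generations=int(cfg.demography["n_generations"]),
        n_sample_per_site=int(cfg.demography["n_sample_per_site"]),
        missing_rate=float(cfg.demography["missing_rate"]),
        founder_schedule=founder_schedule,
        seed=seed,
    )
    dataset = simulate_genotypes(conn_sites, demo_cfg, sites)
    write_vcf(dataset, outdir / "genotypes.vcf")

    div = diversity(dataset)
    div.to_csv(outdir / "diversity.csv")
    fst = pairwise_fst(dataset)
    fst.to_frame().to_csv(outdir / "fst.csv", index_label="site_id")
    coords, varexp = metric_mds(fst, k_axes=int(cfg.analysis["mds_axes"]))
    mds = pd.DataFrame(coords, index=fst.ids,
                       columns=[f"axis{k + 1}" for k in range(coords.shape[1])])
    mds.to_csv(outdir / "mds_coords.csv", index_label="site_id")
    pd.DataFrame({"axis": np.arange(1, len(varexp) + 1),
                  "variance_explained": varexp}).to_csv(
        outdir / "mds_variance.csv", index=False)

    outputs = [outdir / p for p in
               ("genotypes.vcf", "diversity.csv", "fst.csv",
                "mds_coords.csv", "mds_variance.csv")]
    if cfg.analysis.get("genic") == "all":
        rows = []
        ids = dataset.site_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                _, p = genic_test(dataset, ids[i], ids[j])
                rows.append({"site_a": ids[i], "site_b": ids[j], "combined_p": p})
        pd.DataFrame(rows).to_csv(outdir / "genic_tests.csv", index=False)
        outputs.append(outdir / "genic_tests.csv")
    _write_manifest(outdir, "genetics",
                    {**cfg.demography, "founder": cfg.founder, "seed": seed},
                    [outdir / "conn_sites_gen1.csv", outdir / "sites.csv"], outputs)
    return {"dataset": dataset, "diversity": div, "fst": fst,
            "mds": (coords, varexp)}


def stage_compare(cfg: RunConfig) -> dict:
    """Mantel, IBD and environment regressions; regional FST summaries."""
    outdir = Path(cfg.output_dir)
    sites, _ = _load_sites(outdir)
    fst_df = pd.read_csv(_require(outdir / "fst.csv", "genetics"), index_col=0)
    fst = PairwiseStatMatrix(values=fst_df.to_numpy(), ids=list(fst_df.columns),
                             statistic="fst_wc")
    conn_sym = ConnectivityMatrix.from_csv(_require(outdir / "conn_sites_sym.csv", "connect"))
    conn_log = ConnectivityMatrix.from_csv(_require(outdir / "conn_sites_log.csv", "connect"))
    div = pd.read_csv(_require(outdir / "diversity.csv", "genetics"), index_col=0)
    order = fst.ids
    sym_vals = pd.DataFrame(conn_sym.values, index=conn_sym.node_ids,
                            columns=conn_sym.node_ids).loc[order, order].to_numpy()
    log_vals = pd.DataFrame(conn_log.values, index=conn_log.node_ids,
                            columns=conn_log.node_ids).loc[order, order].to_numpy()

    n_perm = int(cfg.analysis["n_perm"])
    seed = cfg.stage_seed("compare")
    mantel_raw = mantel(fst.values, sym_vals, n_perm=n_perm, seed=seed)
    mantel_log = mantel(fst.values, log_vals, n_perm=n_perm, seed=seed + 1)

    flagged_region = cfg.analysis.get("flagged_region")
    flagged = [s for s in order if sites.loc[s, "region"] == flagged_region]
    ibd = ibd_regression(fst, log_vals, flagged_sites=flagged)

    env = demo.demo_env_covariates(sites.loc[order])
    reg = env_regression(div.loc[order], env)

    regions = sites["region"]
    region_table = region_boxplot_table(fst, regions)
    region_table.to_csv(outdir / "region_fst.csv", index=False)

    report = {
        "mantel_untransformed": {"r": mantel_raw.r, "p": mantel_raw.p,
                                 "n_perm": mantel_raw.n_perm},
        "mantel_log": {"r": mantel_log.r, "p": mantel_log.p,
                       "n_perm": mantel_log.n_perm},
        "ibd": {
            name: (None if fit is None else
                   {"slope": float(fit.params["log_connectivity"]),
                    "intercept": float(fit.params["const"]),
                    "r_squared": fit.r_squared, "n_pairs": fit.meta["n_pairs"]})
            for name, fit in ibd.items()
        },
        "env_regression": {
            "r_squared": reg.r_squared,
            "coefficients": {k: float(v) for k, v in reg.params.items()},
            "anova_p": {k: float(v) for k, v in reg.anova["PR(>F)"].dropna().items()},
            "vif": {k: float(v) for k, v in reg.vif.items()},
            "dropped_predictors": reg.dropped,
        },
        "seed": seed,
        "n_perm": n_perm,
    }
    (outdir / "compare_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(outdir, "compare", {"n_perm": n_perm, "seed": seed,
                                        "flagged_region": flagged_region},
                    [outdir / "fst.csv", outdir / "conn_sites_log.csv"],
                    [outdir / "compare_report.json", outdir / "region_fst.csv"])
    return report


STAGES = ("seascape", "track", "connect", "cluster", "genetics", "compare")


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order; returns the comparison report."""
    stage_seascape(cfg)
    stage_track(cfg)
    stage_connect(cfg)
    stage_cluster(cfg)
    stage_genetics(cfg)
    return stage_compare(cfg)
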