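"""End-to-end orchestration: simulate/load, classify, cluster, score, admix.

A run is driven by one :class:`PipelineConfig` (optionally loaded from a
YAML file).  Stages execute in dependency order — matrix loading or
simulation, band classification, distance/tree/PCoA, hybrid index, and
admixture — each writing its artifacts into the output directory, and a
RunReport collects every stage summary in both machine-readable (JSON)
and human-readable (text) form with identical numbers.  One global seed
deterministically derives a per-stage seed (hash of seed + stage name),
so adding stages never shifts the random streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._seeds import derive_seed
from .admixture import AdmixtureConfig, evanno_deltaK, run_admixture
from .distance import (bootstrap_support, distance_matrix, pcoa,
                       write_distances_delimited, write_newick, write_phylip)
from .errors import ConfigError, HybridDetectError
from .hybrid_index import (ClassThresholds, DiagnosticMarkerSet, hybrid_index_table,
                           marker_report, write_report)
from .io_matrix import classify_bands, novel_bands, read_matrix, write_matrix, write_meta
from .synthetic_data import SimConfig, simulate_marker_dataset

log = logging.getLogger(__name__)

ALL_STAGES = ("classify", "distance", "tree", "pcoa", "hybrid_index", "admixture")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "hybriddetect_run"
    seed: int = 0
    matrix_path: str | None = None
    meta_path: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)           # SimConfig overrides
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    tree_method: str = "nj"
    bootstrap_reps: int = 100
    pcoa_axes: int = 2
    diagnostic_tolerance: int = 0
    thresholds: dict = field(default_factory=dict)    # ClassThresholds overrides
    admixture_K: tuple[int, int] = (1, 5)
    admixture_reps: int = 10
    admixture_burnin: int = 2000
    admixture_iters: int = 10000
    admixture_alpha: float = 1.0

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        lo, hi = self.admixture_K
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad admixture K range {lo}:{hi}")
        if self.tree_method not in ("nj", "upgma"):
            raise ConfigError(f"tree_method must be nj or upgma, got {self.tree_method!r}")
        if not self.simulate and self.matrix_path is None:
            raise ConfigError("either simulate: true or matrix_path must be given")
        # constructing these validates their own fields
        self.sim_config = SimConfig(**{"seed": derive_seed(self.seed, "simulate"), **self.sim})
        self.class_thresholds = ClassThresholds(**self.thresholds)


def validate_config(path) -> PipelineConfig:
    """Load and normalise a YAML pipeline configuration.

    Unknown keys are rejected with their key path; all defaults are
    filled in so the echoed configuration is complete.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "admixture_K" in raw and isinstance(raw["admixture_K"], str):
        try:
            lo, hi = map(int, raw["admixture_K"].split(":"))
        except ValueError:
            raise ConfigError(
                f"admixture_K: expected 'lo:hi', got {raw['admixture_K']!r}"
            ) from None
        raw["admixture_K"] = (lo, hi)
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("sim_config", None)
    d.pop("class_thresholds", None)
    d["sim_defaults"] = dataclasses.asdict(config.sim_config)
    d["threshold_defaults"] = dataclasses.asdict(config.class_thresholds)
    return d


def _report_text(report: dict) -> str:
    lines = [f"hybriddetect run report (version {report['version']})", ""]

    def walk(obj, indent=0):
        pad = "  " * indent
        if isinstance(obj, dict):
            for k, v in obj.items():
                if isinstance(v, (dict, list)):
                    lines.append(f"{pad}{k}:")
                    walk(v, indent + 1)
                else:
                    lines.append(f"{pad}{k}: {v}")
        elif isinstance(obj, list):
            for v in obj:
                walk(v, indent)
        else:
            lines.append(f"{pad}{obj}")

    walk(report["stages"])
    if report["warnings"]:
        lines.append("")
        lines.append("warnings:")
        for w in report["warnings"]:
            lines.append(f"  - {w}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the RunReport dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hybriddetect")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {
        "version": __version__,
        "config": config_echo(config),
        "stages": {},
        "warnings": [],
    }
    try:
        if config.simulate:
            matrix, meta, truth = simulate_marker_dataset(config.sim_config)
            write_matrix(matrix, out / "matrix.csv")
            write_meta(meta, out / "meta.csv")
            with open(out / "truth.csv", "w", encoding="utf-8", newline="\n") as fh:
                fh.write("specimen_id,true_class,fraction_A\n")
                for sid in matrix.specimen_ids:
                    fh.write(f"{sid},{truth.true_class[sid]},{truth.fraction_A[sid]}\n")
            report["stages"]["simulate"] = {
                "n_specimens": matrix.n_specimens,
                "n_loci": matrix.n_loci,
                "classes": {
                    k: list(truth.true_class.values()).count(k)
                    for k in sorted(set(truth.true_class.values()))
                },
            }
        else:
            matrix, meta = read_matrix(config.matrix_path, config.meta_path)

        bc = None
        if "classify" in config.stages:
            bc = classify_bands(matrix, meta, diagnostic_tolerance=config.diagnostic_tolerance)
            bc.to_json(out / "band_classification.json")
            nb = novel_bands(matrix, meta)
            report["stages"]["classify"] = {**bc.counts, "novel_bands": len(nb)}

        dm = None
        if {"distance", "tree", "pcoa"} & set(config.stages):
            dm = distance_matrix(matrix)
        if "distance" in config.stages:
            write_phylip(dm, out / "distances.phy")
            write_distances_delimited(dm, out / "distances.csv")
            report["stages"]["distance"] = {
                "n_specimens": len(dm.ids),
                "min_distance": float(dm.data[dm.data > 0].min()) if (dm.data > 0).any() else 0.0,
                "max_distance": float(dm.data.max()),
            }
        if "tree" in config.stages:
            tree = bootstrap_support(
                matrix,
                method=config.tree_method,
                n_reps=config.bootstrap_reps,
                seed=derive_seed(config.seed, "bootstrap"),
            )
            write_newick(tree, out / f"tree_{config.tree_method}.nwk")
            report["stages"]["tree"] = {
                "method": config.tree_method,
                "bootstrap_reps": config.bootstrap_reps,
                "file": f"tree_{config.tree_method}.nwk",
            }
        if "pcoa" in config.stages:
            emb = pcoa(dm, n_axes=config.pcoa_axes)
            with open(out / "pcoa.csv", "w", encoding="utf-8", newline="\n") as fh:
                axes = [f"axis_{i + 1}" for i in range(emb.coordinates.shape[1])]
                fh.write("specimen_id," + ",".join(axes) + "\n")
                for sid, row in zip(emb.specimen_ids, emb.coordinates):
                    fh.write(sid + "," + ",".join(f"{v:.6f}" for v in row) + "\n")
            report["stages"]["pcoa"] = {
                "axes": emb.coordinates.shape[1],
                "proportion_explained": [round(float(p), 4) for p in emb.proportion_explained],
                "negative_eigenvalue_mass": round(emb.negative_eigenvalue_mass, 6),
            }
        if "hybrid_index" in config.stages:
            if bc is None:
                bc = classify_bands(
                    matrix, meta, diagnostic_tolerance=config.diagnostic_tolerance
                )
            dset = DiagnosticMarkerSet.from_classification(bc)
            results = hybrid_index_table(matrix, meta, dset, config.class_thresholds)
            grid = marker_report(matrix, meta, dset, config.class_thresholds)
            write_report(grid, results, out / "hybrid_index")
            report["stages"]["hybrid_index"] = {
                "m_A": dset.m_A,
                "m_B": dset.m_B,
                "calls": {
                    r.specimen_id: {
                        "index_raw": round(r.index_raw, 4),
                        "index_normalized": round(r.index_normalized, 4),
                        "class_call": r.class_call,
                        "introgressed": r.introgressed,
                    }
                    for r in results
                },
            }
        if "admixture" in config.stages:
            lo, hi = config.admixture_K
            runs = {}
            for K in range(lo, hi + 1):
                runs[K] = []
                for rep in range(config.admixture_reps):
                    cfg = AdmixtureConfig(
                        K=K,
                        n_burnin=config.admixture_burnin,
                        n_iter=config.admixture_iters,
                        alpha=config.admixture_alpha,
                        seed=derive_seed(config.seed, f"admixture_K{K}_rep{rep}"),
                    )
                    runs[K].append(run_admixture(matrix, cfg))
                runs[K][0].q_frame().round(6).to_csv(out / f"admixture_Q_K{K}.csv")
            section = {
                "K_range": [lo, hi],
                "replicates": config.admixture_reps,
                "mean_loglik": {K: round(float(sum(r.mean_loglik for r in rs) / len(rs)), 3)
                                for K, rs in runs.items()},
            }
            if hi - lo >= 2 and config.admixture_reps >= 2:
                dk = evanno_deltaK(runs)
                dk_json = dk.table.where(dk.table.notna(), None).to_dict(orient="records")
                (out / "deltaK.json").write_text(
                    json.dumps({"selected_K": dk.selected_K, "table": dk_json}, indent=2),
                    encoding="utf-8",
                )
                section["selected_K"] = dk.selected_K
            else:
                report["warnings"].append(
                    "delta K skipped: needs >=3 consecutive K and >=2 replicates"
                )
            report["stages"]["admixture"] = section
    except HybridDetectError:
        (out / "FAILED").write_text("pipeline failed; see run.log", encoding="utf-8")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=str), encoding="utf-8"
    )
    (out / "report.txt").write_text(_report_text(report), encoding="utf-8")
    return report
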