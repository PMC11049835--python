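"""End-to-end orchestration: generate -> measure -> stats -> tree.

Every artifact written by :func:`run_all` is a deterministic function of
(config, seed): images and truth table from the generator, the per-cell
measurement table, the two group comparisons, the fitted decision tree,
and a markdown report that embeds the full configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .metrics import measure_dataset
from .quantify import SpotParams
from .segmentation import QCLimits
from .stats import compare_groups, per_subject_summary
from .synthetic import (
    GeometryConfig,
    RenderConfig,
    StudyDesign,
    default_presets,
    generate_dataset,
    truth_measurements,
)
from .tree import fit_tree

logger = logging.getLogger("spermfish")

METRICS = ("itd", "cta")


@dataclass
class RunConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    geom: GeometryConfig = field(default_factory=GeometryConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    qc_limits: QCLimits = field(default_factory=QCLimits)
    spot_params: SpotParams = field(default_factory=SpotParams)
    outdir: Path = Path("spermfish_run")
    write_images: bool = True     # False = truth-only fast mode
    tree_max_depth: int = 2
    tree_min_leaf: int = 5

    def describe(self) -> dict:
        d = {
            "design": dataclasses.asdict(self.design),
            "geom": dataclasses.asdict(self.geom),
            "render": dataclasses.asdict(self.render),
            "qc_limits": dataclasses.asdict(self.qc_limits),
            "spot_params": dataclasses.asdict(self.spot_params),
            "outdir": str(self.outdir),
            "write_images": self.write_images,
            "tree_max_depth": self.tree_max_depth,
            "tree_min_leaf": self.tree_min_leaf,
        }
        return d


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a TOML file plus keyword overrides.

    Recognized tables: ``[subjects]`` (id -> class), ``[geom]``,
    ``[render]``, ``[qc]``, ``[spots]``; top-level keys: seed,
    cells_per_subject, outdir, write_images, tree_max_depth,
    tree_min_leaf.
    """
    raw = tomllib.loads(Path(path).read_text())
    raw.update({k: v for k, v in overrides.items() if v is not None})

    design_kw = {}
    if "subjects" in raw:
        design_kw["subjects"] = tuple((sid, cls) for sid, cls in raw["subjects"].items())
    for key in ("cells_per_subject", "seed"):
        if key in raw:
            design_kw[key] = raw[key]
    cfg = RunConfig(design=StudyDesign(**design_kw))
    if "geom" in raw:
        cfg.geom = GeometryConfig(**raw["geom"])
    if "render" in raw:
        cfg.render = RenderConfig(**raw["render"])
    if "qc" in raw:
        cfg.qc_limits = QCLimits(**{k: tuple(v) for k, v in raw["qc"].items()})
    if "spots" in raw:
        cfg.spot_params = SpotParams(**raw["spots"])
    if "outdir" in raw:
        cfg.outdir = Path(raw["outdir"])
    for key in ("write_images", "tree_max_depth", "tree_min_leaf"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {getattr(h, "_spermfish_tag", None) for h in logger.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._spermfish_tag = "stderr"
        logger.addHandler(h)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh._spermfish_tag = "file"
    logger.handlers = [h for h in logger.handlers if getattr(h, "_spermfish_tag", None) != "file"]
    logger.addHandler(fh)


@dataclass
class RunReport:
    config: RunConfig
    measurements: pd.DataFrame
    comparisons: dict
    tree: object
    paths: dict


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts under
    ``config.outdir``; raises on the first failing stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("run_all: seed=%d, %d subjects x %d cells, images=%s",
                config.design.seed, len(config.design.subjects),
                config.design.cells_per_subject, config.write_images)

    presets = default_presets()
    image_dir = outdir / "images" if config.write_images else None
    images, truth, records = generate_dataset(
        config.design,
        presets,
        geom=config.geom,
        render=config.render,
        render_images=config.write_images,
        outdir=image_dir,
    )
    truth_path = outdir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    logger.info("generated %d cells -> %s", len(truth), truth_path)

    if config.write_images:
        from .io import read_image

        loaded = [read_image(p) for p in images]
        measurements = measure_dataset(
            loaded, truth[["cell_id", "subject_id", "class"]],
            qc_limits=config.qc_limits, spot_params=config.spot_params,
        )
    else:
        measurements = truth_measurements(records)
    meas_path = outdir / "measurements.csv"
    measurements.to_csv(meas_path, index=False)
    n_fail = int((~measurements["qc_pass"].astype(bool)).sum())
    logger.info("measured %d cells (%d QC failures) -> %s", len(measurements), n_fail, meas_path)

    comparisons = {m: compare_groups(measurements, m) for m in METRICS}
    stats_rows = [c.to_row() for c in comparisons.values()]
    pd.DataFrame(stats_rows).to_csv(outdir / "stats.csv", index=False)
    (outdir / "stats.json").write_text(json.dumps(stats_rows, indent=1))
    per_subject_summary(measurements).to_csv(outdir / "per_subject.csv", index=False)

    ok = measurements[measurements["qc_pass"].astype(bool)]
    tree = fit_tree(
        ok[list(METRICS)], ok["class"],
        max_depth=config.tree_max_depth, min_leaf=config.tree_min_leaf,
    )
    (outdir / "tree.json").write_text(tree.to_json(indent=1))

    report_path = outdir / "report.md"
    report_path.write_text(_render_report(config, measurements, comparisons, tree))
    logger.info("report -> %s", report_path)

    paths = {
        "truth": truth_path,
        "measurements": meas_path,
        "stats_csv": outdir / "stats.csv",
        "stats_json": outdir / "stats.json",
        "per_subject": outdir / "per_subject.csv",
        "tree": outdir / "tree.json",
        "report": report_path,
        "log": outdir / "run.log",
    }
    return RunReport(config, measurements, comparisons, tree, paths)


def _render_report(config, measurements, comparisons, tree) -> str:
    ok = measurements[measurements["qc_pass"].astype(bool)]
    lines = [
        "# Sperm nuclear-architecture run report",
        "",
        f"Cells measured: {len(measurements)} ({len(ok)} passing QC)",
        "",
        "## Group comparisons (Mann-Whitney, two-sided)",
        "",
        "| metric | n low | n high | median low [2.5-97.5%] | median high [2.5-97.5%] | U | p |",
        "|---|---|---|---|---|---|---|",
    ]
    for m, c in comparisons.items():
        lines.append(
            f"| {m.upper()} | {c.n_low} | {c.n_high} "
            f"| {c.median_low:.3f} [{c.interval_low[0]:.3f}, {c.interval_low[1]:.3f}] "
            f"| {c.median_high:.3f} [{c.interval_high[0]:.3f}, {c.interval_high[1]:.3f}] "
            f"| {c.u_statistic:.1f} | {c.p_two_sided:.3g} |"
        )
    lines += ["", "## Decision tree (Gini impurity)", "", "```",
              tree.format_text().rstrip(), "```", "", "## Configuration", "", "```json",
              json.dumps(config.describe(), indent=1, default=str), "```", ""]
    return "\n".join(lines)
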