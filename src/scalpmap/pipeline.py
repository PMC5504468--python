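"""End-to-end orchestration: simulate -> tenten -> procrustes -> ratios -> transfer.

Each stage reads and writes plain TSV/OBJ files, so re-running any single
stage from persisted intermediates reproduces the full-pipeline outputs
bit-for-bit.  All randomness flows from a single root seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, montage as montage_mod, shape, synthetic, transfer as transfer_mod
from .geometry import (
    FIDUCIAL_NAMES,
    LANDMARK_NAMES,
    load_mesh,
    read_landmark_table,
)
from .montage import HEAD_1020_LABELS, TenTenMontage, place_montage

logger = logging.getLogger("scalpmap")

_FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "scalpmap_out"
    n_subjects: int = 16
    age_range: tuple = (3.0, 22.0)
    montage_system: str = "10-10"
    growth: dict = field(default_factory=dict)   # GrowthModel field overrides
    fixture_dir: str | None = None               # use an existing cohort instead of simulating
    procrustes_tol: float = 1e-8
    procrustes_max_iter: int = 100
    template: str = "nearest-12"                 # subject id or "nearest-<months>"
    plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def validate(self):
        if self.fixture_dir is None and self.n_subjects < 3:
            raise ValueError("cohort needs at least 3 subjects")
        if self.fixture_dir is not None and not Path(self.fixture_dir).exists():
            raise ValueError(f"fixture_dir {self.fixture_dir!r} does not exist")
        if self.montage_system not in montage_mod.MONTAGE_DEFINITIONS:
            raise ValueError(f"unknown montage system {self.montage_system!r}")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> Path:
    model = synthetic.GrowthModel(seed=config.seed, **config.growth)
    cohort = synthetic.make_cohort(
        model, n=config.n_subjects, age_range=config.age_range, seed=config.seed
    )
    fixture = synthetic.write_fixture(cohort, outdir / "cohort")
    logger.info("simulated %d subjects into %s", len(cohort), fixture)
    return fixture


def stage_tenten(fixture_dir: Path, outdir: Path, system: str = "10-10") -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(fixture_dir / "manifest.tsv", sep="\t", dtype={"subject_id": str})
    sets = {ls.subject_id: ls for ls in read_landmark_table(fixture_dir / "landmarks.tsv")}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        scalp = load_mesh(fixture_dir / row["scalp_mesh"])
        m = place_montage(scalp, sets[sid].fiducials, system=system)
        _write_tsv(m.to_frame(), outdir / f"{sid}_montage.tsv")
    return outdir


def _read_montages(montage_dir: Path, system: str) -> dict:
    out = {}
    for path in sorted(Path(montage_dir).glob("*_montage.tsv")):
        sid = path.name[: -len("_montage.tsv")]
        out[sid] = TenTenMontage.from_frame(pd.read_csv(path, sep="\t"), system=system)
    return out


def stage_procrustes(
    fixture_dir: Path,
    montage_dir: Path,
    outdir: Path,
    tol: float = 1e-8,
    max_iter: int = 100,
    system: str = "10-10",
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    sets = read_landmark_table(fixture_dir / "landmarks.tsv")
    montages = _read_montages(montage_dir, system)
    results = {}
    var_rows, score_rows, reg_rows = [], [], []
    for space_name in ("cortex", "head"):
        if space_name == "cortex":
            configs = [shape.configuration_from_landmarks(ls) for ls in sets]
        else:
            configs = [
                shape.configuration_from_montage(
                    montages[ls.subject_id], ls.subject_id, ls.age_months, HEAD_1020_LABELS
                )
                for ls in sets
                if ls.subject_id in montages
            ]
        space = shape.gpa(configs, tol=tol, max_iter=max_iter)
        shape.pca_shapes(space)
        res = shape.regress_scores_on_age(space.scores[:, 0], space.ages)
        results[space_name] = (space, res)
        for i, frac in enumerate(space.variance_fractions[:10], start=1):
            var_rows.append({"space": space_name, "pc": i, "variance_fraction": frac})
        for sid, age, sc in zip(space.subject_ids, space.ages, space.scores[:, 0]):
            score_rows.append({"space": space_name, "subject_id": sid, "age_months": age, "pc1_score": sc})
        reg_rows.append({"space": space_name, "pc": 1, "r": res.r, "p": res.p, "n": res.n})
    _write_tsv(pd.DataFrame(var_rows), outdir / "variance_fractions.tsv")
    _write_tsv(pd.DataFrame(score_rows), outdir / "pc1_scores.tsv")
    _write_tsv(pd.DataFrame(reg_rows), outdir / "score_age_regression.tsv")
    return results


def stage_ratios(fixture_dir: Path, outdir: Path) -> pd.DataFrame:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(fixture_dir / "manifest.tsv", sep="\t", dtype={"subject_id": str})
    sets = read_landmark_table(fixture_dir / "landmarks.tsv")
    brains = {}
    for _, row in manifest.iterrows():
        if isinstance(row["brain_mesh"], str) and row["brain_mesh"]:
            brains[str(row["subject_id"])] = load_mesh(fixture_dir / row["brain_mesh"])
    table = metrics.table1_analysis(sets, brains=brains)
    _write_tsv(table, outdir / "table1.tsv")
    sizes = metrics.axis_length_correlations(sets)
    _write_tsv(sizes, outdir / "axis_length_correlations.tsv")
    return table


def _pick_template(sets, template_spec: str) -> str:
    if template_spec.startswith("nearest-"):
        target = float(template_spec.split("-", 1)[1])
        best = min(sets, key=lambda ls: abs(ls.age_months - target))
        return best.subject_id
    ids = [ls.subject_id for ls in sets]
    if template_spec not in ids:
        raise ValueError(f"template {template_spec!r} not in cohort {ids}")
    return template_spec


def stage_transfer(
    fixture_dir: Path,
    montage_dir: Path,
    outdir: Path,
    template_spec: str = "nearest-12",
    system: str = "10-10",
    plot: bool = False,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.read_fixture(fixture_dir)
    montages = _read_montages(montage_dir, system)
    sets = [s.landmarks for s in cohort]
    template_id = _pick_template(sets, template_spec)
    template = next(s for s in cohort if s.subject_id == template_id)
    result = transfer_mod.transfer_cohort(cohort, template, montages)
    stats = transfer_mod.dispersion(result.points)
    pitch = transfer_mod.montage_pitch_summary(montages[template_id])
    _write_tsv(result.records, outdir / "transfer_points.tsv")
    _write_tsv(stats, outdir / "dispersion.tsv")
    nn = montage_mod.nearest_neighbor_distances(montages[template_id])
    nn_df = pd.DataFrame(
        [{"label": k, "nearest_mm": v} for k, v in sorted(nn.items())]
    )
    _write_tsv(nn_df, outdir / "montage_nn.tsv")
    if plot:
        transfer_mod.plot_dispersion(stats, pitch, outdir / "dispersion.png")
    return {"result": result, "dispersion": stats, "pitch": pitch, "template_id": template_id}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.fixture_dir is not None:
        fixture = Path(config.fixture_dir)
    else:
        fixture = stage_simulate(config, outdir)
    montage_dir = stage_tenten(fixture, outdir / "montages", config.montage_system)
    shape_results = stage_procrustes(
        fixture, montage_dir, outdir / "shape",
        tol=config.procrustes_tol, max_iter=config.procrustes_max_iter,
        system=config.montage_system,
    )
    table1 = stage_ratios(fixture, outdir / "ratios")
    transfer_out = stage_transfer(
        fixture, montage_dir, outdir / "transfer",
        template_spec=config.template, system=config.montage_system, plot=config.plot,
    )
    summary = _summarize(config, shape_results, table1, transfer_out)
    (outdir / "summary.txt").write_text(summary)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    return {
        "fixture": fixture,
        "shape": shape_results,
        "table1": table1,
        "transfer": transfer_out,
        "summary": summary,
    }


def _summarize(config, shape_results, table1, transfer_out) -> str:
    lines = [f"scalpmap pipeline summary (seed={config.seed})", ""]
    for space_name, (space, res) in shape_results.items():
        vf = ", ".join(f"{100 * f:.1f}%" for f in space.variance_fractions[:4])
        lines.append(f"{space_name}: PC1-4 variance fractions {vf}")
        lines.append(f"{space_name}: PC1 score vs age r = {res.r:+.3f} (p = {res.p:.3f}, n = {res.n})")
    lines.append("")
    lines.append("ratio/age correlations (r, p by hemisphere):")
    for _, row in table1.iterrows():
        lines.append(
            f"  {row['definition']:>14s} {row['hemisphere']}  r = {row['r']:+.3f}  p = {row['p_printed']:.3f}"
        )
    stats = transfer_out["dispersion"]
    pitch = transfer_out["pitch"]
    lines.append("")
    lines.append(
        f"transfer to template {transfer_out['template_id']}: "
        f"max per-landmark dispersion median = {stats['median_mm'].max():.1f} mm, "
        f"max upper quartile = {stats['q3_mm'].max():.1f} mm"
    )
    lines.append(
        f"10-10 nearest-neighbor pitch: median = {pitch['median_mm']:.1f} mm "
        f"(quartiles {pitch['q1_mm']:.1f} / {pitch['q3_mm']:.1f} mm)"
    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# input validation (reports, never raises)
# ---------------------------------------------------------------------------

def validate_inputs(
    landmarks_path=None,
    mesh_paths=(),
    fixture_dir=None,
) -> list[dict]:
    """Machine-readable issue list for landmark tables and meshes."""
    issues: list[dict] = []
    if fixture_dir is not None:
        fixture_dir = Path(fixture_dir)
        landmarks_path = fixture_dir / "landmarks.tsv"
        manifest_path = fixture_dir / "manifest.tsv"
        if manifest_path.exists():
            manifest = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
            mesh_paths = [
                fixture_dir / p
                for col in ("brain_mesh", "scalp_mesh")
                for p in manifest[col]
                if isinstance(p, str) and p
            ]
        else:
            issues.append({"severity": "error", "code": "manifest-missing", "message": str(manifest_path)})
    if landmarks_path is not None:
        try:
            sets = read_landmark_table(landmarks_path)
        except Exception as exc:  # noqa: BLE001 - report, never raise
            issues.append({"severity": "error", "code": "landmarks-unreadable", "message": str(exc)})
            sets = []
        for ls in sets:
            for name in FIDUCIAL_NAMES:
                if name not in ls.fiducials:
                    issues.append(
                        {"severity": "error", "code": "fiducial-absent",
                         "message": f"{ls.subject_id}: fiducial {name} absent"}
                    )
            for hemi in ("L", "R"):
                missing = [lid for lid in LANDMARK_NAMES if (lid, hemi) not in ls.points]
                if missing:
                    issues.append(
                        {"severity": "warning", "code": "landmarks-incomplete",
                         "message": f"{ls.subject_id} {hemi}: missing labels {missing}"}
                    )
    for path in mesh_paths:
        try:
            mesh = load_mesh(path)
        except Exception as exc:  # noqa: BLE001
            issues.append({"severity": "error", "code": "mesh-unreadable", "message": f"{path}: {exc}"})
            continue
        n_boundary = mesh.boundary_edge_count()
        if n_boundary:
            issues.append(
                {"severity": "warning", "code": "mesh-not-watertight",
                 "message": f"{path}: {n_boundary} boundary edges"}
            )
    return issues
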