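"""End-to-end orchestration: scalp estimation and the method comparison.

:func:`estimate_scalp` composes the full estimation chain on one scan:
color filter -> k-means fiducial clustering -> per-module pose -> foot
projection -> scaled template fit.  :func:`evaluate_methods` reproduces
the study's comparison on a phantom with known ground truth, computing
289-point above-ear 10-5 errors (after rigid 10-20 alignment) for six
head-modeling strategies:

1. the cap-based scalp estimation,
2. the known generating transform of the phantom (the simulation analog
   of gold-standard volumetric affine registration),
3. the "basic 4" four-point affine (nasion, inion, left/right tragus,
   approximated by the preauricular landmarks),
4. rigid placement of the unscaled atlas via 10-20 correspondences,
5. estimation from a cap-less scan (the hair envelope as the scalp),
6. estimation without accounting for the module legs.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigError
from .fiducials import ColorFilterSpec
from .mesh_io import ColoredMesh, LandmarkSet
from .metrics import (
    ErrorReport,
    grand_mean,
    pointwise_errors,
    position_stats,
    reports_to_frame,
    summarize,
)
from .montage import MontagePointSet, compute_montages
from .phantom import (
    PhantomSpec,
    PhantomTruth,
    generating_scales,
    make_atlas,
    make_cap_scan,
    make_head,
    participant_spec,
    truth_montages,
    without_cap_scan,
)
from .pose import ModuleGeometry, SparseScalpSample, build_sparse_sample
from .registration import (
    SpatialTransform,
    affine_from_4_points,
    apply_transform,
    fit_template_to_sample,
    rigid_from_correspondences,
    unscaled_atlas_placement,
)

logger = logging.getLogger("capmorph.pipeline")

__all__ = [
    "PipelineParams",
    "RunConfig",
    "estimate_scalp",
    "evaluate_methods",
    "compare_cohort",
    "METHOD_IDS",
]

METHOD_IDS = [
    "scalp_estimation",
    "volumetric_gold_standard",
    "basic_4",
    "unscaled_atlas",
    "without_cap",
    "without_legs",
]


@dataclass
class PipelineParams:
    """Tunable parameters of the estimation chain."""

    filter: ColorFilterSpec = dc_field(default_factory=ColorFilterSpec)
    geometry: ModuleGeometry = dc_field(default_factory=ModuleGeometry)
    k: int = 17
    diameter_bound: float = 50.0
    restarts: int = 10
    seed: int = 0
    min_modules: int = 6
    residual_max: float = 2.0
    scaling: str = "anisotropic"
    max_iter: int = 300
    tol: float = 1e-4


@dataclass
class RunConfig:
    """File-level run configuration (CLI surface over PipelineParams)."""

    scan_path: Path | None = None
    template_path: Path | None = None
    landmarks_path: Path | None = None
    output_dir: Path = Path("capmorph_out")
    seed: int = 0
    params: PipelineParams = dc_field(default_factory=PipelineParams)
    verbosity: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise ConfigError(f"cannot read config file {path}")

        def get(section, key, cast, default):
            try:
                return cast(cp.get(section, key))
            except (configparser.NoSectionError, configparser.NoOptionError):
                return default

        filt = ColorFilterSpec(
            red_min=get("filter", "red_min", float, 0.5),
            sat_min=get("filter", "sat_min", float, 0.7),
            hue_max=get("filter", "hue_max", float, 0.1),
        )
        geom = ModuleGeometry(
            leg_vertical=get("module", "leg_vertical_mm", float, 20.0),
            leg_horizontal=get("module", "leg_horizontal_mm", float, 15.0),
            height=get("module", "height_mm", float, 25.0),
            leg_length=get("module", "leg_length_mm", float, 10.0),
        )
        params = PipelineParams(
            filter=filt,
            geometry=geom,
            k=get("cluster", "k", int, 17),
            diameter_bound=get("cluster", "diameter_mm", float, 50.0),
            restarts=get("cluster", "restarts", int, 10),
            seed=get("cluster", "seed", int, 0),
            min_modules=get("pose", "min_modules", int, 6),
            residual_max=get("pose", "residual_max_mm", float, 2.0),
            scaling=get("register", "mode", str, "anisotropic"),
            max_iter=get("register", "max_iter", int, 300),
            tol=get("register", "tol", float, 1e-4),
        )
        paths = {}
        for key in ("scan", "template", "landmarks"):
            v = get("paths", key, str, None)
            paths[f"{key}_path"] = Path(v) if v else None
        return cls(
            output_dir=Path(get("paths", "output_dir", str, "capmorph_out")),
            seed=get("run", "seed", int, params.seed),
            params=params,
            **paths,
        )

    def validate(self, need=("scan", "template")) -> None:
        for key in need:
            p = getattr(self, f"{key}_path")
            if p is None:
                raise ConfigError(f"missing required path: {key}")
            if not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")


@dataclass
class EstimateResult:
    sample: SparseScalpSample
    transform: SpatialTransform
    estimated_mesh: ColoredMesh
    estimated_landmarks: LandmarkSet | None = None


def estimate_scalp(
    scan: ColoredMesh,
    template: ColoredMesh,
    params: PipelineParams | None = None,
    template_landmarks: LandmarkSet | None = None,
    init: SpatialTransform | None = None,
) -> EstimateResult:
    """Scalp morphology estimation from a cap scan.

    Runs detection and pose recovery to build the sparse scalp sample,
    then fits the template surface to it (rotation, translation and the
    requested scaling).  The scan and template are assumed to be roughly
    pre-aligned (same anatomical frame) unless ``init`` is given.
    """
    params = params or PipelineParams()
    sample = build_sparse_sample(
        scan,
        filter_spec=params.filter,
        geometry=params.geometry,
        k=params.k,
        seed=params.seed,
        diameter_bound=params.diameter_bound,
        restarts=params.restarts,
        min_modules=params.min_modules,
        residual_max=params.residual_max,
    )
    transform = fit_template_to_sample(
        template,
        sample,
        allow_scaling=params.scaling,
        init=init,
        max_iter=params.max_iter,
        tol=params.tol,
    )
    est_mesh = apply_transform(transform, template)
    est_lm = (
        apply_transform(transform, template_landmarks)
        if template_landmarks is not None
        else None
    )
    return EstimateResult(sample, transform, est_mesh, est_lm)


def _montage_errors(
    est_mesh: ColoredMesh,
    est_landmarks: LandmarkSet,
    ten20_true: MontagePointSet,
    ten5_true: MontagePointSet,
    method_id: str,
    participant_id: str,
) -> ErrorReport:
    """10-5 error of one estimated surface after rigid 10-20 alignment."""
    ten20_e, ten5_e = compute_montages(est_mesh, est_landmarks)
    align = rigid_from_correspondences(ten20_e, ten20_true)
    ten5_aligned = apply_transform(align, ten5_e)
    errors = pointwise_errors(ten5_aligned, ten5_true)
    return summarize(errors, method_id, participant_id)


def evaluate_methods(
    truth: PhantomTruth,
    geometry: ModuleGeometry | None = None,
    params: PipelineParams | None = None,
    atlas: PhantomTruth | None = None,
    participant_id: str = "phantom",
    methods=METHOD_IDS,
) -> dict:
    """Per-participant error reports for the six head-modeling strategies.

    Returns {method_id: ErrorReport}; each report's ``per_label`` map
    feeds the across-participant position statistics.
    """
    geometry = geometry or ModuleGeometry()
    params = params or PipelineParams(geometry=geometry)
    atlas = atlas or make_atlas()
    spec = truth.spec

    scan = make_cap_scan(truth, spec, geometry)
    ten20_true, ten5_true = truth_montages(truth)
    atlas_ten20, _ = truth_montages(atlas)
    reports: dict[str, ErrorReport] = {}

    def add(method, est_mesh, est_lm):
        reports[method] = _montage_errors(
            est_mesh, est_lm, ten20_true, ten5_true, method, participant_id
        )
        logger.info(
            "%s / %s: mean %.2f mm", participant_id, method, reports[method].mean
        )

    if "scalp_estimation" in methods:
        res = estimate_scalp(
            scan, atlas.scalp_mesh, params, template_landmarks=atlas.landmarks
        )
        add("scalp_estimation", res.estimated_mesh, res.estimated_landmarks)

    if "volumetric_gold_standard" in methods:
        gold = SpatialTransform.from_rs(
            np.eye(3), generating_scales(spec), np.zeros(3)
        )
        add(
            "volumetric_gold_standard",
            apply_transform(gold, atlas.scalp_mesh),
            apply_transform(gold, atlas.landmarks),
        )

    if "basic_4" in methods:
        basic4 = affine_from_4_points(
            atlas.landmarks.as_dict(), truth.landmarks.as_dict()
        )
        add(
            "basic_4",
            apply_transform(basic4, atlas.scalp_mesh),
            apply_transform(basic4, atlas.landmarks),
        )

    if "unscaled_atlas" in methods:
        rigid = unscaled_atlas_placement(atlas_ten20, ten20_true)
        add(
            "unscaled_atlas",
            apply_transform(rigid, atlas.scalp_mesh),
            apply_transform(rigid, atlas.landmarks),
        )

    if "without_cap" in methods:
        nc_mesh, nc_lm = without_cap_scan(truth, spec)
        add("without_cap", nc_mesh, nc_lm)

    if "without_legs" in methods:
        nl_params = replace(
            params,
            geometry=geometry.with_height(geometry.height - geometry.leg_length),
        )
        res = estimate_scalp(
            scan, atlas.scalp_mesh, nl_params, template_landmarks=atlas.landmarks
        )
        add("without_legs", res.estimated_mesh, res.estimated_landmarks)

    return reports


def compare_cohort(
    n_participants: int = 10,
    base_spec: PhantomSpec | None = None,
    geometry: ModuleGeometry | None = None,
    params: PipelineParams | None = None,
    seed: int = 0,
    output_dir=None,
    methods=METHOD_IDS,
) -> dict:
    """The phantom-cohort comparison experiment.

    Generates ``n_participants`` seeded participants around the base
    conditions, evaluates every method on each, and aggregates grand
    means and per-position statistics.

    Returns dict with keys: "reports" (per-participant), "grand"
    ({method: ErrorReport}), "positions" ({method: PositionStats}).
    """
    base_spec = base_spec or PhantomSpec()
    geometry = geometry or ModuleGeometry()
    params = params or PipelineParams(geometry=geometry, seed=seed)
    atlas = make_atlas(base_spec.mesh_resolution)
    seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(seed).generate_state(n_participants)
    ]
    all_reports: list[ErrorReport] = []
    per_method: dict[str, list[ErrorReport]] = {m: [] for m in methods}
    for i, pseed in enumerate(seeds):
        spec = participant_spec(base_spec, pseed)
        truth = make_head(spec)
        reports = evaluate_methods(
            truth,
            geometry,
            replace(params, seed=pseed),
            atlas=atlas,
            participant_id=f"P{i + 1:02d}",
            methods=methods,
        )
        for m in methods:
            per_method[m].append(reports[m])
            all_reports.append(reports[m])
    grand = {m: grand_mean(per_method[m]) for m in methods}
    positions = {
        m: position_stats([r.per_label for r in per_method[m]]) for m in methods
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = reports_to_frame(all_reports + list(grand.values()))
        frame.to_csv(out / "method_errors.csv", index=False)
        for m in methods:
            positions[m].to_csv(out / f"positions_{m}.csv")
    return {"reports": per_method, "grand": grand, "positions": positions}
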