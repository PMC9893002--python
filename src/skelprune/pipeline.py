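"""End-to-end pipeline: preprocess -> [register] -> skeletonize ->
analyze -> model."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from . import analyze as _analyze
from . import colonize as _colonize
from . import model as _model
from . import preprocess as _preprocess
from . import register as _register
from .cloud import PointCloud
from .transform import RigidTransform

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cloud: PointCloud                      # merged, denoised working cloud
    transform: Optional[RigidTransform]    # back->front motion (two-view runs)
    registration_rmse: Optional[float]
    skeleton: object
    labeled: _analyze.LabeledSkeleton
    plan: _analyze.PruningPlan
    pruned_skeleton: object
    radii: _model.RadiusMap
    mesh: _model.TreeMesh


def register_views(
    front: PointCloud,
    back: PointCloud,
    markers_front: List[PointCloud],
    markers_back: List[PointCloud],
    icp_params: Optional[_register.IcpParams] = None,
) -> RigidTransform:
    """Marker-initialized, ICP-refined rigid motion mapping ``back`` onto
    ``front``."""
    if len(markers_front) != 3 or len(markers_back) != 3:
        raise ValueError("exactly three marker clouds per view are required")
    cF = np.array([_register.fit_sphere(m).center for m in markers_front])
    cB = np.array([_register.fit_sphere(m).center for m in markers_back])
    perm = _register.match_markers(cF, cB)
    init = _register.rigid_from_pairs(cB[perm], cF)
    log.info("marker initialization: rotation %.2f deg", init.rotation_angle_deg())
    refined, trace = _register.icp_refine(back, front, init,
                                          icp_params or _register.IcpParams())
    log.info("ICP refinement: %d iterations, final RMSE %.3g cm", len(trace), trace[-1])
    return refined


def run_pipeline(
    config: Dict,
    cloud: PointCloud,
    back_cloud: Optional[PointCloud] = None,
    markers_front: Optional[List[PointCloud]] = None,
    markers_back: Optional[List[PointCloud]] = None,
    crop_box: Optional[tuple] = None,
    seed_position: Optional[np.ndarray] = None,
    root_radius: Optional[float] = None,
) -> PipelineResult:
    """Run every stage with the given config (see ``constants.DEFAULTS``)."""
    sor = _preprocess.SorParams(k=int(config["sor_k"]), lam=float(config["sor_lambda"]))

    def clean(c: PointCloud) -> PointCloud:
        if crop_box is not None:
            c = _preprocess.crop_region(c, box=crop_box)
        inl, _ = _preprocess.remove_outliers(c, sor)
        return inl

    front = clean(cloud)
    transform = None
    rmse = None
    if back_cloud is not None:
        back = clean(back_cloud)
        transform = register_views(front, back, markers_front or [], markers_back or [])
        rmse = _register.registration_error(front, back, transform)
        log.info("registration error %.3g cm", rmse)
        merged = PointCloud(np.vstack([front.points, transform.apply(back.points)]))
    else:
        merged = front

    params = _colonize.ColonizationParams(
        R=float(config["R"]), theta=float(config["theta"]),
        Ds=float(config["Ds"]), Rd=float(config["Rd"]))
    skeleton = _colonize.colonize(merged, seed_position, params)

    labeled = _analyze.analyze_skeleton(
        skeleton,
        psi_max=float(config["psi_max"]),
        min_length=float(config["min_branch_length"]),
        fraction=float(config["prune_fraction"]),
    )
    plan = labeled.plan

    pruned = _model.prune_skeleton(skeleton, plan)
    radii = _model.assign_radii(
        pruned,
        root_radius=float(root_radius if root_radius is not None else config["root_radius"]),
        exponent=float(config["pipe_exponent"]),
    )
    mesh = _model.build_mesh(pruned, radii)
    return PipelineResult(
        cloud=merged, transform=transform, registration_rmse=rmse,
        skeleton=skeleton, labeled=labeled, plan=plan,
        pruned_skeleton=pruned, radii=radii, mesh=mesh,
    )
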