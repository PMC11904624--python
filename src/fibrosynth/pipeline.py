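"""End-to-end orchestration: exemplar -> distance map -> patch dataset ->
(filtered) reconstructions -> pore-network analysis, with a run manifest.

Every stage draws its randomness from a stable sub-seed of the run's global
seed, so adding or re-running a stage never perturbs the randomness of the
stages before it.  Every artifact written to disk is listed in
``manifest.json`` with its SHA-256 content hash and the full config echo,
which makes runs bit-reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io
from .distance_map import BinaryVolume, double_distance_map
from .patch_dataset import sample_patches
from .phantom import PhantomSpec, generate_fibrous_volume
from .pore_network import extract_network, morphology_summary
from .reconstruct import ReconstructionConfig, reconstruct_volume

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)

_STAGES = ("phantom", "dataset", "reconstruct", "analysis")


def stage_seed(global_seed: int, stage: str, offset: int = 0) -> int:
    """Stable per-stage sub-seed (< 2^31) derived from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx, int(offset)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full synthesis-and-analysis run."""

    out_dir: str
    exemplar_path: str | None = None  # None -> generate a phantom
    output_shape: tuple[int, int, int] = (96, 96, 96)
    patch_shape: tuple[int, int, int] = (24, 24, 24)
    margin: int = 6
    sigma: float = 0.5
    n_per_transform: int = 200
    feature_target: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_realizations: int = 1
    target_porosity: float = 0.61
    voxel_size: float = 6.25
    h_merge: float = 1.0
    longitudinal_axis: int = 2
    seed: int = 0


def _average_summaries(summaries: list[dict]) -> dict:
    keys = summaries[0].keys()
    return {k: float(np.mean([s[k] for s in summaries])) for k in keys}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and return the manifest dictionary.

    Emits, under ``config.out_dir``: the exemplar volume, each
    reconstruction, per-realization and averaged property summaries
    (plus the exemplar's own summary and relative errors), and
    ``manifest.json`` listing every artifact with its content hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = io.sha256_of(path)

    # --- exemplar ---------------------------------------------------------
    if config.exemplar_path is not None:
        log.info("loading exemplar from %s", config.exemplar_path)
        exemplar = io.read_volume(config.exemplar_path)
        if not isinstance(exemplar, BinaryVolume):
            raise ValueError("exemplar must be a binary volume")
    else:
        log.info("generating fibrous phantom exemplar, porosity %.2f",
                 config.target_porosity)
        exemplar = generate_fibrous_volume(PhantomSpec(
            shape=config.output_shape,
            target_porosity=config.target_porosity,
            voxel_size=config.voxel_size,
            seed=stage_seed(config.seed, "phantom"),
        ))
    p = io.write_volume(exemplar, out / "exemplar.tif")
    register(p)
    register(io.sidecar_path(p))

    # --- dataset ----------------------------------------------------------
    log.info("building patch dataset (N=%d per transform, patch %s)",
             config.n_per_transform, config.patch_shape)
    dmap = double_distance_map(exemplar)
    dataset = sample_patches(dmap, config.n_per_transform, config.patch_shape,
                             seed=stage_seed(config.seed, "dataset"))
    dataset.to_csv(out / "patch_features.csv")
    register(out / "patch_features.csv")

    # --- reconstructions + analysis --------------------------------------
    summaries = []
    for r in range(config.n_realizations):
        rc = ReconstructionConfig(
            output_shape=config.output_shape,
            patch_shape=config.patch_shape,
            margin=config.margin,
            sigma=config.sigma,
            seed=stage_seed(config.seed, "reconstruct", r),
            feature_target=config.feature_target,
        )
        log.info("reconstruction %d/%d (seed %d)", r + 1,
                 config.n_realizations, rc.seed)
        volume, report = reconstruct_volume(dataset, rc, return_report=True)
        p = io.write_volume(volume, out / f"reconstruction_{r:03d}.tif")
        register(p)
        register(io.sidecar_path(p))

        network = extract_network(volume, h_merge=config.h_merge)
        summary = morphology_summary(volume, network,
                                     longitudinal_axis=config.longitudinal_axis)
        summary["matching_fraction_below_0.2"] = report.fraction_below(0.2)
        summary["seed"] = rc.seed
        spath = out / f"summary_{r:03d}.json"
        spath.write_text(json.dumps(summary, indent=1))
        register(spath)
        summaries.append(summary)

    # --- exemplar analysis and averages -----------------------------------
    log.info("analysing exemplar")
    ex_network = extract_network(exemplar, h_merge=config.h_merge)
    ex_summary = morphology_summary(exemplar, ex_network,
                                    longitudinal_axis=config.longitudinal_axis)
    (out / "exemplar_summary.json").write_text(json.dumps(ex_summary, indent=1))
    register(out / "exemplar_summary.json")

    avg = _average_summaries([{k: v for k, v in s.items() if k != "seed"}
                              for s in summaries])
    rel_err = {
        k: abs(avg[k] - ex_summary[k]) / abs(ex_summary[k])
        for k in ex_summary if ex_summary[k] != 0
    }
    averaged = {"n_realizations": config.n_realizations,
                "average": avg, "exemplar": ex_summary,
                "relative_error": rel_err}
    (out / "averaged_summary.json").write_text(json.dumps(averaged, indent=1))
    register(out / "averaged_summary.json")

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("wrote manifest with %d artifacts", len(artifacts))
    return manifest
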