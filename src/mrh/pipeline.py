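"""End-to-end run orchestration: phantom -> patches -> train -> evaluate.

A RunConfig (usually loaded from YAML) names the inputs, the stages to
execute, and the overrides for the network and training schedule.  One
global seed feeds named substreams (phantom, split, init, perturb) so
individual stages can be rerun independently with identical results.
Every run directory receives a machine-readable ``summary.json``
stamped with the config hash, seed, and package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import evalsuite, io, mrhnet, patches, perturb, phantom
from .contrasts import polynomial_baseline_fit

__all__ = ["RunConfig", "run_pipeline", "acquisition_budget", "substream_seed"]

_STAGES = ("phantom", "patches", "train", "predict", "contribution", "evaluate")


def substream_seed(global_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    Either phantom parameters (synthetic run) or paths to existing
    NIfTI inputs/targets/masks must be given.  ``channel_manifest``
    maps channel label -> {group, time_weight}.
    """

    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # synthetic inputs
    phantom_shape: tuple[int, int, int] = (32, 32, 32)
    phantom_channels: int = 12
    phantom_classes: int = 4
    phantom_mapping: str = "subset-dependent"
    phantom_active_channels: tuple[int, ...] = (0, 1, 2)
    phantom_noise: float = 0.05
    # file inputs (override the phantom when set)
    input_path: str | None = None
    target_path: str | None = None
    mask_path: str | None = None
    channel_manifest: dict = field(default_factory=dict)
    # patches / training
    n_patches: int = 8000
    n_val: int = 1000
    patch_k: int = 3
    slice_axis: int = 0
    n_residual_blocks: int = 8
    channels_per_layer: int = 16
    training: dict = field(default_factory=dict)
    # analysis
    contribution_noise: float = 0.10
    contribution_repeats: int = 3
    roc_polarity: str = "hypo"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for p in (self.input_path, self.target_path, self.mask_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.input_path is None) != (self.target_path is None):
            raise ValueError("input_path and target_path must be given together")
        if self.input_path is not None and self.mask_path is None:
            raise ValueError("file-based runs require a mask path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.load_yaml(path)
        for key in ("phantom_shape", "phantom_active_channels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def acquisition_budget(
    report: perturb.ContributionReport,
    time_weights: dict[str, float] | np.ndarray,
    coverage: float,
) -> tuple[np.ndarray, float]:
    """Channel subset covering the contribution target, and its time cost.

    ``time_weights`` gives per-channel acquisition-time weights (by
    label, or as an array in channel order).  Returns the selected
    channel indices and the fraction of total acquisition time they
    require.
    """
    if isinstance(time_weights, dict):
        missing = [l for l in report.channel_labels if l not in time_weights]
        if missing:
            raise ValueError(f"missing time weights for channels: {missing}")
        w = np.array([time_weights[l] for l in report.channel_labels], float)
    else:
        w = np.asarray(time_weights, float)
        if w.size != report.n_channels:
            raise ValueError("one time weight per channel required")
    if (w < 0).any():
        raise ValueError("time weights must be nonnegative")
    subset = perturb.select_subset(report, coverage=coverage)
    fraction = float(w[subset].sum() / w.sum())
    return subset, fraction


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the summary.

    On a stage failure, artifacts from completed stages remain in the
    run directory and the raised error names the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "timings": {},
    }
    state: dict = {}

    def _save_summary() -> None:
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, default=float)

    for stage in config.stages:
        t0 = time.time()
        try:
            _run_stage(stage, config, state, out, summary)
        except Exception as exc:
            summary["failed_stage"] = stage
            summary["error"] = str(exc)
            _save_summary()
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        summary["timings"][stage] = round(time.time() - t0, 3)
        _save_summary()
    return summary


def _run_stage(stage, config: RunConfig, state, out: Path, summary) -> None:
    if stage == "phantom":
        if config.input_path is not None:
            labels = list(config.channel_manifest) or None
            state["volume"] = io.load_volume(config.input_path, labels)
            state["target"] = io.load_volume(config.target_path)
            state["mask"] = io.load_mask(config.mask_path)
            summary["stages"]["phantom"] = {"source": "files"}
            return
        spec = phantom.default_phantom_spec(
            shape=config.phantom_shape,
            n_channels=config.phantom_channels,
            n_classes=config.phantom_classes,
            mapping_form=config.phantom_mapping,
            active_channels=config.phantom_active_channels,
            noise_sigma_fraction=config.phantom_noise,
            seed=substream_seed(config.seed, "phantom-spec"),
        )
        vol, tgt, mask, labels_vol = phantom.make_phantom(
            spec, substream_seed(config.seed, "phantom")
        )
        state.update(volume=vol, target=tgt, mask=mask, labels=labels_vol,
                     spec=spec)
        io.save_volume(vol, out / "inputs.nii.gz")
        io.save_volume(tgt, out / "target.nii.gz")
        io.save_volume(mask.astype(np.uint8), out / "mask.nii.gz")
        io.save_volume(labels_vol.astype(np.int16), out / "labels.nii.gz")
        io.save_yaml(
            {"seed": config.seed, "n_classes": spec.n_classes,
             "n_channels": spec.n_channels,
             "noise_sigma_fraction": spec.noise_sigma_fraction,
             "mapping_form": spec.mapping.form},
            out / "phantom.yaml",
        )
        summary["stages"]["phantom"] = {
            "shape": list(spec.shape), "n_channels": spec.n_channels,
        }
    elif stage == "patches":
        ps = patches.extract_patches(
            state["volume"], state["target"], state["mask"],
            k=config.patch_k, n=config.n_patches, axis=config.slice_axis,
            seed=substream_seed(config.seed, "patches"),
        )
        ps, _ = patches.normalize_channels(ps, "fit", normalize_target=True)
        train_ps, val_ps = patches.split_validation(
            ps, config.n_val, substream_seed(config.seed, "split")
        )
        state.update(train_ps=train_ps, val_ps=val_ps)
        io.save_patchset(ps, out / "patches.h5")
        summary["stages"]["patches"] = {"n_train": train_ps.n, "n_val": val_ps.n}
    elif stage == "train":
        spec = mrhnet.NetworkSpec(
            in_channels=state["train_ps"].n_channels,
            n_residual_blocks=config.n_residual_blocks,
            channels_per_layer=config.channels_per_layer,
            patch_size=config.patch_k,
        )
        net = mrhnet.build_mrh(spec, substream_seed(config.seed, "init"))
        # pipeline default: the desk-scale-stable rate (overridable)
        tc = mrhnet.TrainingConfig(
            seed=substream_seed(config.seed, "sgd"),
            **{"learning_rate": 0.05, **config.training},
        )
        model = mrhnet.train(net, state["train_ps"], state["val_ps"], tc)
        state["model"] = model
        io.save_model(model, out / "model.npz")
        summary["stages"]["train"] = {
            "selected_epoch": model.selected_epoch,
            "val_loss": model.history["val_loss"][model.selected_epoch - 1],
            "n_parameters": mrhnet.count_parameters(model.network),
        }
    elif stage == "predict":
        pred = mrhnet.translate_volume(
            state["model"], state["volume"], state["mask"], config.slice_axis
        )
        state["prediction"] = pred
        io.save_volume(pred, out / "prediction.nii.gz")
        summary["stages"]["predict"] = {"voxels": int(state["mask"].sum())}
    elif stage == "contribution":
        report = perturb.channel_contribution(
            state["model"], state["volume"], state["mask"],
            noise_fraction=config.contribution_noise,
            repeats=config.contribution_repeats,
            seed=substream_seed(config.seed, "perturb"),
            axis=config.slice_axis,
        )
        state["report"] = report
        report.to_dataframe().to_csv(out / "contribution.csv", index=False)
        io.save_yaml(
            {"noise_fraction": report.noise_fraction,
             "repeats": report.repeats, "seed": report.seed},
            out / "contribution.yaml",
        )
        summary["stages"]["contribution"] = {
            "ranking": report.ranking.tolist(),
            "cumulative": report.cumulative.tolist(),
        }
    elif stage == "evaluate":
        pred = state["prediction"].data
        ref = state["target"].data
        mask = state["mask"]
        metrics = {
            "rmse": evalsuite.rmse(pred, ref, mask),
            "r2": evalsuite.voxelwise_r2(pred, ref, mask),
            "ssim": evalsuite.ssim(pred, ref, mask),
            "auc": evalsuite.roc_analysis(pred, ref, mask,
                                          config.roc_polarity).auc,
        }
        # order-1 polynomial baseline on center voxels for context
        flat_in = state["volume"].data[mask]
        flat_t = ref[mask]
        base = polynomial_baseline_fit(flat_in, flat_t, order=1)
        metrics["baseline_r2"] = evalsuite.voxelwise_r2(
            base.predict(state["volume"].data), ref, mask
        )
        summary["stages"]["evaluate"] = metrics
        with open(out / "metrics.json", "w") as f:
            json.dump(metrics, f, indent=2)
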