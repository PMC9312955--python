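"""Flat key-value run configuration (YAML) with schema versioning.

The file is a single flat mapping; keys are namespaced by prefix
(``synth_``, ``scal_``, ``model_``, ``train_``).  Unknown keys are errors so
typos fail fast, and every invariant is checked before any heavy computation.
Every stochastic stage derives its seed from the single top-level ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import MViTConfig
from .preprocess import ScalogramConfig
from .synthetic import SynthConfig
from .train import TrainConfig

SCHEMA_VERSION = 1

_DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "source": "synthetic",  # or a clip-directory path
    "threshold": 0.5,
    # synthetic data
    "synth_n_subjects": 4,
    "synth_clips_per_class": 10,
    "synth_n_channels": 4,
    "synth_fs": 100.0,
    "synth_clip_len_s": 120.0,
    "synth_snr": 2.0,
    "synth_sig_band_lo": 18.0,
    "synth_sig_band_hi": 24.0,
    "synth_burst_rate": 6.0,
    # scalograms
    "scal_n_scales": 100,
    "scal_f_min": 0.5,
    "scal_f_max": None,
    "scal_log_power": True,
    "scal_resize_h": 32,
    "scal_resize_w": 64,
    "scal_normalize": True,
    # model
    "model_patch_h": 8,
    "model_patch_w": 8,
    "model_embed_dim": 32,
    "model_depth": 2,
    "model_n_heads": 2,
    "model_mlp_hidden": 64,
    "model_dropout": 0.1,
    "model_share_branch_weights": False,
    # training
    "train_learning_rate": 1e-4,
    "train_batch_size": 32,
    "train_max_epochs": 50,
    "train_class_weighting": True,
    "train_patience": 5,
    "train_val_fraction": 0.2,
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolved and validated."""

    raw: dict
    seed: int
    source: str
    threshold: float
    synth: SynthConfig
    scal: ScalogramConfig
    train: TrainConfig

    def model_config(self, n_branches: int) -> MViTConfig:
        r = self.raw
        if self.scal.resize_to is None:
            raise ConfigError("modelling requires scal_resize_h/scal_resize_w to be set")
        return MViTConfig(
            n_branches=n_branches,
            image_hw=self.scal.resize_to,
            patch_hw=(r["model_patch_h"], r["model_patch_w"]),
            embed_dim=r["model_embed_dim"],
            depth=r["model_depth"],
            n_heads=r["model_n_heads"],
            mlp_hidden=r["model_mlp_hidden"],
            dropout=r["model_dropout"],
            share_branch_weights=r["model_share_branch_weights"],
        )


def load_run_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load and validate a run config; missing keys take defaults.

    ``seed`` (e.g. from the command line) overrides the file's seed."""
    raw = dict(_DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        unknown = sorted(set(loaded) - set(_DEFAULTS))
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {unknown}")
        raw.update(loaded)
    if raw["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {raw['schema_version']} (expected {SCHEMA_VERSION})"
        )
    if seed is not None:
        raw["seed"] = int(seed)

    synth = SynthConfig(
        n_subjects=raw["synth_n_subjects"],
        clips_per_class=raw["synth_clips_per_class"],
        n_channels=raw["synth_n_channels"],
        fs=raw["synth_fs"],
        clip_len_s=raw["synth_clip_len_s"],
        snr=raw["synth_snr"],
        sig_band=(raw["synth_sig_band_lo"], raw["synth_sig_band_hi"]),
        burst_rate=raw["synth_burst_rate"],
        seed=raw["seed"],
    )
    resize = (
        (raw["scal_resize_h"], raw["scal_resize_w"])
        if raw["scal_resize_h"] and raw["scal_resize_w"]
        else None
    )
    scal = ScalogramConfig(
        n_scales=raw["scal_n_scales"],
        f_min=raw["scal_f_min"],
        f_max=raw["scal_f_max"],
        log_power=raw["scal_log_power"],
        resize_to=resize,
        normalize=raw["scal_normalize"],
    )
    train = TrainConfig(
        learning_rate=raw["train_learning_rate"],
        batch_size=raw["train_batch_size"],
        max_epochs=raw["train_max_epochs"],
        class_weighting=raw["train_class_weighting"],
        patience=raw["train_patience"],
        val_fraction=raw["train_val_fraction"],
        seed=raw["seed"],
    )
    source = str(raw["source"])
    if source != "synthetic" and not Path(source).exists():
        raise ConfigError(f"source directory {source!r} does not exist")
    # fail-fast on model invariants against the configured image shape
    if resize is not None:
        if resize[0] % raw["model_patch_h"] or resize[1] % raw["model_patch_w"]:
            raise ConfigError(
                f"patch {raw['model_patch_h']}x{raw['model_patch_w']} does not divide "
                f"image {resize[0]}x{resize[1]}"
            )
        if raw["model_embed_dim"] % raw["model_n_heads"]:
            raise ConfigError("model_embed_dim must be divisible by model_n_heads")
    return RunConfig(
        raw=raw,
        seed=raw["seed"],
        source=source,
        threshold=raw["threshold"],
        synth=synth,
        scal=scal,
        train=train,
    )
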