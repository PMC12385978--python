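"""Checkpoint container: one ``.npz`` archive holding every weight array
keyed by layer and role, the training-set adaptive vectors, and an embedded
YAML config describing the layer stack; loading validates array shapes
against the config."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .model_core import LayerConfig, ModelSpec, ModelWeights
from .training import TrainedModel, TrainTrace

__all__ = ["save_checkpoint", "load_checkpoint", "spec_to_dict", "spec_from_dict"]


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "layers": [
            {"num_d": c.num_d, "num_z": c.num_z, "tau": c.tau,
             "meta_prior_w": c.meta_prior_w}
            for c in spec.layers
        ],
        "obs_dim": spec.obs_dim,
        "goal_dim": spec.goal_dim,
        "proprio_dim": spec.proprio_dim,
    }


def spec_from_dict(d: dict) -> ModelSpec:
    layers = tuple(LayerConfig(**lc) for lc in d["layers"])
    return ModelSpec(layers=layers, obs_dim=d["obs_dim"],
                     goal_dim=d["goal_dim"], proprio_dim=d["proprio_dim"])


def save_checkpoint(path, model: TrainedModel, extra_meta: dict | None = None
                    ) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": spec_to_dict(model.weights.spec)}
    if extra_meta:
        meta["meta"] = extra_meta
    arrays = dict(model.weights.to_arrays())
    for l, (am, asig) in enumerate(zip(model.A_mu, model.A_sig)):
        arrays[f"train_A/{l}/mu"] = am
        arrays[f"train_A/{l}/sigma"] = asig
    arrays["yaml_config"] = np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[TrainedModel, dict]:
    """Load a checkpoint; weights come back frozen.  Returns the model and
    any extra metadata stored alongside it."""
    with np.load(Path(path)) as data:
        meta = yaml.safe_load(bytes(data["yaml_config"]).decode())
        spec = spec_from_dict(meta["config"])
        weights = ModelWeights.from_arrays(
            spec, {k: data[k] for k in data.files if "/" in k and
                   not k.startswith("train_A/")},
            frozen=True)
        A_mu = [data[f"train_A/{l}/mu"] for l in range(spec.num_layers)]
        A_sig = [data[f"train_A/{l}/sigma"] for l in range(spec.num_layers)]
    model = TrainedModel(weights, A_mu, A_sig, TrainTrace())
    return model, meta.get("meta", {})
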