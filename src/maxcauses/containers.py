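"""HDF5 result container and run configuration.

Layout of the container::

    /params/{W, sigma, pi, model_kind}
    /trace/{free_energy, pi, sigma, n_selected, fraction, temperature, wall_time}
    /data/{patches, shape, states?}
    /ground_truth/{W, signs, pi, sigma, amplitude, grid_size, model_kind}?
    /meta/{config (YAML), seed, format_version}

Any saved run is self-describing: the exact configuration that produced
it is recoverable from ``/meta/config`` and a checkpoint can be reloaded
to resume or analyze.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import yaml

from .learning import EMTrace
from .models import ModelParams, PatchSet
from .synthetic import BarsGroundTruth

__all__ = ["RunConfig", "save_run", "load_params", "load_trace",
           "load_patches", "load_ground_truth", "load_config"]

FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to reproduce a training run."""

    model_kind: str = "MCA"
    H: int = 10
    H_prime: int = 6
    gamma: int = 4
    iterations: int = 100
    rho: int = 25
    start_temperature: float = 1.0
    seed: int = 0
    patch_shape: tuple[int, int] | None = None
    preprocessing: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.model_kind.upper() not in ("MCA", "BSC"):
            raise ValueError("model_kind must be MCA or BSC")
        if not (1 <= self.gamma <= self.H_prime <= self.H):
            raise ValueError("need 1 <= gamma <= H_prime <= H")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.rho < 3 or self.rho % 2 == 0:
            raise ValueError("rho must be an odd integer >= 3")

    def to_yaml(self) -> str:
        d = asdict(self)
        if d["patch_shape"] is not None:
            d["patch_shape"] = list(d["patch_shape"])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if d.get("patch_shape") is not None:
            d["patch_shape"] = tuple(d["patch_shape"])
        return cls(**d)


def save_run(
    path,
    config: RunConfig,
    params: ModelParams | None = None,
    trace: EMTrace | None = None,
    patches: PatchSet | None = None,
    states: np.ndarray | None = None,
    ground_truth: BarsGroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["config"] = config.to_yaml()
        meta.attrs["seed"] = config.seed
        meta.attrs["format_version"] = FORMAT_VERSION
        if params is not None:
            g = f.create_group("params")
            g.create_dataset("W", data=params.W)
            g.attrs["sigma"] = params.sigma
            g.attrs["pi"] = params.pi
            g.attrs["model_kind"] = params.model_kind
        if trace is not None:
            g = f.create_group("trace")
            for key, arr in trace.as_dict().items():
                g.create_dataset(key, data=arr)
        if patches is not None:
            g = f.create_group("data")
            g.create_dataset("patches", data=patches.Y)
            if patches.shape is not None:
                g.attrs["shape"] = patches.shape
            if states is not None:
                g.create_dataset("states", data=np.asarray(states, dtype=np.int8))
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("W", data=ground_truth.W)
            g.create_dataset("signs", data=ground_truth.signs)
            g.attrs["pi"] = ground_truth.pi
            g.attrs["sigma"] = ground_truth.sigma
            g.attrs["amplitude"] = ground_truth.amplitude
            g.attrs["grid_size"] = ground_truth.grid_size
            g.attrs["model_kind"] = ground_truth.model_kind


def load_params(path) -> ModelParams:
    with h5py.File(path, "r") as f:
        g = f["params"]
        return ModelParams(W=g["W"][...], sigma=float(g.attrs["sigma"]),
                           pi=float(g.attrs["pi"]),
                           model_kind=str(g.attrs["model_kind"]))


def load_trace(path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f["trace"][k][...] for k in f["trace"]}


def load_patches(path) -> PatchSet:
    with h5py.File(path, "r") as f:
        g = f["data"]
        shape = tuple(int(v) for v in g.attrs["shape"]) if "shape" in g.attrs else None
        return PatchSet(g["patches"][...], shape=shape)


def load_ground_truth(path) -> BarsGroundTruth | None:
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            return None
        g = f["ground_truth"]
        return BarsGroundTruth(
            grid_size=int(g.attrs["grid_size"]), W=g["W"][...],
            amplitude=float(g.attrs["amplitude"]), signs=g["signs"][...],
            pi=float(g.attrs["pi"]), sigma=float(g.attrs["sigma"]),
            model_kind=str(g.attrs["model_kind"]),
        )


def load_config(path) -> RunConfig:
    with h5py.File(path, "r") as f:
        return RunConfig.from_yaml(str(f["meta"].attrs["config"]))
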