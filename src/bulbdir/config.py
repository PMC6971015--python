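"""Run configuration: one YAML file drives synth/train/simulate/evaluate.

The dataclasses below hold every tunable of the pipeline — detector
ring, phantom morphology ranges and resolution, feature parameters,
regressor hyperparameters, the agreement threshold tau and the success
threshold — with the defaults the package documents.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RingConfig:
    separation_deg: float = 60.0
    distance_mm: float = 200.0
    azimuth0_deg: float = 0.0


@dataclass
class PhantomConfig:
    volume_size: int = 128
    voxel_size_mm: float = 0.5
    detector_pixels: int = 160
    pixel_size_mm: float = 0.6
    n_phantoms: int = 20
    poses_per_phantom: int = 50


@dataclass
class FeatureConfig:
    threshold_frac: float = 0.05
    frangi_beta: float = 0.5
    frangi_c: float = 15.0
    frangi_sigmas: tuple[float, ...] = (3.0, 5.0, 7.0)
    frangi_classical: bool = False
    intensity_scale: float = 255.0
    lbp_radius: int = 2
    lbp_neighbours: int = 6

    def extract_kwargs(self) -> dict:
        return {
            "frac": self.threshold_frac,
            "beta": self.frangi_beta,
            "c": self.frangi_c,
            "sigmas": tuple(self.frangi_sigmas),
            "classical": self.frangi_classical,
            "intensity_scale": self.intensity_scale,
            "lbp_r": self.lbp_radius,
            "lbp_k": self.lbp_neighbours,
        }


@dataclass
class RegressorConfig:
    kind: str = "ann"
    kernel_width: float = 500.0
    kernel_width_param: str = "half_sq"  # exp(-d^2/(2 w^2)); "plain": exp(-d^2/w)
    svr_C: float = 10.0
    svr_epsilon: float = 0.01
    elm_C: float = 100.0
    elm_runs: int = 20
    ann_hidden: tuple[int, ...] = (60, 30, 15)
    ann_max_epochs: int = 1000
    ann_grad_tol: float = 1e-6
    ann_unit_circle_loss: bool = True

    def train_kwargs(self) -> dict:
        if self.kind == "svr":
            return {
                "width": self.kernel_width,
                "width_param": self.kernel_width_param,
                "C": self.svr_C,
                "epsilon": self.svr_epsilon,
            }
        if self.kind == "elm":
            return {
                "width": self.kernel_width,
                "width_param": self.kernel_width_param,
                "C": self.elm_C,
            }
        if self.kind == "ann":
            return {
                "hidden": tuple(self.ann_hidden),
                "max_epochs": self.ann_max_epochs,
                "grad_tol": self.ann_grad_tol,
                "unit_circle_loss": self.ann_unit_circle_loss,
            }
        raise ValueError(f"unknown regressor kind {self.kind!r}")


@dataclass
class PipelineConfig:
    ring: RingConfig = field(default_factory=RingConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    tau_deg: float = 40.0
    success_deg: float = 30.0
    max_passes: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sub = {"ring": RingConfig, "phantom": PhantomConfig,
               "features": FeatureConfig, "regressor": RegressorConfig}
        for f in fields(cls):
            if f.name not in raw:
                continue
            if f.name in sub:
                kwargs[f.name] = sub[f.name](**raw[f.name])
            else:
                kwargs[f.name] = raw[f.name]
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
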