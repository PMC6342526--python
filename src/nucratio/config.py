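"""Pipeline configuration.

Nested dataclass blocks, one per stage, serialized to/from YAML. Every
threshold the analysis depends on is an explicit config value with a
stated default; unknown keys are rejected up front so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any

import yaml

from . import __version__

__all__ = ["PipelineConfig", "load_config", "dump_config"]


def _from_mapping(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under '{path}'"
            f" (allowed: {sorted(allowed)})"
        )
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if hasattr(f.type, "__dataclass_fields__") or (
            isinstance(f.type, str) and f.type in _BLOCKS
        ):
            sub_cls = _BLOCKS[f.type] if isinstance(f.type, str) else f.type
            val = _from_mapping(sub_cls, val or {}, f"{path}.{f.name}")
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class SimulateBlock:
    """Synthetic stack generation (see :class:`nucratio.synthetic.SynthParams`)."""

    grid_shape: tuple = (32, 128, 128)
    voxel_spacing: tuple = (1.0, 0.5, 0.5)
    n_adaxial: int = 100
    n_abaxial: int = 74
    nucleus_radius_range: tuple = (1.2, 2.0)
    domain_split: float = 0.5
    adaxial_ratio_mean: float = 0.24
    adaxial_ratio_sd: float = 0.20
    abaxial_ratio_mean: float = 0.29
    abaxial_ratio_sd: float = 0.24
    mdii_amplitude_range: tuple = (1000.0, 3000.0)
    background_level: float = 10.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    bit_depth: int = 12
    include_calibration_nucleus: bool = True
    min_separation: float = 1.0
    # render-time blur: "model" uses the preprocess block's optics,
    # "none" disables, a number is an isotropic Gaussian sigma in um
    psf_mode: str = "model"


@dataclass
class PreprocessBlock:
    """Pre-segmentation chain; iteration counts of 0 skip a stage."""

    deconvolve: bool = True
    rl_iterations: int = 8
    psf_na: float = 0.95
    psf_excitation_nm: float = 514.0
    psf_emission_nm: float = 527.0
    psf_refractive_index: float = 1.333
    wiener: bool = False
    wiener_size: int = 3
    median_iterations: int = 1
    median_radius: int = 1
    gaussian_sigma: float = 1.0
    gaussian_iterations: int = 1


@dataclass
class SegmentBlock:
    """Attractor labeling and label refinement thresholds (um / um^3)."""

    neighborhood_kind: str = "cross"
    neighborhood_radius: float = 1.0
    neighborhood_physical: bool = False
    merge_distance_um: float = 2.0
    merge_depth_threshold: float = 0.0  # 0 disables depth merging
    merge_depth_mode: str = "min"
    small_size_threshold_um3: float = 4.0
    small_max_merge_distance_um: float = 3.0
    remove_min_volume_um3: float = 2.0
    remove_min_mean_intensity: float = 0.0


@dataclass
class QuantifyBlock:
    """Per-nucleus extraction and quality filtering."""

    min_mean_mdii: float | None = None  # None -> quantile rule
    mdii_quantile: float = 0.05
    min_volume_um3: float = 2.0
    max_volume_um3: float = 500.0
    background_subtract: float = 0.0  # counts removed from both channels; 0 = off
    normalization_scope: str = "crop"  # or "stack" for per-leaf joint scaling


@dataclass
class StatsBlock:
    auc_method: str = "rank-sum"  # or "trapezoid"
    report_decimals: int = 3


@dataclass
class RatioImageBlock:
    protocol: str = "neg"
    nuclear_threshold: float | None = None  # pos protocol; None -> Otsu


_BLOCKS = {
    "SimulateBlock": SimulateBlock,
    "PreprocessBlock": PreprocessBlock,
    "SegmentBlock": SegmentBlock,
    "QuantifyBlock": QuantifyBlock,
    "StatsBlock": StatsBlock,
    "RatioImageBlock": RatioImageBlock,
}


@dataclass
class PipelineConfig:
    """Resolved configuration of a full run."""

    seed: int = 0
    version: str = __version__
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    segment: SegmentBlock = field(default_factory=SegmentBlock)
    quantify: QuantifyBlock = field(default_factory=QuantifyBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    ratio_image: RatioImageBlock = field(default_factory=RatioImageBlock)

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _from_mapping(cls, dict(data or {}), "config")

    def to_mapping(self) -> dict:
        return asdict(self)

    def synth_params(self):
        """Materialize :class:`~nucratio.synthetic.SynthParams` from the block."""
        from .synthetic import SynthParams

        s = self.simulate
        return SynthParams(
            grid_shape=tuple(int(v) for v in s.grid_shape),
            voxel_spacing=tuple(float(v) for v in s.voxel_spacing),
            n_nuclei_per_domain={"adaxial": s.n_adaxial, "abaxial": s.n_abaxial},
            nucleus_radius_range=tuple(float(v) for v in s.nucleus_radius_range),
            domain_split=s.domain_split,
            ratio_dist={
                "adaxial": (s.adaxial_ratio_mean, s.adaxial_ratio_sd),
                "abaxial": (s.abaxial_ratio_mean, s.abaxial_ratio_sd),
            },
            mdii_amplitude_range=tuple(float(v) for v in s.mdii_amplitude_range),
            background_level=s.background_level,
            gaussian_noise_sd=s.gaussian_noise_sd,
            poisson_noise=s.poisson_noise,
            bit_depth=s.bit_depth,
            include_calibration_nucleus=s.include_calibration_nucleus,
            min_separation=s.min_separation,
            seed=self.seed,
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(data)


def dump_config(config: PipelineConfig, path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(config.to_mapping()), fh, sort_keys=False)
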