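"""Ground-truthed synthetic two-channel confocal stacks.

Emulates imaging of the R2D2 ratiometric auxin sensor: nuclei carry an
auxin-degradable DII reporter and a non-degradable mDII control expressed
from the same promoter, so the per-nucleus DII/mDII intensity ratio reads
out auxin sensing. The generator scatters non-overlapping spherical nuclei
(in physical units; ellipsoids in anisotropic voxels) across two tissue
domains ("adaxial" toward low y, "abaxial" toward high y), draws each
nucleus' true ratio from a per-domain truncated normal on [0, 1], renders
both channels, and optionally applies PSF blur, Poisson and Gaussian noise,
a background offset and integer quantization.

Defaults mirror the study conditions this package reproduces: 12-bit
stacks with 1 um section spacing, per-domain ratio distributions with
mean 0.24 / SD 0.20 (adaxial) and mean 0.29 / SD 0.24 (abaxial), and
roughly 100 adaxial + 74 abaxial nuclei per stack (2006 and 1475 nuclei
pooled over 20 stacks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import fsolve
from scipy.stats import truncnorm

from .stack import ImageStack, make_toy_volume

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_ground_truth",
    "render_stack",
    "make_toy_volume",
    "sample_truncated_normal",
    "truncated_normal_params",
]

#: per-domain ratio distributions: target mean and SD of the truncated-to-[0, 1]
#: true-ratio distribution (the generator moment-matches these exactly)
DEFAULT_RATIO_DIST = {"adaxial": (0.24, 0.20), "abaxial": (0.29, 0.24)}


@dataclass
class SynthParams:
    """Parameters of the synthetic imaging forward model.

    Attributes
    ----------
    grid_shape : (z, y, x) voxel counts.
    voxel_spacing : um per axis (z, y, x). The xy pixel size of the original
        acquisitions is not knowable from the stack format alone; 0.5 um is
        a typical value for a 25x objective and is exposed in config.
    n_nuclei_per_domain : either a single int (same for both domains) or a
        mapping ``{"adaxial": n, "abaxial": m}``.
    nucleus_radius_range : (min, max) nuclear radius in um.
    domain_split : fraction of the y extent assigned to the adaxial domain
        (centers with y below the split are adaxial).
    ratio_dist : per-domain target (mean, sd) of the true-ratio
        distribution — a normal truncated to [0, 1] whose post-truncation
        moments are solved to match these values exactly.
    mdii_amplitude_range : (min, max) in-nucleus mDII amplitude in counts.
    background_level : additive background offset (counts) in both channels.
    gaussian_noise_sd : detector (read) noise SD in counts.
    poisson_noise : apply shot noise to signal + background.
    bit_depth : quantization depth; intensities clip to [0, 2**depth - 1].
    include_calibration_nucleus : add one nucleus with true ratio exactly
        1.0 and the maximum amplitude, so max-matching normalization
        downstream recovers ratios on an absolute scale.
    min_separation : extra clearance (um) between nucleus surfaces, beyond
        non-overlap, so PSF blur does not fuse neighbours.
    seed : RNG seed for placement, ratios and noise.
    """

    grid_shape: tuple[int, int, int] = (32, 128, 128)
    voxel_spacing: tuple[float, float, float] = (1.0, 0.5, 0.5)
    n_nuclei_per_domain: int | dict = field(
        default_factory=lambda: {"adaxial": 100, "abaxial": 74}
    )
    nucleus_radius_range: tuple[float, float] = (1.2, 2.0)
    domain_split: float = 0.5
    ratio_dist: dict = field(default_factory=lambda: dict(DEFAULT_RATIO_DIST))
    mdii_amplitude_range: tuple[float, float] = (1000.0, 3000.0)
    background_level: float = 10.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = True
    bit_depth: int = 12
    include_calibration_nucleus: bool = True
    min_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        rmin, rmax = self.nucleus_radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        extents = [n * s for n, s in zip(self.grid_shape, self.voxel_spacing)]
        if rmax >= min(extents) / 4:
            raise ValueError(
                f"max radius {rmax} um too large for grid extent {min(extents)} um"
            )
        if not 0.0 <= self.domain_split <= 1.0:
            raise ValueError("domain_split must lie in [0, 1]")
        for dom, (mu, sd) in self.ratio_dist.items():
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"ratio mean for {dom!r} must lie in [0, 1]")
            if sd < 0:
                raise ValueError("ratio SD must be non-negative")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")

    def counts(self) -> dict[str, int]:
        """Requested nucleus count per domain."""
        if isinstance(self.n_nuclei_per_domain, dict):
            return {k: int(v) for k, v in self.n_nuclei_per_domain.items()}
        n = int(self.n_nuclei_per_domain)
        return {"adaxial": n, "abaxial": n}


@dataclass
class GroundTruth:
    """Known nucleus parameters underlying a rendered stack.

    One row per nucleus: center (um, z/y/x), radius (um), domain tag,
    true DII/mDII ratio and mDII amplitude. Nuclei are pairwise
    non-overlapping by construction.
    """

    centers: np.ndarray  # (n, 3) um, z/y/x
    radii: np.ndarray  # (n,) um
    domains: np.ndarray  # (n,) str
    true_ratios: np.ndarray  # (n,) in [0, 1]
    amplitudes: np.ndarray  # (n,) counts
    calibration: np.ndarray = None  # (n,) bool; the ratio-1.0 fiducial

    def __post_init__(self):
        if self.calibration is None:
            self.calibration = np.zeros(len(self.radii), dtype=bool)

    def __len__(self) -> int:
        return len(self.radii)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(1, len(self) + 1),
                "z_um": self.centers[:, 0] if len(self) else [],
                "y_um": self.centers[:, 1] if len(self) else [],
                "x_um": self.centers[:, 2] if len(self) else [],
                "radius_um": self.radii,
                "domain": self.domains,
                "true_ratio": self.true_ratios,
                "amplitude": self.amplitudes,
                "calibration": self.calibration,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path)
        return cls(
            centers=df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float),
            radii=df["radius_um"].to_numpy(dtype=float),
            domains=df["domain"].to_numpy(dtype=object),
            true_ratios=df["true_ratio"].to_numpy(dtype=float),
            amplitudes=df["amplitude"].to_numpy(dtype=float),
            calibration=(
                df["calibration"].to_numpy(dtype=bool)
                if "calibration" in df
                else None
            ),
        )


@lru_cache(maxsize=32)
def truncated_normal_params(
    target_mean: float, target_sd: float, lo: float = 0.0, hi: float = 1.0
) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose [lo, hi] truncation has the
    requested mean and SD.

    The study's group summaries are moments of the observed (bounded)
    ratio distributions, so the generator moment-matches: it solves for
    the pre-truncation parameters such that the truncated distribution
    itself has ``target_mean`` and ``target_sd``.
    """
    if not lo <= target_mean <= hi:
        raise ValueError("target mean must lie inside the truncation bounds")
    if target_sd <= 0:
        raise ValueError("target SD must be positive (0 is a point mass)")

    def eqs(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - target_mean, float(np.sqrt(v)) - target_sd]

    sol, _, ier, msg = fsolve(
        eqs, [target_mean, np.log(target_sd)], full_output=True
    )
    if ier != 1:
        raise ValueError(
            f"no truncated normal on [{lo}, {hi}] with mean {target_mean}, "
            f"SD {target_sd}: {msg}"
        )
    return float(sol[0]), float(np.exp(sol[1]))


def sample_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int,
    lo: float = 0.0, hi: float = 1.0,
) -> np.ndarray:
    """Draw n values whose distribution is a normal truncated to [lo, hi]
    with the given (post-truncation) mean and SD.

    Sampling is exact via the truncated normal's quantile function;
    ``sd == 0`` degenerates to a point mass at ``mean``.
    """
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = truncated_normal_params(float(mean), float(sd), lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_ground_truth(params: SynthParams, max_attempts: int = 20000) -> GroundTruth:
    """Place non-overlapping nuclei and draw their true ratios.

    Placement is rejection sampling: candidate centers are drawn uniformly
    within the domain's y band (inset by the nucleus radius on every axis)
    and rejected if closer than ``r_i + r_j + min_separation`` to any
    accepted nucleus. The domain tag follows from the center's y position
    relative to ``domain_split``. With ``include_calibration_nucleus`` one
    extra adaxial-side nucleus gets true ratio 1.0 at maximum amplitude.
    """
    rng = np.random.default_rng(params.seed)
    extents = np.array(
        [n * s for n, s in zip(params.grid_shape, params.voxel_spacing)]
    )
    split_y = params.domain_split * extents[1]
    counts = params.counts()

    centers: list[np.ndarray] = []
    radii: list[float] = []
    domains: list[str] = []

    def place(domain: str, radius: float) -> None:
        lo = np.array([radius, radius, radius])
        hi = extents - radius
        if domain == "adaxial":
            hi = hi.copy()
            hi[1] = min(hi[1], split_y)
        else:
            lo = lo.copy()
            lo[1] = max(lo[1], split_y)
        if np.any(hi <= lo):
            raise RuntimeError(
                f"domain {domain!r} band too narrow for radius {radius:.2f} um"
            )
        for _ in range(max_attempts):
            c = rng.uniform(lo, hi)
            ok = True
            for c2, r2 in zip(centers, radii):
                if np.linalg.norm(c - c2) <= radius + r2 + params.min_separation:
                    ok = False
                    break
            if ok:
                centers.append(c)
                radii.append(radius)
                domains.append(domain)
                return
        raise RuntimeError(
            f"could not place nucleus in domain {domain!r} after "
            f"{max_attempts} attempts; reduce counts or radii"
        )

    rmin, rmax = params.nucleus_radius_range
    for domain in ("adaxial", "abaxial"):
        for _ in range(counts.get(domain, 0)):
            place(domain, float(rng.uniform(rmin, rmax)))

    n_regular = len(radii)
    if params.include_calibration_nucleus:
        # Brightest possible reference with ratio 1.0 anchors the
        # max-matching normalization at unit scale.
        cal_domain = "adaxial" if counts.get("adaxial", 0) or not counts.get("abaxial", 0) else "abaxial"
        place(cal_domain, float(rng.uniform(rmin, rmax)))

    ratios = np.empty(len(radii))
    doms = np.array(domains, dtype=object)
    for domain, (mu, sd) in params.ratio_dist.items():
        idx = np.flatnonzero(doms[:n_regular] == domain)
        ratios[idx] = sample_truncated_normal(rng, mu, sd, len(idx))
    amp_lo, amp_hi = params.mdii_amplitude_range
    amps = rng.uniform(amp_lo, amp_hi, size=len(radii))
    calibration = np.zeros(len(radii), dtype=bool)
    if params.include_calibration_nucleus:
        # the fiducial outshines every tissue nucleus so both channel
        # maxima are taken inside it, keeping the normalization unbiased
        ratios[n_regular] = 1.0
        amps[n_regular] = 1.15 * amp_hi
        calibration[n_regular] = True

    return GroundTruth(
        centers=np.array(centers).reshape(-1, 3),
        radii=np.array(radii),
        domains=doms,
        true_ratios=ratios,
        amplitudes=amps,
        calibration=calibration,
    )


def render_stack(
    gt: GroundTruth,
    params: SynthParams,
    psf: np.ndarray | float | None = None,
) -> ImageStack:
    """Render the two reporter channels from ground truth.

    The mDII channel is ``background + sum(amplitude inside each nucleus)``;
    the DII channel uses ``true_ratio * amplitude`` instead. ``psf`` may be
    a normalized 3D kernel (convolved via FFT), a scalar Gaussian sigma in
    um (isotropic blur, cheaper), or None. Noise order is Poisson on
    signal + background, then additive Gaussian, then clipping and
    quantization to the integer range of ``bit_depth``.
    """
    shape = params.grid_shape
    spacing = np.asarray(params.voxel_spacing)
    extents = np.array([n * s for n, s in zip(shape, spacing)])
    if len(gt) and (np.any(gt.centers < 0) or np.any(gt.centers > extents)):
        raise ValueError("ground-truth centers fall outside the grid")

    dii = np.zeros(shape, dtype=float)
    mdii = np.zeros(shape, dtype=float)
    for c, r, ratio, amp in zip(gt.centers, gt.radii, gt.true_ratios, gt.amplitudes):
        # bounding box in voxel indices
        lo = np.maximum(np.floor((c - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0]) + 0.5) * spacing[0],
            (np.arange(lo[1], hi[1]) + 0.5) * spacing[1],
            (np.arange(lo[2], hi[2]) + 0.5) * spacing[2],
            indexing="ij",
        )
        inside = (
            (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        ) <= r**2
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        mdii[sl][inside] += amp
        dii[sl][inside] += ratio * amp

    if psf is not None:
        if np.isscalar(psf):
            sigma_vox = float(psf) / spacing
            dii = gaussian_filter(dii, sigma_vox, mode="reflect")
            mdii = gaussian_filter(mdii, sigma_vox, mode="reflect")
        else:
            from scipy.signal import fftconvolve

            kernel = np.asarray(psf, dtype=float)
            if abs(kernel.sum() - 1.0) > 1e-6:
                raise ValueError("PSF kernel must be normalized to sum 1")
            pad = [s // 2 for s in kernel.shape]
            for arr_name in ("dii", "mdii"):
                arr = {"dii": dii, "mdii": mdii}[arr_name]
                padded = np.pad(arr, [(p, p) for p in pad], mode="reflect")
                conv = fftconvolve(padded, kernel, mode="same")
                cropped = conv[tuple(slice(p, p + s) for p, s in zip(pad, shape))]
                if arr_name == "dii":
                    dii = cropped
                else:
                    mdii = cropped

    dii += params.background_level
    mdii += params.background_level

    rng = np.random.default_rng(params.seed + 1)
    if params.poisson_noise:
        dii = rng.poisson(np.maximum(dii, 0)).astype(float)
        mdii = rng.poisson(np.maximum(mdii, 0)).astype(float)
    if params.gaussian_noise_sd > 0:
        dii = dii + rng.normal(0, params.gaussian_noise_sd, size=shape)
        mdii = mdii + rng.normal(0, params.gaussian_noise_sd, size=shape)

    vmax = 2 ** params.bit_depth - 1
    voxels = np.stack(
        [
            np.clip(np.rint(dii), 0, vmax),
            np.clip(np.rint(mdii), 0, vmax),
        ],
        axis=-1,
    ).astype(np.uint16)
    return ImageStack(
        voxels=voxels,
        spacing=params.voxel_spacing,
        bit_depth=params.bit_depth,
        channels=("DII", "mDII"),
    )
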