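"""Simulation configuration with desk-scale defaults.

Latent ground truth covers six constructs: two neural integrity scores
(``lc``, ``snvta``), three cognitive factors (``wm``, ``em``, ``gf``)
and a medial-temporal-lobe volume factor (``mtl``).  Modality offsets
default to the empirical ordering MT+ > FSE > MT− of nucleus-to-reference
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

CONSTRUCTS = ("lc", "snvta", "wm", "em", "gf", "mtl")
NEURAL = ("lc", "snvta")
COGNITIVE = ("wm", "em", "gf")
GROUPS = ("younger", "older")
TIMEPOINTS = (1, 2, 3)

# task -> (factor, loading, intercept, residual_sd); loadings kept modest so
# indicator variances stay well below 1 and large-sample moment checks are
# sharp at desk-scale n
DEFAULT_COGNITIVE_LOADINGS: dict[str, tuple[str, float, float, float]] = {
    "spatial_u": ("wm", 0.50, 0.0, 0.40),
    "letter_u": ("wm", 0.45, 0.0, 0.42),
    "number": ("wm", 0.40, 0.0, 0.45),
    "scene": ("em", 0.50, 0.0, 0.40),
    "list": ("em", 0.45, 0.0, 0.42),
    "face": ("em", 0.40, 0.0, 0.45),
    "object": ("em", 0.42, 0.0, 0.44),
    "problem": ("gf", 0.50, 0.0, 0.40),
    "analog": ("gf", 0.45, 0.0, 0.42),
    "letter": ("gf", 0.42, 0.0, 0.44),
}


class ConfigError(ValueError):
    pass


@dataclass
class ModalityParams:
    gain: float          # intensity-ratio units per latent unit
    roi_offset: float    # expected nucleus-to-reference contrast
    ref_mean: float      # reference-region mean intensity (scanner units)
    noise_sd: float      # additive voxel noise s.d. (scanner units)


@dataclass
class ChangeParams:
    mean: float = 0.0            # mean latent change per interval
    variance: float = 0.25       # variance of latent change
    cov_baseline: float = -0.05  # covariance of change with baseline level
    age_slope: float = 0.0       # change per year of (centred) age


@dataclass
class GroupMoments:
    means: np.ndarray       # length-6 vector over CONSTRUCTS
    covariance: np.ndarray  # 6x6 positive semi-definite

    def validate(self, name: str) -> None:
        means = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if means.shape != (len(CONSTRUCTS),) or cov.shape != (
            len(CONSTRUCTS), len(CONSTRUCTS)
        ):
            raise ConfigError(f"factor moments for {name!r} have wrong shape")
        if not np.allclose(cov, cov.T):
            raise ConfigError(f"factor covariance for {name!r} is not symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10:
            raise ConfigError(
                f"factor covariance for {name!r} is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
        self.means = means
        self.covariance = cov


def _default_cov(rho: float = 0.4) -> np.ndarray:
    k = len(CONSTRUCTS)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    return cov


def default_factor_moments() -> dict[str, GroupMoments]:
    young = GroupMoments(np.zeros(len(CONSTRUCTS)), _default_cov())
    old = GroupMoments(
        np.array([-0.8, -0.6, -1.2, -1.2, -1.1, -0.8]), _default_cov()
    )
    return {"younger": young, "older": old}


def default_modality_params() -> dict[str, ModalityParams]:
    # contrast ordering MT+ > FSE > MT-
    return {
        "mtplus": ModalityParams(gain=0.03, roi_offset=0.26, ref_mean=100.0, noise_sd=1.0),
        "fse": ModalityParams(gain=0.03, roi_offset=0.20, ref_mean=100.0, noise_sd=1.0),
        "mtminus": ModalityParams(gain=0.03, roi_offset=0.06, ref_mean=100.0, noise_sd=1.0),
    }


def default_change_model() -> dict[str, ChangeParams]:
    model = {c: ChangeParams() for c in CONSTRUCTS}
    model["lc"] = ChangeParams(mean=0.0, variance=0.3, cov_baseline=-0.05,
                               age_slope=-0.02)
    model["snvta"] = ChangeParams(mean=0.0, variance=0.3, cov_baseline=-0.05,
                                  age_slope=-0.02)
    for c in COGNITIVE:
        model[c] = ChangeParams(mean=-0.1, variance=0.2, cov_baseline=-0.05,
                                age_slope=-0.01)
    return model


def default_availability() -> dict[tuple[str, int], float]:
    avail = {}
    for mod in ("mtplus", "mtminus"):
        for tp in (1, 2):
            avail[(mod, tp)] = 1.0
    avail[("fse", 2)] = 1.0  # FSE exists at TP2 only (two acquisitions)
    return avail


def default_roi_geometry(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Voxel coordinate blocks for nuclei, references and ventricle.

    Bilateral nuclei sit either side of the midline over several axial
    slices; reference boxes sit below them; the ventricle blob overlaps
    the medial edge of both LC regions so the exclusion mask has bite.
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 16:
        raise ConfigError("grid too small for the default ROI geometry")
    cx, cy = nx // 2, ny // 2
    z0 = nz // 2

    def block(x0, x1, y0, y1, zlo, zhi):
        xs, ys, zs = np.meshgrid(
            np.arange(x0, x1), np.arange(y0, y1), np.arange(zlo, zhi),
            indexing="ij",
        )
        return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)

    geometry = {
        "lc_left": block(cx - 4, cx - 2, cy + 2, cy + 4, z0, z0 + 4),
        "lc_right": block(cx + 2, cx + 4, cy + 2, cy + 4, z0, z0 + 4),
        "snvta_left": block(cx - 5, cx - 2, cy - 5, cy - 2, z0 + 4, z0 + 7),
        "snvta_right": block(cx + 2, cx + 5, cy - 5, cy - 2, z0 + 4, z0 + 7),
        "pons_ref": block(cx - 3, cx + 3, cy - 2, cy + 1, z0, z0 + 4),
        "crus_ref": block(cx - 3, cx + 3, cy - 8, cy - 6, z0 + 4, z0 + 7),
        # medial blob straddling the inner edge of both LC blocks
        "ventricle": block(cx - 3, cx + 3, cy + 3, cy + 5, z0 + 1, z0 + 3),
    }
    return geometry


@dataclass
class SimulationConfig:
    n_young: int = 30
    n_old: int = 30
    grid_shape: tuple[int, int, int] = (40, 50, 60)
    roi_geometry: dict[str, np.ndarray] | None = None
    modality_params: dict[str, ModalityParams] = field(
        default_factory=default_modality_params
    )
    cognitive_loadings: dict[str, tuple[str, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COGNITIVE_LOADINGS)
    )
    factor_moments: dict[str, GroupMoments] = field(
        default_factory=default_factor_moments
    )
    change_model: dict[str, ChangeParams] = field(default_factory=default_change_model)
    availability: dict[tuple[str, int], float] = field(
        default_factory=default_availability
    )
    ventricle_enabled: bool = True
    ventricle_brightness: float = 1.8  # x ref_mean, in the MT contrast
    background_level: float = 0.6     # x ref_mean outside masks
    age_range_young: tuple[float, float] = (20.0, 35.0)
    age_range_old: tuple[float, float] = (61.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_geometry is None:
            self.roi_geometry = default_roi_geometry(tuple(self.grid_shape))

    @property
    def n_total(self) -> int:
        return self.n_young + self.n_old

    def validate(self) -> None:
        if self.n_young < 0 or self.n_old < 0 or self.n_total == 0:
            raise ConfigError("need at least one participant")
        for name, mp in self.modality_params.items():
            if mp.noise_sd < 0 or mp.ref_mean <= 0:
                raise ConfigError(f"invalid modality parameters for {name!r}")
        for name, gm in self.factor_moments.items():
            gm.validate(name)
        for c, ch in self.change_model.items():
            if ch.variance < 0:
                raise ConfigError(f"negative change variance for {c!r}")
            if ch.variance > 0 and ch.cov_baseline**2 > ch.variance * 4.0:
                raise ConfigError(f"implausible baseline-change covariance for {c!r}")
        for task, (factor, *_rest) in self.cognitive_loadings.items():
            if factor not in COGNITIVE:
                raise ConfigError(f"task {task!r} mapped to unknown factor {factor!r}")
        for key, p in self.availability.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"availability probability out of [0,1] for {key}")
            if key[0] == "fse" and key[1] != 2:
                raise ConfigError("FSE is acquired at TP2 only")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        shape = tuple(self.grid_shape)
        occupied: dict[str, set] = {}
        for name, coords in self.roi_geometry.items():
            coords = np.asarray(coords, dtype=int)
            if coords.ndim != 2 or coords.shape[1] != 3:
                raise ConfigError(f"roi geometry {name!r} must be (k, 3) coordinates")
            if coords.min() < 0 or np.any(coords.max(axis=0) >= np.array(shape)):
                raise ConfigError(f"roi geometry {name!r} exceeds the grid")
            occupied[name] = set(map(tuple, coords))
        for roi in ("lc_left", "lc_right"):
            if occupied[roi] & occupied["pons_ref"]:
                raise ConfigError(f"{roi} overlaps its reference region")
        for roi in ("snvta_left", "snvta_right"):
            if occupied[roi] & occupied["crus_ref"]:
                raise ConfigError(f"{roi} overlaps its reference region")

    def masks(self) -> dict[str, np.ndarray]:
        out = {}
        for name, coords in self.roi_geometry.items():
            arr = np.zeros(tuple(self.grid_shape), dtype=bool)
            coords = np.asarray(coords, dtype=int)
            arr[coords[:, 0], coords[:, 1], coords[:, 2]] = True
            out[name] = arr
        return out

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_young": self.n_young,
            "n_old": self.n_old,
            "grid_shape": list(self.grid_shape),
            "seed": self.seed,
            "ventricle_enabled": self.ventricle_enabled,
            "ventricle_brightness": self.ventricle_brightness,
            "background_level": self.background_level,
            "modality_params": {
                k: vars(v) for k, v in self.modality_params.items()
            },
            "cognitive_loadings": {
                k: list(v) for k, v in self.cognitive_loadings.items()
            },
            "factor_moments": {
                k: {
                    "means": np.asarray(v.means).tolist(),
                    "covariance": np.asarray(v.covariance).tolist(),
                }
                for k, v in self.factor_moments.items()
            },
            "change_model": {k: vars(v) for k, v in self.change_model.items()},
            "availability": {
                f"{mod}:tp{tp}": p for (mod, tp), p in self.availability.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs: dict = {}
        for key in (
            "n_young", "n_old", "seed", "ventricle_enabled",
            "ventricle_brightness", "background_level",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "grid_shape" in d:
            kwargs["grid_shape"] = tuple(d["grid_shape"])
        if "modality_params" in d:
            kwargs["modality_params"] = {
                k: ModalityParams(**v) for k, v in d["modality_params"].items()
            }
        if "cognitive_loadings" in d:
            kwargs["cognitive_loadings"] = {
                k: tuple(v) for k, v in d["cognitive_loadings"].items()
            }
        if "factor_moments" in d:
            kwargs["factor_moments"] = {
                k: GroupMoments(np.asarray(v["means"]), np.asarray(v["covariance"]))
                for k, v in d["factor_moments"].items()
            }
        if "change_model" in d:
            kwargs["change_model"] = {
                k: ChangeParams(**v) for k, v in d["change_model"].items()
            }
        if "availability" in d:
            avail = {}
            for key, p in d["availability"].items():
                mod, tp = key.split(":tp")
                avail[(mod, int(tp))] = float(p)
            kwargs["availability"] = avail
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(d)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
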