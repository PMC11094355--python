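"""Synthetic hyperspectral scenes of corn seeds with known vigor labels.

Real hyperspectral seed data is rarely shareable, so every downstream stage
(calibration, segmentation, preprocessing, classifiers) is exercised on
simulated scenes: elliptical seeds on a dark background, imaged over the
388–1025 nm range in 360 bands, with four vigor classes (HV/MV/LV/NV) whose
mean reflectance curves obey the orderings observed in aged sweet-corn seeds:

* the unaged HV class reflects most across the whole range;
* among the aged classes, LV is highest on average over 400–750 nm while
  MV is highest over 750–1025 nm (LV and NV stay close — the hard pair).

Each seed perturbs its class curve with a multiplicative slope and additive
offset (the scatter family that MSC inverts) plus band-wise Gaussian noise,
and the scene is emitted as raw counts together with dark/white reference
cubes so that black/white calibration is part of the tested path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube import CalibrationRefs, Hypercube, calibrate, write_envi
from .vigor import VIGOR_GRADES, classify_vigor

__all__ = [
    "ClassSpectrumModel",
    "SceneSpec",
    "SyntheticScene",
    "make_class_spectra",
    "render_scene",
    "sample_shoot_lengths",
    "write_scene",
]

WAVELENGTH_MIN_NM = 388.0
WAVELENGTH_MAX_NM = 1025.0
DEFAULT_N_BANDS = 360

# Shoot-length bins per class: (low, high); HV capped at 12 cm for sampling.
_SHOOT_BINS = {"HV": (7.0, 12.0), "MV": (3.0, 7.0), "LV": (1.0, 3.0), "NV": (0.0, 1.0)}


def default_wavelength_grid(n_bands: int = DEFAULT_N_BANDS) -> np.ndarray:
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_bands)


@dataclass
class ClassSpectrumModel:
    """Mean reflectance curve of one vigor class plus its per-seed scatter model.

    ``slope_sd``/``offset_sd`` parameterize the per-seed affine distortion
    reflectance' = offset + slope * mean(λ) with slope ~ N(1, slope_sd²) and
    offset ~ N(0, offset_sd²); ``noise_sd`` is band-wise additive noise.
    """

    label: str
    wavelengths: np.ndarray
    mean_reflectance: np.ndarray
    slope_sd: float = 0.05
    offset_sd: float = 0.02
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.label not in VIGOR_GRADES:
            raise ValueError(f"unknown vigor class {self.label!r}")
        if not np.all((self.mean_reflectance > 0) & (self.mean_reflectance < 1)):
            raise ValueError("mean reflectances must lie in (0, 1)")


def _gaussian_bump(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _band_mean(curve: np.ndarray, wl: np.ndarray, lo: float, hi: float) -> float:
    sel = (wl >= lo) & (wl <= hi)
    return float(curve[sel].mean())


def check_class_ordering(models: dict[str, ClassSpectrumModel]) -> None:
    """Assert the empirical orderings of the four class mean curves."""
    wl = models["HV"].wavelengths
    full = {k: float(m.mean_reflectance.mean()) for k, m in models.items()}
    if not all(full["HV"] > full[k] for k in ("MV", "LV", "NV")):
        raise AssertionError("HV mean curve must dominate on average")
    vis = {k: _band_mean(models[k].mean_reflectance, wl, 400, 750) for k in models}
    nir = {k: _band_mean(models[k].mean_reflectance, wl, 750, 1025) for k in models}
    if not (vis["LV"] > vis["MV"] and vis["LV"] > vis["NV"]):
        raise AssertionError("LV must be highest of the aged classes in 400-750 nm")
    if not (nir["MV"] > nir["LV"] and nir["MV"] > nir["NV"]):
        raise AssertionError("MV must be highest of the aged classes in 750-1025 nm")


# Base curves: smooth ramp + broad Gaussian bumps, amplitudes tuned so the
# class orderings hold with margin even after the seeded +-8% bump jitter.
_CURVE_RECIPES = {
    # label: (base, ramp, [(amplitude, center nm, width nm), ...])
    "HV": (0.50, 0.20, [(0.08, 550.0, 60.0), (0.05, 900.0, 80.0)]),
    "MV": (0.30, 0.22, [(0.04, 560.0, 60.0), (0.08, 900.0, 90.0)]),
    "LV": (0.38, 0.08, [(0.09, 540.0, 70.0), (0.03, 880.0, 80.0)]),
    "NV": (0.33, 0.10, [(0.05, 545.0, 70.0), (0.03, 890.0, 85.0)]),
}


def make_class_spectra(
    rng_seed: int,
    wavelength_grid: np.ndarray | None = None,
    noise_sd: float = 0.01,
) -> dict[str, ClassSpectrumModel]:
    """Generate the four class mean-reflectance curves on a wavelength grid.

    The curves are sums of a smooth ramp and 2–3 broad Gaussian bumps whose
    amplitudes are jittered by the seeded RNG; the class orderings are
    verified numerically on every call.
    """
    wl = default_wavelength_grid() if wavelength_grid is None else np.asarray(
        wavelength_grid, dtype=float
    )
    if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if wl[0] < WAVELENGTH_MIN_NM - 1e-9 or wl[-1] > WAVELENGTH_MAX_NM + 1e-9:
        raise ValueError(
            f"wavelength grid must lie within [{WAVELENGTH_MIN_NM}, "
            f"{WAVELENGTH_MAX_NM}] nm"
        )
    rng = np.random.default_rng(rng_seed)
    t = (wl - WAVELENGTH_MIN_NM) / (WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM)
    models: dict[str, ClassSpectrumModel] = {}
    for label in VIGOR_GRADES:
        base, ramp, bumps = _CURVE_RECIPES[label]
        curve = base + ramp * t
        for amp, center, width in bumps:
            jitter = 1.0 + rng.uniform(-0.08, 0.08)
            curve = curve + amp * jitter * _gaussian_bump(wl, center, width)
        models[label] = ClassSpectrumModel(label, wl, curve, noise_sd=noise_sd)
    check_class_ordering(models)
    return models


@dataclass
class SceneSpec:
    """Geometry of one simulated scene.

    A ``grid_rows x grid_cols`` lattice of elliptical seeds (semi-axes in
    pixels) centered on an ``height x width x n_bands`` cube. Defaults give a
    desk-scale 5x10 = 50-seed scene on a 128x256x360 cube.
    """

    grid_rows: int = 5
    grid_cols: int = 10
    seed_semi_axes: tuple[float, float] = (6.0, 4.5)  # (row, col) semi-axes, px
    height: int = 128
    width: int = 256
    n_bands: int = DEFAULT_N_BANDS
    background_reflectance: float = 0.05
    center_jitter_px: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        pitch_r = self.height / self.grid_rows
        pitch_c = self.width / self.grid_cols
        a, b = self.seed_semi_axes
        if pitch_r < 2 * (a + self.center_jitter_px) or pitch_c < 2 * (
            b + self.center_jitter_px
        ):
            raise ValueError("scene too small for the seed grid without overlap")

    @property
    def n_seeds(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SyntheticScene:
    """Raw + reference cubes, per-pixel label map and ground-truth table."""

    raw: Hypercube
    dark: Hypercube
    white: Hypercube
    label_map: np.ndarray  # 0 = background, 1..n_seeds = seed id
    truth: pd.DataFrame  # seed_id, vigor, shoot_length_cm
    reflectance_truth: np.ndarray = field(repr=False, default=None)

    @property
    def refs(self) -> CalibrationRefs:
        return CalibrationRefs(self.dark.data, self.white.data)

    def calibrated(self) -> Hypercube:
        return calibrate(self.raw, self.refs)


def sample_shoot_lengths(vigor_class: str, n: int, rng_seed: int) -> np.ndarray:
    """Draw shoot lengths (cm) uniformly within the class's bin."""
    if vigor_class not in _SHOOT_BINS:
        raise ValueError(f"unknown vigor class {vigor_class!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = _SHOOT_BINS[vigor_class]
    rng = np.random.default_rng(rng_seed)
    draws = rng.uniform(lo, hi, size=n)
    # uniform() can return its low endpoint; for HV the bin is open at 7
    if vigor_class == "HV":
        draws = np.maximum(draws, np.nextafter(7.0, np.inf))
    return draws


def render_scene(
    spec: SceneSpec,
    models: dict[str, ClassSpectrumModel],
    class_counts: dict[str, int] | None = None,
) -> SyntheticScene:
    """Render a scene: place seeds, apply per-seed scatter, emit raw+ref cubes.

    Raw counts are constructed as ``dark + reflectance * (white - dark) +
    noise`` so that black/white calibration inverts the construction exactly
    when all noise terms are zero.
    """
    if class_counts is None:
        counts = _balanced_counts(spec.n_seeds)
    else:
        counts = dict(class_counts)
    if sum(counts.values()) != spec.n_seeds:
        raise ValueError(
            f"class counts sum to {sum(counts.values())}, grid holds {spec.n_seeds}"
        )
    rng = np.random.default_rng(spec.rng_seed)
    wl = next(iter(models.values())).wavelengths
    if wl.size != spec.n_bands:
        raise ValueError("model wavelength grid does not match spec band count")

    # assign classes to grid cells (seeded shuffle)
    labels = [lab for lab in VIGOR_GRADES for _ in range(counts.get(lab, 0))]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    label_map = np.zeros((spec.height, spec.width), dtype=np.int32)
    pitch_r = spec.height / spec.grid_rows
    pitch_c = spec.width / spec.grid_cols
    a, b = spec.seed_semi_axes
    rows_idx, cols_idx = np.mgrid[0 : spec.height, 0 : spec.width]

    truth_rows = []
    seed_params = []  # (seed_id, label, slope, offset)
    seed_id = 0
    for gr in range(spec.grid_rows):
        for gc in range(spec.grid_cols):
            lab = labels[seed_id]
            seed_id += 1
            cr = (gr + 0.5) * pitch_r + rng.uniform(
                -spec.center_jitter_px, spec.center_jitter_px
            )
            cc = (gc + 0.5) * pitch_c + rng.uniform(
                -spec.center_jitter_px, spec.center_jitter_px
            )
            mask = ((rows_idx - cr) / a) ** 2 + ((cols_idx - cc) / b) ** 2 <= 1.0
            label_map[mask] = seed_id
            model = models[lab]
            slope = 1.0 + model.slope_sd * rng.standard_normal()
            offset = model.offset_sd * rng.standard_normal()
            shoot = _sample_one_length(lab, rng)
            seed_params.append((seed_id, lab, slope, offset))
            truth_rows.append(
                {"seed_id": seed_id, "vigor": lab, "shoot_length_cm": shoot}
            )

    # reflectance cube: background plus per-seed affine-distorted class curve
    refl = np.full(
        (spec.height, spec.width, spec.n_bands),
        spec.background_reflectance,
        dtype=np.float64,
    )
    for sid, lab, slope, offset in seed_params:
        mask = label_map == sid
        refl[mask] = offset + slope * models[lab].mean_reflectance
    noise_sd = next(iter(models.values())).noise_sd
    if noise_sd > 0:
        refl = refl + noise_sd * rng.standard_normal(refl.shape)

    # references: dark current ~100 counts, white panel ~4000 with a smooth
    # band-dependent illumination profile
    t = np.linspace(0.0, 1.0, spec.n_bands)
    illum = 4000.0 * (0.85 + 0.15 * np.sin(np.pi * t))
    dark_level = np.full(spec.n_bands, 100.0)
    dark = np.broadcast_to(dark_level, refl.shape).copy()
    white = np.broadcast_to(illum, refl.shape).copy()
    if noise_sd > 0:
        dark += 2.0 * rng.standard_normal(dark.shape)
        white += 8.0 * rng.standard_normal(white.shape)
    raw = dark_level + refl * (illum - dark_level)

    truth = pd.DataFrame(truth_rows)
    return SyntheticScene(
        raw=Hypercube(raw, wl, domain="raw"),
        dark=Hypercube(dark, wl, domain="raw"),
        white=Hypercube(white, wl, domain="raw"),
        label_map=label_map,
        truth=truth,
        reflectance_truth=refl,
    )


def _sample_one_length(label: str, rng: np.random.Generator) -> float:
    lo, hi = _SHOOT_BINS[label]
    x = float(rng.uniform(lo, hi))
    if label == "HV" and x <= 7.0:
        x = np.nextafter(7.0, np.inf)
    return x


def _balanced_counts(n_seeds: int) -> dict[str, int]:
    base, extra = divmod(n_seeds, 4)
    return {
        lab: base + (1 if i < extra else 0) for i, lab in enumerate(VIGOR_GRADES)
    }


def assign_nearest_class(
    spectrum: np.ndarray, models: dict[str, ClassSpectrumModel]
) -> str:
    """Nearest-class-curve assignment, invariant to per-seed affine scatter.

    For each class curve c, the spectrum s is regressed as s ~ a + b*c and
    the class with the smallest residual sum of squares wins — the matched
    decision rule for the offset+slope scatter family the generator applies.
    """
    best, best_res = None, np.inf
    for label, model in models.items():
        c = model.mean_reflectance
        A = np.stack([np.ones_like(c), c], axis=1)
        _, res, *_ = np.linalg.lstsq(A, spectrum, rcond=None)
        r = float(res[0]) if len(res) else 0.0
        if r < best_res:
            best, best_res = label, r
    return best


def write_scene(scene: SyntheticScene, out_dir, interleave: str = "bsq") -> None:
    """Write a scene as ENVI pairs + truth CSV + a PNG label-map preview."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, cube in (("raw", scene.raw), ("dark", scene.dark), ("white", scene.white)):
        cast = Hypercube(
            cube.data.astype(np.float32), cube.wavelengths, domain=cube.domain
        )
        write_envi(cast, out / f"{name}.hdr", out / f"{name}.img", interleave=interleave)
    scene.truth.assign(
        vigor_check=[classify_vigor(x) for x in scene.truth.shoot_length_cm]
    ).to_csv(out / "truth.csv", index=False)
    _write_label_png(scene.label_map, out / "labels.png")


def _write_label_png(label_map: np.ndarray, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(label_map, cmap="nipy_spectral", interpolation="nearest")
    ax.set_title("seed label map")
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
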