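"""Synthetic NIR spectra of black rice brands.

The study data this package analyses are grain absorbance spectra measured by
Fourier-transform NIR in diffuse reflectance.  The generator emulates their
salient structure rather than the radiative physics: each spectrum is a sum of
Gaussian absorption bands (water combination/overtone bands near 5175 and
6930 cm^-1, C-H bands near 4266/4335 cm^-1 and in the 8200-8600 cm^-1 second
overtone region) subject to

* a per-sample multiplicative scatter factor (particle-size effect),
* a per-sample additive baseline (offset plus a mild linear slope),
* a small relative jitter of band amplitudes (within-brand constituent
  variation), and
* i.i.d. Gaussian instrument noise.

Brands share band positions but differ in amplitude *ratios* — different
balances of constituents, not different chemistry — controlled by a single
``separation`` scale where 0 makes the brands exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "BrandRecipe",
    "default_grid",
    "default_brand_library",
    "simulate_spectra",
    "simulate_study",
    "save_brand_library",
    "load_brand_library",
    "STUDY_CLASS_SIZES",
]

#: Per-brand sample counts of the emulated study design.
STUDY_CLASS_SIZES = {"A": 48, "B": 46, "C": 48}

#: Batch structure of the emulated study (used only when batch effects are on).
STUDY_BATCHES = {"A": (16, 16, 16), "B": (23, 23), "C": (16, 16, 16)}

_GRID_MAX = 10_000.0
_GRID_MIN = 4_000.0
_GRID_POINTS = 1557

# Shared band geometry: C-H stretch/deformation pair, water combination band,
# water/O-H first-overtone band, C-H second-overtone region.
_BAND_CENTERS = np.array([4266.0, 4335.0, 5175.0, 6930.0, 8400.0])
_BAND_WIDTHS = np.array([45.0, 45.0, 130.0, 170.0, 190.0])
_BASE_AMPLITUDES = np.array([0.38, 0.42, 1.20, 0.90, 0.40])

# Relative amplitude offsets per brand at separation = 1 (constituent-ratio
# differences of a few percent, comparable between brands).
_BRAND_DELTAS = {
    "A": np.array([0.00, 0.00, 0.00, 0.00, 0.00]),
    "B": np.array([0.09, -0.06, 0.03, -0.05, 0.12]),
    "C": np.array([-0.08, 0.11, -0.04, 0.06, -0.09]),
}


@dataclass
class BrandRecipe:
    """Generative recipe for one brand's spectra.

    Band amplitudes are in absorbance units; centers and widths (Gaussian
    sigma) in cm^-1.  Baseline offset/slope ranges and the scatter-factor
    range are sampled uniformly per spectrum; ``amplitude_jitter_rel`` is the
    relative s.d. of per-sample band-amplitude jitter; ``noise_sd`` is the
    additive instrument noise s.d. in absorbance units.
    """

    name: str
    band_centers: np.ndarray
    band_amplitudes: np.ndarray
    band_widths: np.ndarray
    baseline_offset_range: tuple[float, float] = (-0.05, 0.05)
    baseline_slope_range: tuple[float, float] = (-0.01, 0.01)
    scatter_factor_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.003
    amplitude_jitter_rel: float = 0.01
    batch_amplitude_sd: float = 0.0
    batch_sizes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        self.band_amplitudes = np.asarray(self.band_amplitudes, dtype=float)
        self.band_widths = np.asarray(self.band_widths, dtype=float)
        if not (
            self.band_centers.shape
            == self.band_amplitudes.shape
            == self.band_widths.shape
        ):
            raise ValueError("band vectors must have equal length")
        if np.any(self.band_widths <= 0):
            raise ValueError("band widths must be positive")
        if np.any(self.band_amplitudes < 0):
            raise ValueError("band amplitudes must be non-negative")
        lo, hi = self.scatter_factor_range
        if not (0 < lo <= hi):
            raise ValueError("scatter_factor_range must lie in (0, inf)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def band_sum(self, grid: np.ndarray) -> np.ndarray:
        """Noise-free pure-component spectrum on ``grid``."""
        nu = np.asarray(grid, dtype=float)[:, None]
        g = np.exp(-((nu - self.band_centers) ** 2) / (2.0 * self.band_widths**2))
        return g @ self.band_amplitudes


def default_grid() -> np.ndarray:
    """The study wavenumber axis: 1557 equally spaced points, 10,000 -> 4,000 cm^-1."""
    return np.linspace(_GRID_MAX, _GRID_MIN, _GRID_POINTS)


def default_brand_library(separation: float = 1.0) -> list[BrandRecipe]:
    """Three brand recipes sharing band positions, differing in amplitude ratios.

    ``separation`` scales the between-brand amplitude offsets; 0 gives three
    identical (exchangeable) brands, 1 the default study conditions.
    """
    recipes = []
    for name in ("A", "B", "C"):
        amps = _BASE_AMPLITUDES * (1.0 + separation * _BRAND_DELTAS[name])
        recipes.append(
            BrandRecipe(
                name=name,
                band_centers=_BAND_CENTERS.copy(),
                band_amplitudes=amps,
                band_widths=_BAND_WIDTHS.copy(),
                batch_sizes=STUDY_BATCHES[name],
            )
        )
    return recipes


def simulate_spectra(
    recipe: BrandRecipe,
    n: int,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> SpectraSet:
    """Draw ``n`` spectra from a brand recipe on ``grid``.

    Each spectrum is ``scatter * (jittered band sum) + offset + slope * t +
    noise`` with ``t`` the 0..1 position along the axis.  Deterministic for a
    fixed integer seed; a Generator may be passed to share a random stream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t = (grid - grid.min()) / max(grid.max() - grid.min(), 1e-12)

    scatter = rng.uniform(*recipe.scatter_factor_range, size=n)
    offset = rng.uniform(*recipe.baseline_offset_range, size=n)
    slope = rng.uniform(*recipe.baseline_slope_range, size=n)
    nbands = recipe.band_centers.size
    jitter = 1.0 + recipe.amplitude_jitter_rel * rng.standard_normal((n, nbands))

    if recipe.batch_amplitude_sd > 0 and recipe.batch_sizes:
        if sum(recipe.batch_sizes) != n:
            raise ValueError("batch_sizes must sum to n when batch effects are on")
        shifts = rng.normal(0.0, recipe.batch_amplitude_sd, size=len(recipe.batch_sizes))
        batch = np.repeat(shifts, recipe.batch_sizes)
        jitter = jitter * (1.0 + batch[:, None])

    nu = grid[:, None]
    bands = np.exp(-((nu - recipe.band_centers) ** 2) / (2.0 * recipe.band_widths**2))
    signal = (jitter * recipe.band_amplitudes) @ bands.T  # (n, p)
    X = (
        scatter[:, None] * signal
        + offset[:, None]
        + slope[:, None] * t[None, :]
        + rng.normal(0.0, recipe.noise_sd, size=(n, grid.size))
    )
    labels = np.full(n, recipe.name)
    ids = np.array([f"{recipe.name}{i + 1:03d}" for i in range(n)])
    return SpectraSet(absorbance=X, wavenumbers=grid, labels=labels, sample_ids=ids)


def save_brand_library(recipes: list[BrandRecipe], path) -> None:
    """Serialize a recipe library to a JSON config file (lists of plain keys)."""
    import json

    payload = []
    for r in recipes:
        d = {
            "name": r.name,
            "band_centers": r.band_centers.tolist(),
            "band_amplitudes": r.band_amplitudes.tolist(),
            "band_widths": r.band_widths.tolist(),
            "baseline_offset_range": list(r.baseline_offset_range),
            "baseline_slope_range": list(r.baseline_slope_range),
            "scatter_factor_range": list(r.scatter_factor_range),
            "noise_sd": r.noise_sd,
            "amplitude_jitter_rel": r.amplitude_jitter_rel,
            "batch_amplitude_sd": r.batch_amplitude_sd,
            "batch_sizes": list(r.batch_sizes),
        }
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_brand_library(path) -> list[BrandRecipe]:
    """Load a recipe library written by :func:`save_brand_library`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    recipes = []
    for d in payload:
        recipes.append(
            BrandRecipe(
                name=d["name"],
                band_centers=d["band_centers"],
                band_amplitudes=d["band_amplitudes"],
                band_widths=d["band_widths"],
                baseline_offset_range=tuple(d["baseline_offset_range"]),
                baseline_slope_range=tuple(d["baseline_slope_range"]),
                scatter_factor_range=tuple(d["scatter_factor_range"]),
                noise_sd=d["noise_sd"],
                amplitude_jitter_rel=d["amplitude_jitter_rel"],
                batch_amplitude_sd=d["batch_amplitude_sd"],
                batch_sizes=tuple(d["batch_sizes"]),
            )
        )
    return recipes


def simulate_study(
    seed: int = 0,
    separation: float = 1.0,
    batch_effects: bool = False,
    batch_amplitude_sd: float = 0.005,
) -> SpectraSet:
    """Generate the full 142-sample study: brands A x 48, B x 46, C x 48.

    All randomness flows from one Generator derived from ``seed``; the grid is
    the default 1557-point axis.  ``batch_effects`` switches on a small
    per-batch amplitude offset mirroring the study's 3/2/3 batch structure.
    """
    rng = np.random.default_rng(seed)
    grid = default_grid()
    parts = []
    for recipe in default_brand_library(separation):
        if batch_effects:
            recipe = replace(recipe, batch_amplitude_sd=batch_amplitude_sd)
        parts.append(
            simulate_spectra(recipe, STUDY_CLASS_SIZES[recipe.name], grid, seed=rng)
        )
    return SpectraSet(
        absorbance=np.vstack([p.absorbance for p in parts]),
        wavenumbers=grid,
        labels=np.concatenate([p.labels for p in parts]),
        sample_ids=np.concatenate([p.sample_ids for p in parts]),
    )
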