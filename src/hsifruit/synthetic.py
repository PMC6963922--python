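"""Synthetic line-scan scenes with known per-fruit origin labels.

Generates raw digital-number hypercubes plus dark/white reference frames by
inverting the reflectance-correction equation: ``raw = dark + r * (white -
dark) + noise``, with three origin classes whose reflectance signatures share
a smooth baseline but differ in the depths of planted Gaussian absorption
features.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cube import Hypercube, ReferenceFrames, WavelengthAxis
from .errors import CapacityError

ORIGIN_NAMES = ("Gansu", "Ningxia", "Xinjiang")

#: absorption-feature centers offered to the signature generator (nm);
#: pairwise separation >= 33 nm so each one is resolvable on the 256-band axis
DEFAULT_FEATURE_CENTERS = (
    995.0, 1056.0, 1089.0, 1136.0, 1190.0, 1244.0,
    1284.0, 1352.0, 1402.0, 1456.0, 1500.0, 1632.0,
)

BACKGROUND_REFLECTANCE = 0.02


@dataclass(frozen=True)
class OriginSignature:
    """Reflectance signature of one origin class on the 256-band axis."""

    origin_id: int
    baseline: np.ndarray
    feature_centers: np.ndarray
    feature_depths: np.ndarray
    feature_widths: np.ndarray
    axis: WavelengthAxis = field(default_factory=WavelengthAxis.default)

    def __post_init__(self) -> None:
        if self.origin_id not in (0, 1, 2):
            raise ValueError(f"unknown origin_id {self.origin_id}; expected 0, 1 or 2")
        lo, hi = self.axis.values[0], self.axis.values[-1]
        centers = np.asarray(self.feature_centers, dtype=float)
        if centers.size and (centers.min() < lo or centers.max() > hi):
            raise ValueError("feature centers must lie within the wavelength axis")
        curve = self.curve()
        if curve.min() <= 0.01 or curve.max() >= 0.99:
            raise ValueError("signature leaves the (0.01, 0.99) reflectance window")

    def curve(self) -> np.ndarray:
        """Reflectance at every band: baseline minus the Gaussian features."""
        lam = self.axis.values
        r = np.asarray(self.baseline, dtype=float).copy()
        for c, d, w in zip(self.feature_centers, self.feature_depths, self.feature_widths):
            r -= d * np.exp(-0.5 * ((lam - c) / w) ** 2)
        return r


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, radiometry and noise knobs for one simulated scene batch."""

    n_fruits_per_class: tuple[int, int, int] = (20, 20, 20)
    fruit_axis_range: tuple[int, int] = (6, 11)
    scene_width: int = 320
    scene_length_L: int = 150
    max_fruits_per_scene: int = 20
    noise_sd_additive: float = 0.02
    illumination_gain_sd: float = 0.005
    fruit_scale_sd: float = 0.03
    dark_level: float = 100.0
    white_level: float = 900.0
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_fruits_per_class):
            raise ValueError("fruit counts must be positive")
        if self.dark_level >= self.white_level:
            raise ValueError("dark_level must be below white_level")
        if self.scene_width <= 0 or self.scene_length_L <= 0:
            raise ValueError("scene dimensions must be positive")


@dataclass
class GroundTruth:
    """Per-pixel fruit ids (0 = background) and the fruit id -> origin map."""

    label_image: np.ndarray
    fruit_origins: dict[int, int]

    def __post_init__(self) -> None:
        ids = np.unique(self.label_image)
        ids = ids[ids > 0]
        expected = np.arange(1, ids.size + 1)
        if not np.array_equal(ids, expected):
            raise ValueError("fruit ids must be contiguous from 1")
        missing = [int(i) for i in ids if int(i) not in self.fruit_origins]
        if missing:
            raise ValueError(f"fruit ids without an origin: {missing}")

    @property
    def n_fruits(self) -> int:
        return len(self.fruit_origins)


def make_signature(
    origin_id: int,
    seed: int,
    feature_centers: tuple[float, ...] = DEFAULT_FEATURE_CENTERS,
    base_depth: float = 0.08,
    separation: float = 1.0,
    axis: WavelengthAxis | None = None,
) -> OriginSignature:
    """Signature for one origin class.

    The baseline and the per-feature base depths/widths are drawn from
    ``seed`` alone (shared across classes); each class then perturbs the
    feature depths by up to ``45% * separation``, so classes overlap heavily
    but stay distinguishable.  ``separation=0`` collapses all classes onto
    the same curve.
    """
    if origin_id not in (0, 1, 2):
        raise ValueError(f"unknown origin_id {origin_id}; expected 0, 1 or 2")
    axis = axis or WavelengthAxis.default()
    lam = axis.values
    shared = np.random.default_rng(seed)
    span = lam[-1] - lam[0]
    phase = shared.uniform(0.0, 2.0 * np.pi)
    mid = lam[0] + span * shared.uniform(0.4, 0.6)
    baseline = (
        0.58
        - 0.10 * ((lam - mid) / span) ** 2
        + 0.05 * np.sin(2.0 * np.pi * (lam - lam[0]) / 600.0 + phase)
    )
    centers = np.asarray(feature_centers, dtype=float)
    base_depths = base_depth * shared.uniform(0.6, 1.4, size=centers.size)
    widths = shared.uniform(7.0, 11.0, size=centers.size)
    # rotating -1/0/+1 pattern guarantees between-class depth spread at every
    # feature; a small random per-class jitter keeps classes from being tidy
    pattern = np.array([-1.0, 0.0, 1.0])
    modifier = pattern[(origin_id + np.arange(centers.size)) % 3]
    perclass = np.random.default_rng([seed, 1 + origin_id])
    jitter = 0.1 * perclass.uniform(-1.0, 1.0, size=centers.size)
    depths = base_depths * (1.0 + separation * (0.35 * modifier + jitter))
    return OriginSignature(
        origin_id=origin_id,
        baseline=baseline,
        feature_centers=centers,
        feature_depths=depths,
        feature_widths=widths,
        axis=axis,
    )


def _place_fruits(rng: np.random.Generator, cfg: SceneConfig, n_fruits: int):
    """Reject-and-retry placement of non-touching axis-aligned ellipses."""
    w, length = cfg.scene_width, cfg.scene_length_L
    lo, hi = cfg.fruit_axis_range
    occupied = np.zeros((w, length), dtype=bool)
    xs = np.arange(w)[:, None]
    ys = np.arange(length)[None, :]
    masks = []
    attempts_per_fruit = 200
    for i in range(n_fruits):
        placed = False
        for _ in range(attempts_per_fruit):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            cx = rng.uniform(a + 1, w - a - 2)
            cy = rng.uniform(b + 1, length - b - 2)
            mask = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
            # dilate by 1 px to enforce a visible gap between fruits
            grown = mask.copy()
            grown[1:] |= mask[:-1]
            grown[:-1] |= mask[1:]
            grown[:, 1:] |= mask[:, :-1]
            grown[:, :-1] |= mask[:, 1:]
            if not (grown & occupied).any():
                occupied |= grown
                masks.append(mask)
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"placed only {i} of {n_fruits} fruits in a "
                f"{w}x{length} scene after {attempts_per_fruit} attempts each; "
                "reduce the fruit count or enlarge the scene"
            )
    return masks


def render_scene(
    signatures: tuple[OriginSignature, OriginSignature, OriginSignature],
    cfg: SceneConfig,
    fruit_origin_sequence: list[int] | None = None,
) -> tuple[Hypercube, np.ndarray, np.ndarray, GroundTruth]:
    """Render one raw scene: cube, per-line dark/white frames, ground truth.

    ``fruit_origin_sequence`` gives the origin of each fruit in placement
    order; by default the configured per-class counts are interleaved.
    """
    axis = signatures[0].axis
    n_bands = len(axis)
    rng = np.random.default_rng(cfg.seed)
    if fruit_origin_sequence is None:
        fruit_origin_sequence = [
            c for c in range(3) for _ in range(cfg.n_fruits_per_class[c])
        ]
    n_fruits = len(fruit_origin_sequence)
    masks = _place_fruits(rng, cfg, n_fruits)

    curves = [s.curve() for s in signatures]
    w, length = cfg.scene_width, cfg.scene_length_L
    refl = np.full((w, length, n_bands), BACKGROUND_REFLECTANCE)
    label_image = np.zeros((w, length), dtype=np.int32)
    fruit_origins: dict[int, int] = {}
    for i, (mask, origin) in enumerate(zip(masks, fruit_origin_sequence), start=1):
        scale = 1.0 + cfg.fruit_scale_sd * rng.standard_normal()
        refl[mask] = np.clip(scale, 0.1, None) * curves[origin]
        label_image[mask] = i
        fruit_origins[i] = int(origin)

    # per-line references with a smooth deterministic spatial/spectral ripple
    col = np.linspace(0.0, 1.0, w)[:, None]
    band = np.linspace(0.0, 1.0, n_bands)[None, :]
    ripple = 0.01 * np.sin(2 * np.pi * (2.0 * col + 1.5 * band) + rng.uniform(0, 2 * np.pi))
    dark = cfg.dark_level * (1.0 + 0.5 * ripple)
    white = cfg.white_level * (1.0 + ripple)

    gain = 1.0 + cfg.illumination_gain_sd * rng.standard_normal(length)
    noisy = refl * gain[None, :, None]
    if cfg.noise_sd_additive > 0:
        noisy = noisy + cfg.noise_sd_additive * rng.standard_normal(refl.shape)
    raw = dark[:, None, :] + noisy * (white - dark)[:, None, :]
    cube = Hypercube(data=raw, axis=axis, kind="raw")
    return cube, dark, white, GroundTruth(label_image=label_image, fruit_origins=fruit_origins)


def plan_dataset(cfg: SceneConfig) -> list[tuple[int, int]]:
    """Scene plan as ``(origin_id, n_fruits)`` chunks, one entry per scene.

    Pure bookkeeping: lets callers verify paper-scale totals without paying
    for the rendering.
    """
    plan: list[tuple[int, int]] = []
    for origin, total in enumerate(cfg.n_fruits_per_class):
        remaining = total
        while remaining > 0:
            take = min(cfg.max_fruits_per_scene, remaining)
            plan.append((origin, take))
            remaining -= take
    return plan


def generate_dataset(
    cfg: SceneConfig, seed: int | None = None
) -> list[tuple[Hypercube, np.ndarray, np.ndarray, GroundTruth]]:
    """Render all scenes for the configured per-class fruit counts.

    One origin per scene (fruits of one batch are imaged together); large
    classes are chunked into scenes of at most ``max_fruits_per_scene``.
    """
    seed = cfg.seed if seed is None else seed
    signatures = tuple(
        make_signature(c, seed, separation=cfg.separation) for c in range(3)
    )
    scene_seeds = np.random.SeedSequence(seed).spawn(len(plan_dataset(cfg)))
    scenes = []
    for (origin, take), ss in zip(plan_dataset(cfg), scene_seeds):
        scene_cfg = replace(cfg, seed=int(ss.generate_state(1)[0]))
        scenes.append(
            render_scene(signatures, scene_cfg, fruit_origin_sequence=[origin] * take)
        )
    return scenes
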