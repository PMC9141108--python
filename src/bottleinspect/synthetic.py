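"""Synthetic bottle-inspection scenes with exact ground truth.

Emulates what a back-lit bottle video contains after the bottle is flipped:
small dark or bright impurities drifting through the liquid (round specks,
1-2 px wide hair-like fibres, irregular glass chips), rising air bubbles
rendered as bright-rim ellipses, static wall stains, stepwise global
illumination changes, and additive Gaussian sensor noise.  Ground truth
(per-frame object masks, class labels, tight boxes) is recorded before noise
is added, so evaluation is against the intended object support.

Particles reflect at the frame bounds and bubbles wrap from top to bottom:
impurities are confined to the bottle and bubble streams are continuous, so
long sequences stay populated.  All randomness comes from one
``numpy.random.default_rng(seed)`` stream; the same config regenerates a
bit-identical sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Literal, Sequence, Tuple

import numpy as np
from skimage import draw as skdraw


class ConfigurationError(ValueError):
    """Raised for invalid scene or pipeline configuration."""


@dataclass
class ParticleSpec:
    """A moving impurity: linear drift plus Gaussian positional jitter."""

    shape_kind: Literal["speck", "hair", "chip"] = "speck"
    polarity: Literal["dark", "bright"] = "dark"
    size: float = 4.0  # characteristic extent in px (disc diameter / hair length / chip diameter)
    start_position: Tuple[float, float] = (10.0, 10.0)  # (row, col)
    velocity: Tuple[float, float] = (1.0, 0.5)  # px/frame (d_row, d_col)
    jitter_sigma: float = 0.0  # px/frame
    contrast: float = 120.0  # gray levels away from the local background
    orientation_deg: float = 0.0  # hair only; 0 = horizontal

    def validate(self) -> None:
        if self.size < 1:
            raise ConfigurationError("particle size must be >= 1 px")
        if self.shape_kind not in ("speck", "hair", "chip"):
            raise ConfigurationError(f"unknown shape_kind {self.shape_kind!r}")
        if self.polarity not in ("dark", "bright"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")


@dataclass
class BubbleSpec:
    """A rising air bubble drawn as a bright-rim ellipse (rim brighter than interior)."""

    radius: float = 5.0  # semi-major axis, px (horizontal)
    eccentricity: float = 0.5  # in [0, 1); 0 = circle
    rise_speed: float = 2.0  # px/frame, upward
    wobble_sigma: float = 0.5  # lateral px/frame
    rim_brightness: float = 60.0  # gray levels added on the rim
    start_position: Tuple[float, float] = (100.0, 50.0)
    rim_thickness: float = 2.0  # px

    def validate(self) -> None:
        if not (0 <= self.eccentricity < 1):
            raise ConfigurationError("eccentricity must lie in [0, 1)")
        if self.radius < 1:
            raise ConfigurationError("bubble radius must be >= 1 px")


@dataclass
class StainSpec:
    """A static wall stain: constant intensity offset, never in ground truth."""

    position: Tuple[int, int] = (30, 30)
    size: float = 5.0
    intensity_offset: float = -40.0


@dataclass
class SceneConfig:
    frame_shape: Tuple[int, int] = (128, 128)
    n_frames: int = 50
    particles: List[ParticleSpec] = field(default_factory=list)
    bubbles: List[BubbleSpec] = field(default_factory=list)
    stains: List[StainSpec] = field(default_factory=list)
    illumination_schedule: List[Tuple[int, float]] = field(default_factory=list)
    noise_sigma: float = 0.0
    background_level: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.frame_shape
        if rows < 16 or cols < 16:
            raise ConfigurationError("frame_shape components must be >= 16")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not (0 <= self.background_level <= 255):
            raise ConfigurationError("background_level must lie in [0, 255]")
        for idx, _ in self.illumination_schedule:
            if not (0 <= idx < self.n_frames):
                raise ConfigurationError("illumination schedule index out of range")
        for p in self.particles:
            p.validate()
        for b in self.bubbles:
            b.validate()


@dataclass
class ObjectRecord:
    object_id: int
    klass: Literal["impurity", "bubble"]
    box: Tuple[int, int, int, int]  # (row_start, row_end, col_start, col_end), half-open


@dataclass
class GroundTruth:
    """Per-frame binary object masks and (id, class, tight box) records."""

    masks: np.ndarray  # (n_frames, rows, cols) bool
    objects: List[List[ObjectRecord]]  # per frame

    def to_json(self) -> str:
        payload = {
            "n_frames": int(self.masks.shape[0]),
            "shape": [int(self.masks.shape[1]), int(self.masks.shape[2])],
            "frames": [
                {
                    "mask_rle": _rle_encode(self.masks[t]),
                    "objects": [asdict(o) for o in self.objects[t]],
                }
                for t in range(self.masks.shape[0])
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        shape = tuple(payload["shape"])
        masks = np.zeros((payload["n_frames"], *shape), dtype=bool)
        objects: List[List[ObjectRecord]] = []
        for t, fr in enumerate(payload["frames"]):
            masks[t] = _rle_decode(fr["mask_rle"], shape)
            objects.append(
                [ObjectRecord(o["object_id"], o["klass"], tuple(o["box"])) for o in fr["objects"]]
            )
        return cls(masks=masks, objects=objects)


def _rle_encode(mask: np.ndarray) -> List[int]:
    """Row-major run lengths, starting with a (possibly zero) background run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:  # convention: first run is background
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: Sequence[int], shape: Tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


# ---------------------------------------------------------------------------
# rendering


def _paint(frame: np.ndarray, rr: np.ndarray, cc: np.ndarray, value: float) -> Tuple[np.ndarray, np.ndarray]:
    rows, cols = frame.shape
    keep = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
    rr, cc = rr[keep], cc[keep]
    frame[rr, cc] = value
    return rr, cc


def _particle_pixels(spec: ParticleSpec, position: Tuple[float, float],
                     chip_vertices: np.ndarray | None = None) -> Tuple[np.ndarray, np.ndarray]:
    r0, c0 = position
    if spec.shape_kind == "speck":
        return skdraw.disk((r0, c0), max(spec.size / 2.0, 0.5))
    if spec.shape_kind == "hair":
        theta = np.deg2rad(spec.orientation_deg)
        half = (spec.size - 1) / 2.0
        dr, dc = half * np.sin(theta), half * np.cos(theta)
        rr1, cc1 = skdraw.line(int(round(r0 - dr)), int(round(c0 - dc)),
                               int(round(r0 + dr)), int(round(c0 + dc)))
        # thicken to 2 px across the segment
        rr2, cc2 = rr1 + (1 if abs(dc) >= abs(dr) else 0), cc1 + (0 if abs(dc) >= abs(dr) else 1)
        return np.concatenate([rr1, rr2]), np.concatenate([cc1, cc2])
    # chip: irregular polygon, fixed vertex pattern scaled to size
    verts = chip_vertices if chip_vertices is not None else _DEFAULT_CHIP
    rr, cc = skdraw.polygon(r0 + verts[:, 0] * spec.size / 2.0,
                            c0 + verts[:, 1] * spec.size / 2.0)
    if rr.size == 0:  # tiny polygons can rasterise to nothing; paint the centre
        rr, cc = skdraw.disk((r0, c0), max(spec.size / 2.0, 0.5))
    return rr, cc


# unit-diameter irregular pentagon used when no per-particle vertices are drawn
_DEFAULT_CHIP = np.array(
    [[-1.0, -0.3], [-0.4, 1.0], [0.8, 0.7], [1.0, -0.4], [0.1, -1.0]]
)


def render_object(spec, position: Tuple[float, float], frame: np.ndarray,
                  background_level: float | None = None,
                  chip_vertices: np.ndarray | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Paint one object onto ``frame`` in place; returns its painted (rr, cc).

    Particles paint ``background ± contrast`` per polarity; bubbles paint a
    bright elliptical rim of ``rim_brightness`` above the local level.
    Clipping at frame borders is silent.
    """
    bg = float(np.median(frame)) if background_level is None else float(background_level)
    if isinstance(spec, BubbleSpec):
        ry = spec.radius * np.sqrt(1.0 - spec.eccentricity**2)  # vertical semi-axis
        rx = spec.radius
        rr_o, cc_o = skdraw.ellipse(position[0], position[1], max(ry, 0.8), max(rx, 0.8))
        t = spec.rim_thickness
        inner = np.zeros(frame.shape, dtype=bool)
        if ry - t > 0.5 and rx - t > 0.5:
            rr_i, cc_i = skdraw.ellipse(position[0], position[1], ry - t, rx - t)
            keep = (rr_i >= 0) & (rr_i < frame.shape[0]) & (cc_i >= 0) & (cc_i < frame.shape[1])
            inner[rr_i[keep], cc_i[keep]] = True
        keep = (rr_o >= 0) & (rr_o < frame.shape[0]) & (cc_o >= 0) & (cc_o < frame.shape[1])
        rr_o, cc_o = rr_o[keep], cc_o[keep]
        rim = ~inner[rr_o, cc_o]
        rr, cc = rr_o[rim], cc_o[rim]
        frame[rr, cc] = np.clip(bg + spec.rim_brightness, 0, 255)
        return rr, cc
    value = bg - spec.contrast if spec.polarity == "dark" else bg + spec.contrast
    rr, cc = _particle_pixels(spec, position, chip_vertices)
    return _paint(frame, rr.astype(int), cc.astype(int), np.clip(value, 0, 255))


def illumination_step(frames: np.ndarray, schedule: Sequence[Tuple[int, float]]) -> np.ndarray:
    """Add each scheduled global offset to every frame from its index onward.

    Offsets compose additively; results clamp to [0, 255]. Ground truth is
    unaffected (a light change moves no object).
    """
    out = frames.astype(np.float64, copy=True)
    for idx, off in schedule:
        out[idx:] += off
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _reflect(pos: float, vel: float, lo: float, hi: float) -> Tuple[float, float]:
    """Reflect a coordinate into [lo, hi], flipping the velocity on a bounce."""
    if hi <= lo:
        return (lo + hi) / 2.0, vel
    span = hi - lo
    x = pos - lo
    period = 2.0 * span
    x = x % period
    if x > span:
        x = period - x
        vel = -vel
    return x + lo, vel


def generate_sequence(config: SceneConfig) -> Tuple[np.ndarray, GroundTruth]:
    """Render the configured scene.

    Returns ``(frames, ground_truth)`` where frames is a
    ``(n_frames, rows, cols)`` uint8 array.  Per frame: background + stains,
    then bubbles and particles on top, then the cumulative illumination
    offset; ground truth is captured at that point; i.i.d. Gaussian noise of
    ``noise_sigma`` is added last and the result clamps to [0, 255].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.frame_shape
    n = config.n_frames

    # static plate: background + stains
    plate = np.full((rows, cols), float(config.background_level))
    for st in config.stains:
        rr, cc = skdraw.disk(st.position, max(st.size / 2.0, 0.5))
        _paint(plate, rr, cc, np.clip(config.background_level + st.intensity_offset, 0, 255))

    # per-chip irregular vertices, drawn once so the shape is rigid
    chip_verts = []
    for p in config.particles:
        if p.shape_kind == "chip":
            ang = np.sort(rng.uniform(0, 2 * np.pi, 5))
            rad = rng.uniform(0.6, 1.0, 5)
            chip_verts.append(np.column_stack([rad * np.sin(ang), rad * np.cos(ang)]))
        else:
            chip_verts.append(None)

    p_pos = [np.array(p.start_position, dtype=float) for p in config.particles]
    p_vel = [np.array(p.velocity, dtype=float) for p in config.particles]
    b_pos = [np.array(b.start_position, dtype=float) for b in config.bubbles]

    offsets = np.zeros(n)
    for idx, off in config.illumination_schedule:
        offsets[idx:] += off

    frames = np.empty((n, rows, cols), dtype=np.uint8)
    masks = np.zeros((n, rows, cols), dtype=bool)
    objects: List[List[ObjectRecord]] = []

    for t in range(n):
        frame = plate.copy()
        recs: List[ObjectRecord] = []
        oid = 0
        for bi, b in enumerate(config.bubbles):
            rr, cc = render_object(b, tuple(b_pos[bi]), frame,
                                   background_level=config.background_level)
            if rr.size:
                recs.append(ObjectRecord(oid, "bubble", _tight_box(rr, cc)))
                masks[t, rr, cc] = True
            oid += 1
        for pi, p in enumerate(config.particles):
            rr, cc = render_object(p, tuple(p_pos[pi]), frame,
                                   background_level=config.background_level,
                                   chip_vertices=chip_verts[pi])
            if rr.size:
                recs.append(ObjectRecord(oid, "impurity", _tight_box(rr, cc)))
                masks[t, rr, cc] = True
            oid += 1
        objects.append(recs)

        frame = np.clip(frame + offsets[t], 0, 255)
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, size=frame.shape)
        frames[t] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

        # advance motion state for the next frame
        for pi, p in enumerate(config.particles):
            step = p_vel[pi].copy()
            if p.jitter_sigma > 0:
                step += rng.normal(0.0, p.jitter_sigma, size=2)
            p_pos[pi] = p_pos[pi] + step
            margin = p.size / 2.0 + 1.0
            p_pos[pi][0], p_vel[pi][0] = _reflect(p_pos[pi][0], p_vel[pi][0], margin, rows - 1 - margin)
            p_pos[pi][1], p_vel[pi][1] = _reflect(p_pos[pi][1], p_vel[pi][1], margin, cols - 1 - margin)
        for bi, b in enumerate(config.bubbles):
            b_pos[bi][0] -= b.rise_speed
            if b.wobble_sigma > 0:
                b_pos[bi][1] += rng.normal(0.0, b.wobble_sigma)
            b_pos[bi][1] = float(np.clip(b_pos[bi][1], b.radius + 1, cols - 2 - b.radius))
            if b_pos[bi][0] < -b.radius:  # left through the top: wrap to below the bottom
                b_pos[bi][0] += rows + 2 * b.radius

    return frames, GroundTruth(masks=masks, objects=objects)


def _tight_box(rr: np.ndarray, cc: np.ndarray) -> Tuple[int, int, int, int]:
    return (int(rr.min()), int(rr.max()) + 1, int(cc.min()), int(cc.max()) + 1)


def write_sequence(frames: np.ndarray, directory, ground_truth: GroundTruth | None = None,
                   write_mask_pngs: bool = False) -> None:
    """Write frames as zero-padded 8-bit grayscale PNGs plus ground-truth JSON."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(frames.shape[0]):
        iio.imwrite(directory / f"frame_{t:06d}.png", frames[t])
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(ground_truth.to_json())
        if write_mask_pngs:
            mdir = directory / "masks"
            mdir.mkdir(exist_ok=True)
            for t in range(frames.shape[0]):
                iio.imwrite(mdir / f"mask_{t:06d}.png",
                            (ground_truth.masks[t] * 255).astype(np.uint8))


def read_sequence(directory) -> np.ndarray:
    """Read a lexicographically sorted PNG/TIFF frame directory as (n, rows, cols) uint8."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no frame images found in {directory}")
    frames = []
    for p in paths:
        try:
            img = iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise IOError(f"unreadable frame {p}") from exc
        if img.ndim == 3:
            img = img[..., 0]
        frames.append(img.astype(np.uint8))
    return np.stack(frames)
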