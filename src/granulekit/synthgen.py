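"""Synthetic confocal-field generator with full ground truth.

The generator emulates the statistical structure of single-plane confocal
acquisitions of neuronal somata: cell bodies whose cytoplasm appears as a
bright ring around a dark nuclear void, near-diffraction-limited RNP
granules rendered as isotropic 2D Gaussian puncta over the diffuse
cytoplasmic pool, registered smFISH spot channels with a controlled
in-granule fraction, decondensation time-lapses in which the granule
partition coefficient relaxes exponentially after a stimulus frame, and
GCaMP-style calcium traces.  Every stochastic choice is recorded in a
:class:`GroundTruth` object sufficient to recompute the expected value of
every downstream measurement without the rendered image.

The default scene packs somata densely so that cytoplasm is the majority
phase of the field, matching the crowded cell-body fields the analysis is
designed for (see docs/methods.md for why this matters to the cytoplasm
mask).  Granule and noise defaults are chosen for detector testability:
the rendered intensity scales of the emulated acquisitions are free
parameters, as only processed ratios of them are ever reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import yaml

from .image import DEFAULT_PIXEL_SIZE, ImageField
from .traces import CalciumTrace

__all__ = [
    "SceneError",
    "CellRing",
    "GranuleTruth",
    "SpotTruth",
    "SceneSpec",
    "KineticsSpec",
    "GroundTruth",
    "generate_field",
    "generate_timelapse",
    "generate_smfish_pair",
    "generate_calcium_trace",
    "random_scene",
    "save_scene",
]


class SceneError(ValueError):
    """A scene specification violates its invariants."""


@dataclass(frozen=True)
class CellRing:
    """One soma: a cytoplasmic annulus around a dark nuclear disk."""

    center: tuple[float, float]  # (row, col), px
    inner_radius: float  # nucleus radius, px
    outer_radius: float  # soma radius, px

    def validate(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise SceneError(
                f"cell ring requires 0 < inner_radius < outer_radius, "
                f"got ({self.inner_radius}, {self.outer_radius})"
            )

    def contains_in_ring(self, point: tuple[float, float]) -> bool:
        d = np.hypot(point[0] - self.center[0], point[1] - self.center[1])
        return self.inner_radius <= d <= self.outer_radius

    def in_nucleus(self, point: tuple[float, float]) -> bool:
        d = np.hypot(point[0] - self.center[0], point[1] - self.center[1])
        return d < self.inner_radius


@dataclass(frozen=True)
class GranuleTruth:
    """Ground truth for one granule: an isotropic 2D Gaussian punctum.

    The true partition coefficient of a noise-free granule is
    ``(cytoplasm_level + amplitude) / cytoplasm_level``.
    """

    center: tuple[float, float]  # (row, col), px
    sigma: float = 1.5  # Gaussian radius parameter, raw px
    amplitude: float = 300.0  # intensity above the local cytoplasm level

    def validate(self) -> None:
        if self.sigma <= 0:
            raise SceneError(f"granule sigma must be > 0, got {self.sigma}")
        if self.amplitude <= 0:
            raise SceneError(f"granule amplitude must be > 0, got {self.amplitude}")

    def true_partition(self, cytoplasm_level: float) -> float:
        return (cytoplasm_level + self.amplitude) / cytoplasm_level


@dataclass(frozen=True)
class SpotTruth:
    """Ground truth for one RNA spot."""

    row: float
    col: float
    in_granule: bool


@dataclass
class SceneSpec:
    """Geometry, intensity levels and noise of one synthetic field."""

    field_shape: tuple[int, int] = (256, 256)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    cells: list[CellRing] = dc_field(default_factory=list)
    cytoplasm_level: float = 200.0
    background_level: float = 40.0  # outside cells and inside nuclei
    granules: list[GranuleTruth] = dc_field(default_factory=list)
    noise_gaussian_sd: float = 0.0
    noise_poisson_gain: float = 0.0  # 0 disables shot noise
    bit_depth: int = 16

    def validate(self) -> None:
        if len(self.field_shape) != 2 or min(self.field_shape) < 8:
            raise SceneError(f"field_shape must be 2D and >= 8 px, got {self.field_shape}")
        for lvl, name in [
            (self.cytoplasm_level, "cytoplasm_level"),
            (self.background_level, "background_level"),
            (self.noise_gaussian_sd, "noise_gaussian_sd"),
            (self.noise_poisson_gain, "noise_poisson_gain"),
        ]:
            if lvl < 0:
                raise SceneError(f"{name} must be >= 0, got {lvl}")
        if self.bit_depth not in (16, 32):
            raise SceneError(f"bit_depth must be 16 or 32, got {self.bit_depth}")
        for cell in self.cells:
            cell.validate()
        for g in self.granules:
            g.validate()
            if not self._in_cytoplasm(g.center):
                raise SceneError(
                    f"granule at {g.center} lies outside every cytoplasmic ring"
                )

    def _in_cytoplasm(self, point: tuple[float, float]) -> bool:
        if not any(c.contains_in_ring(point) for c in self.cells):
            return False
        return not any(c.in_nucleus(point) for c in self.cells)

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class KineticsSpec:
    """Exponential relaxation of the granule partition coefficient.

    Before the stimulus frame the partition coefficient is
    ``initial_partition``; from the stimulus frame onwards it follows

        rho(t) = final + (initial - final) * exp(-k * (t - stimulus_frame))

    which emulates progressive granule decondensation after treatment.
    """

    n_frames: int
    stimulus_frame: int
    initial_partition: float
    final_partition: float
    rate_k: float  # per frame
    frame_interval: float = 30.0  # seconds

    def validate(self) -> None:
        if not 0 <= self.stimulus_frame < self.n_frames:
            raise SceneError(
                f"stimulus_frame {self.stimulus_frame} must lie in [0, {self.n_frames})"
            )
        if not self.initial_partition >= self.final_partition >= 1.0:
            raise SceneError(
                "kinetics require initial_partition >= final_partition >= 1; got "
                f"({self.initial_partition}, {self.final_partition})"
            )
        if self.rate_k < 0:
            raise SceneError(f"rate_k must be >= 0, got {self.rate_k}")

    def partition_at(self, frame: int) -> float:
        """Closed-form rho(t) of the decondensation law."""
        if frame < self.stimulus_frame:
            return self.initial_partition
        return self.final_partition + (self.initial_partition - self.final_partition) * float(
            np.exp(-self.rate_k * (frame - self.stimulus_frame))
        )


@dataclass
class GroundTruth:
    """Everything needed to recompute expected measurements without pixels.

    ``granules`` is a flat list for single fields and a per-frame list of
    lists for time-lapses.
    """

    granules: list[GranuleTruth] | list[list[GranuleTruth]]
    spots: list[SpotTruth] = dc_field(default_factory=list)
    kinetics: KineticsSpec | None = None
    seed: int | None = None
    cytoplasm_level: float = 200.0

    def true_partitions(self) -> np.ndarray:
        """True partition coefficient of every granule (single-field truth)."""
        if self.granules and isinstance(self.granules[0], list):
            raise ValueError("use kinetics.partition_at for time-lapse truth")
        return np.array([g.true_partition(self.cytoplasm_level) for g in self.granules])

    @property
    def n_spots_in_granules(self) -> int:
        return sum(s.in_granule for s in self.spots)


# ---------------------------------------------------------------------------
# rendering


def _template(spec: SceneSpec) -> np.ndarray:
    """Noise-free cell template: background, cytoplasm union, dark nuclei."""
    h, w = spec.field_shape
    rr, cc = np.mgrid[0:h, 0:w]
    img = np.full((h, w), spec.background_level, dtype=float)
    in_soma = np.zeros((h, w), dtype=bool)
    in_nucleus = np.zeros((h, w), dtype=bool)
    for cell in spec.cells:
        d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
        in_soma |= d2 <= cell.outer_radius**2
        in_nucleus |= d2 < cell.inner_radius**2
    img[in_soma] = spec.cytoplasm_level
    img[in_nucleus] = spec.background_level  # nuclear void
    return img


def _add_gaussians(
    img: np.ndarray,
    puncta: Sequence[GranuleTruth],
    truncate: float = 5.0,
) -> None:
    """Add isotropic Gaussian puncta in place (local patches for speed)."""
    h, w = img.shape
    for g in puncta:
        r0, c0 = g.center
        ext = int(np.ceil(truncate * g.sigma))
        ra, rb = max(0, int(np.floor(r0)) - ext), min(h, int(np.ceil(r0)) + ext + 1)
        ca, cb = max(0, int(np.floor(c0)) - ext), min(w, int(np.ceil(c0)) + ext + 1)
        rr, cc = np.mgrid[ra:rb, ca:cb]
        img[ra:rb, ca:cb] += g.amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * g.sigma**2)
        )


def _finish(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply noise and clip to the declared bit depth (camera saturation)."""
    if spec.noise_poisson_gain > 0:
        img = rng.poisson(np.clip(img, 0, None) / spec.noise_poisson_gain) * spec.noise_poisson_gain
        img = img.astype(float)
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise_gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, spec.max_value)


def _render(spec: SceneSpec, granules: Sequence[GranuleTruth], rng: np.random.Generator,
            extra: Sequence[GranuleTruth] = ()) -> ImageField:
    img = _template(spec)
    _add_gaussians(img, granules)
    if extra:
        _add_gaussians(img, extra)
    img = _finish(img, spec, rng)
    return ImageField(img, pixel_size=spec.pixel_size, bit_depth=spec.bit_depth)


def generate_field(spec: SceneSpec, seed: int) -> tuple[ImageField, GroundTruth]:
    """Render one field: template + granule Gaussians + noise, with truth.

    Deterministic for a given ``(spec, seed)``.  Granule centers outside
    every cytoplasmic ring are rejected at validation.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    fld = _render(spec, spec.granules, rng)
    fld = replace(fld, channel="granules")
    gt = GroundTruth(
        granules=list(spec.granules), seed=seed, cytoplasm_level=spec.cytoplasm_level
    )
    return fld, gt


def generate_timelapse(
    spec: SceneSpec, kinetics: KineticsSpec, seed: int, conserve_total: bool = False
) -> tuple[list[ImageField], GroundTruth]:
    """Render a decondensation time-lapse sharing one cell geometry.

    At frame ``t`` every granule's amplitude is set so that its noise-free
    partition coefficient equals the closed-form trajectory ``rho(t)``:
    ``amplitude(t) = (rho(t) - 1) * cytoplasm(t)``.

    With ``conserve_total=False`` (default) the cytoplasm level is
    constant and the trajectory is exact but total intensity drops as
    granules dim.  With ``conserve_total=True`` the intensity released by
    decondensing granules is redistributed uniformly over the cytoplasm,
    so the noise-free integrated intensity of every frame is equal (up to
    Gaussian truncation) while each granule still satisfies ``rho(t)``
    against the adjusted cytoplasm level.
    """
    spec.validate()
    kinetics.validate()
    rng = np.random.default_rng(seed)
    frames: list[ImageField] = []
    truth_frames: list[list[GranuleTruth]] = []

    n_cyto_px = None
    if conserve_total:
        template = _template(spec)
        n_cyto_px = int(np.sum(template == spec.cytoplasm_level))
        if n_cyto_px == 0:
            raise SceneError("conserve_total requires a cytoplasm region")

    flux = 2.0 * np.pi * sum(g.sigma**2 for g in spec.granules)  # per unit amplitude
    rho0 = kinetics.partition_at(0)
    for t in range(kinetics.n_frames):
        rho_t = kinetics.partition_at(t)
        if conserve_total:
            # cytoplasm level solving total-intensity conservation:
            # (N_px + flux*(rho(t)-1)) * c(t) = (N_px + flux*(rho0-1)) * c0
            cyto_t = (
                spec.cytoplasm_level
                * (n_cyto_px + flux * (rho0 - 1.0))
                / (n_cyto_px + flux * (rho_t - 1.0))
            )
        else:
            cyto_t = spec.cytoplasm_level
        amp = (rho_t - 1.0) * cyto_t
        granules_t = [replace(g, amplitude=amp) for g in spec.granules]
        spec_t = replace_spec_level(spec, cyto_t) if conserve_total else spec
        fld = _render(spec_t, granules_t, rng)
        frames.append(replace(fld, channel="granules"))
        truth_frames.append(granules_t)
    gt = GroundTruth(
        granules=truth_frames,
        kinetics=kinetics,
        seed=seed,
        cytoplasm_level=spec.cytoplasm_level,
    )
    return frames, gt


def replace_spec_level(spec: SceneSpec, cytoplasm_level: float) -> SceneSpec:
    """Copy of a scene with a different cytoplasm level (granules kept)."""
    out = replace(spec, cytoplasm_level=cytoplasm_level)
    return out


def generate_smfish_pair(
    spec: SceneSpec,
    n_spots: int,
    in_granule_fraction: float,
    seed: int,
    spot_sigma: float = 1.0,
    spot_amplitude: float = 400.0,
    min_spot_separation: float = 6.0,
    clearance: float | None = None,
) -> tuple[ImageField, ImageField, GroundTruth]:
    """Render registered granule and smFISH channels with known overlap.

    Exactly ``round(n_spots * in_granule_fraction)`` spots are placed at
    granule centers (at most one per granule); the remainder go to
    granule-free cytoplasm, at least ``clearance`` px (default
    ``max(3 * granule sigma, 5)``) away from every granule center and
    ``min_spot_separation`` px from each other so the spot detector can
    resolve them.
    """
    spec.validate()
    if not 0.0 <= in_granule_fraction <= 1.0:
        raise SceneError(f"in_granule_fraction must be in [0, 1], got {in_granule_fraction}")
    n_in = int(round(n_spots * in_granule_fraction))
    if in_granule_fraction > 0 and not spec.granules:
        raise SceneError("in_granule_fraction > 0 requires a scene with granules")
    if n_in > len(spec.granules):
        raise SceneError(
            f"{n_in} in-granule spots requested but only {len(spec.granules)} granules "
            "available (one spot per granule)"
        )
    rng = np.random.default_rng(seed)

    granule_field = _render(spec, spec.granules, rng)
    granule_field = replace(granule_field, channel="granules")

    if clearance is None:
        gsig = max((g.sigma for g in spec.granules), default=1.5)
        clearance = max(3.0 * gsig, 5.0)

    spots: list[SpotTruth] = []
    # in-granule spots: at the centers of a random granule subset
    chosen = rng.permutation(len(spec.granules))[:n_in]
    for idx in chosen:
        r, c = spec.granules[idx].center
        spots.append(SpotTruth(float(r), float(c), True))

    # free-cytoplasm spots: rejection-sampled integer positions
    n_out = n_spots - n_in
    h, w = spec.field_shape
    centers = np.array([g.center for g in spec.granules], dtype=float).reshape(-1, 2)
    placed = np.array([[s.row, s.col] for s in spots], dtype=float).reshape(-1, 2)
    tries = 0
    max_tries = 20000 * max(n_out, 1)
    while len(spots) < n_spots:
        tries += 1
        if tries > max_tries:
            raise SceneError(
                "could not place all free-cytoplasm spots; scene too crowded for "
                f"{n_spots} spots with separation {min_spot_separation}"
            )
        p = (float(rng.integers(2, h - 2)), float(rng.integers(2, w - 2)))
        if not spec._in_cytoplasm(p):
            continue
        if centers.size and np.min(np.hypot(*(centers - p).T)) <= clearance:
            continue
        if placed.size and np.min(np.hypot(*(placed - p).T)) < min_spot_separation:
            continue
        spots.append(SpotTruth(p[0], p[1], False))
        placed = np.vstack([placed, p])

    spot_truth = [
        GranuleTruth(center=(s.row, s.col), sigma=spot_sigma, amplitude=spot_amplitude)
        for s in spots
    ]
    spot_img = _template(spec)
    _add_gaussians(spot_img, spot_truth)
    spot_field = ImageField(
        _finish(spot_img, spec, rng),
        pixel_size=spec.pixel_size,
        channel="smFISH",
        bit_depth=spec.bit_depth,
    )
    gt = GroundTruth(
        granules=list(spec.granules),
        spots=spots,
        seed=seed,
        cytoplasm_level=spec.cytoplasm_level,
    )
    return granule_field, spot_field, gt


def generate_calcium_trace(
    baseline: float,
    peak_delta: float,
    peak_frame: int,
    decay_rate: float,
    plateau_delta: float,
    n_frames: int,
    noise_sd: float,
    seed: int,
    stimulus_frame: int = 4,
    frame_interval: float = 30.0,
) -> CalciumTrace:
    """Simulate a GCaMP-style ROI-mean intensity trace.

    Noise-free shape: constant ``baseline`` before the stimulus frame, a
    linear rise from stimulus to peak, then
    ``baseline + plateau_delta + (peak_delta - plateau_delta) * exp(-decay_rate * (t - peak_frame))``,
    emulating a calcium transient peaking minutes after treatment with a
    dose-dependent long-term plateau.
    """
    if baseline <= 0:
        raise SceneError("baseline must be > 0 (dF/F undefined otherwise)")
    if not 0 <= stimulus_frame <= peak_frame < n_frames:
        raise SceneError(
            f"need 0 <= stimulus_frame <= peak_frame < n_frames, got "
            f"({stimulus_frame}, {peak_frame}, {n_frames})"
        )
    t = np.arange(n_frames, dtype=float)
    trace = np.full(n_frames, baseline, dtype=float)
    if peak_frame > stimulus_frame:
        ramp = (t >= stimulus_frame) & (t <= peak_frame)
        trace[ramp] = baseline + peak_delta * (t[ramp] - stimulus_frame) / (
            peak_frame - stimulus_frame
        )
    else:
        trace[peak_frame] = baseline + peak_delta
    post = t > peak_frame
    trace[post] = (
        baseline
        + plateau_delta
        + (peak_delta - plateau_delta) * np.exp(-decay_rate * (t[post] - peak_frame))
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    trace = np.clip(trace, 1e-9, None)
    return CalciumTrace(values=trace, frame_interval=frame_interval, stimulus_frame=stimulus_frame)


# ---------------------------------------------------------------------------
# scene builders


def _packed_cells(field_shape: tuple[int, int]) -> list[CellRing]:
    """Six overlapping somata tiling the field, cytoplasm as majority phase."""
    h, w = field_shape
    rows = [h * 0.27, h * 0.73]
    cols = [w * 0.18, w * 0.5, w * 0.82]
    outer = 0.26 * min(h, w) * 1.15
    inner = outer * 0.42
    return [CellRing((r, c), inner, outer) for r in rows for c in cols]


def random_scene(
    n_granules: int,
    seed: int,
    field_shape: tuple[int, int] = (256, 256),
    amplitude_range: tuple[float, float] = (150.0, 450.0),
    sigma: float = 1.5,
    min_separation: float = 6.0,
    cytoplasm_level: float = 200.0,
    background_level: float = 40.0,
    noise_gaussian_sd: float = 0.0,
    noise_poisson_gain: float = 0.0,
    cells: list[CellRing] | None = None,
) -> SceneSpec:
    """Build a packed-soma scene with granules placed at random.

    Granule centers are integer pixels inside cytoplasm, pairwise at least
    ``min_separation`` px apart; amplitudes are uniform over
    ``amplitude_range`` (partition coefficients 1.75-3.25 at the default
    levels, the magnitude the measured granules span).
    """
    rng = np.random.default_rng(seed)
    spec = SceneSpec(
        field_shape=field_shape,
        cells=cells if cells is not None else _packed_cells(field_shape),
        cytoplasm_level=cytoplasm_level,
        background_level=background_level,
        noise_gaussian_sd=noise_gaussian_sd,
        noise_poisson_gain=noise_poisson_gain,
    )
    h, w = field_shape
    margin = int(np.ceil(4 * sigma))
    placed: list[tuple[float, float]] = []
    granules: list[GranuleTruth] = []
    tries = 0
    max_tries = 50000 * max(n_granules, 1)
    while len(granules) < n_granules:
        tries += 1
        if tries > max_tries:
            raise SceneError(
                f"could not place {n_granules} granules with separation {min_separation}"
            )
        p = (float(rng.integers(margin, h - margin)), float(rng.integers(margin, w - margin)))
        if not spec._in_cytoplasm(p):
            continue
        if placed and min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in placed) < min_separation:
            continue
        amp = float(rng.uniform(*amplitude_range))
        granules.append(GranuleTruth(center=p, sigma=sigma, amplitude=amp))
        placed.append(p)
    spec.granules = granules
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# sidecar I/O


def save_scene(
    out_dir,
    spec: SceneSpec,
    gt: GroundTruth,
    fields: ImageField | Sequence[ImageField],
) -> None:
    """Write TIFF image(s) plus CSV/YAML ground-truth sidecars."""
    import os

    from .image import write_tiff

    os.makedirs(out_dir, exist_ok=True)
    write_tiff(os.path.join(out_dir, "field.tif"), fields)

    rows = []
    if gt.granules and isinstance(gt.granules[0], list):
        for frame_idx, frame_granules in enumerate(gt.granules):
            for g in frame_granules:
                rows.append((frame_idx, g.center[0], g.center[1], g.sigma, g.amplitude, ""))
    else:
        for g in gt.granules:
            rows.append((0, g.center[0], g.center[1], g.sigma, g.amplitude, ""))
    for s in gt.spots:
        rows.append((0, s.row, s.col, "", "", int(s.in_granule)))
    import csv

    with open(os.path.join(out_dir, "ground_truth.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "row", "col", "sigma", "amplitude", "in_granule"])
        writer.writerows(rows)

    meta = {
        "seed": gt.seed,
        "field_shape": list(spec.field_shape),
        "pixel_size": spec.pixel_size,
        "cytoplasm_level": spec.cytoplasm_level,
        "background_level": spec.background_level,
        "noise_gaussian_sd": spec.noise_gaussian_sd,
        "noise_poisson_gain": spec.noise_poisson_gain,
        "bit_depth": spec.bit_depth,
        "cells": [
            {"center": list(c.center), "inner_radius": c.inner_radius, "outer_radius": c.outer_radius}
            for c in spec.cells
        ],
    }
    if gt.kinetics is not None:
        k = gt.kinetics
        meta["kinetics"] = {
            "n_frames": k.n_frames,
            "stimulus_frame": k.stimulus_frame,
            "initial_partition": k.initial_partition,
            "final_partition": k.final_partition,
            "rate_k": k.rate_k,
            "frame_interval": k.frame_interval,
        }
    with open(os.path.join(out_dir, "scene.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
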