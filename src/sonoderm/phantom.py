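"""Synthetic B-mode skin phantoms with known ground truth.

A phantom frame is a three-layer skin model seen by a high-frequency
(20 MHz class) linear probe: a bright, rough entry echo at the surface, an
optional hypoechoic subepidermal band (SLEB) and a dermis below it.
Within-layer texture is multiplicative gamma speckle (shape ``k``, mean 1)
around the layer's mean intensity — the standard surrogate for B-mode
speckle — clipped to [0, 255].  Surface roughness is correlated Gaussian
noise on the entry-echo upper edge; lower boundaries follow the upper edge
plus the layer thickness plus independent small jitter, so roughness and
thickness variation are separately controllable.

Cohorts emulate a longitudinal treatment study: each marker has latent
per-marker parameters (layer thicknesses, mean intensities, roughness)
drawn around the base spec, shifted across visit weeks by user-specified
standardized effects, plus an untreated control arm.  Everything is
reproducible from one master seed via per-frame substreams.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .layers import (
    LAYER_NAMES,
    LayerAnnotation,
    UltrasoundFrame,
    rasterize_mask,
    write_contours,
    read_contours,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "CohortBundle",
    "EFFECT_FEATURES",
    "BASELINE_SPREADS",
    "generate_frame",
    "generate_cohort",
    "write_fixture",
    "load_fixture",
]

#: Latent features a cohort effect may target.
EFFECT_FEATURES = ("thickness", "mpi", "sr")

#: Between-marker baseline spreads used to scale standardized effects and to
#: draw per-marker latent parameters.  Thickness in mm, mpi in intensity
#: units, sr in pixels.  Magnitudes chosen to emulate the week-0 dispersion
#: of a treated actinic-keratosis cohort.
BASELINE_SPREADS = {
    ("thickness", "entry_echo"): 0.02,
    ("thickness", "sleb"): 0.09,
    ("thickness", "dermis"): 0.21,
    ("mpi", "entry_echo"): 23.9,
    ("mpi", "sleb"): 7.12,
    ("mpi", "dermis"): 10.02,
    ("sr", "entry_echo"): 3.0,
}


@dataclass
class PhantomSpec:
    """Generative parameters for one synthetic frame.

    ``speckle_shape`` is the gamma shape ``k`` (mean-1 multiplicative
    speckle; larger is smoother); ``None`` or ``inf`` disables speckle so
    each layer is painted at its constant mean intensity.
    ``roughness_amplitude_px`` is the marginal SD of the smoothed
    entry-echo upper edge; ``thickness_jitter_px`` the SD of the
    independent jitter added to each lower boundary.
    """

    height_px: int = 256
    width_px: int = 384
    axial_spacing_mm_per_px: float = 0.02
    lateral_spacing_mm_per_px: float = 0.05
    entry_thickness_mm: float = 0.1981
    sleb_thickness_mm: float = 0.4039
    dermis_thickness_mm: float = 1.5482
    mean_intensity_per_layer: dict = field(
        default_factory=lambda: {"entry_echo": 159.0, "sleb": 27.0, "dermis": 40.5}
    )
    roughness_amplitude_px: float = 3.0
    roughness_correlation_len_px: float = 8.0
    thickness_jitter_px: float = 2.0
    speckle_shape: float | None = 3.0
    surface_offset_px: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        for layer, mu in self.mean_intensity_per_layer.items():
            if layer not in LAYER_NAMES:
                raise ValueError(f"unknown layer {layer!r}")
            if not 0 <= mu <= 255:
                raise ValueError(f"mean intensity of {layer!r} outside [0, 255]")
        for name in ("entry_thickness_mm", "dermis_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sleb_thickness_mm < 0:
            raise ValueError("sleb_thickness_mm must be nonnegative")
        if self.axial_spacing_mm_per_px <= 0:
            raise ValueError("axial spacing must be positive")
        self._check_stack()

    def _check_stack(self) -> None:
        row = float(self.surface_offset_px)
        for layer, t_mm in (
            ("entry_echo", self.entry_thickness_mm),
            ("sleb", self.sleb_thickness_mm),
            ("dermis", self.dermis_thickness_mm),
        ):
            row += t_mm / self.axial_spacing_mm_per_px
            if row > self.height_px:
                raise ValueError(
                    f"layer stack exceeds image height at layer {layer!r} "
                    f"(needs row {row:.0f} of {self.height_px})"
                )

    @property
    def speckle_enabled(self) -> bool:
        return self.speckle_shape is not None and math.isfinite(self.speckle_shape)


def _smoothed_noise(rng: np.random.Generator, n: int, sd: float, corr_len: float) -> np.ndarray:
    """Correlated Gaussian noise with marginal SD ``sd``.

    White noise convolved with a Gaussian kernel normalized to unit L2
    norm, so smoothing sets the correlation length without deflating the
    per-point SD.
    """
    if sd == 0:
        return np.zeros(n)
    half = max(1, int(round(3 * corr_len)))
    x = np.arange(-half, half + 1, dtype=float)
    kern = np.exp(-0.5 * (x / corr_len) ** 2)
    kern /= np.linalg.norm(kern)
    white = rng.normal(0.0, sd, n + 2 * half)
    return np.convolve(white, kern, mode="valid")


def generate_frame(
    spec: PhantomSpec, rng: np.random.Generator | None = None, frame_id: str = "phantom"
) -> tuple[UltrasoundFrame, list[LayerAnnotation]]:
    """Render one phantom frame and the exact boundaries used to paint it.

    Layers from the surface: entry echo, SLEB (absent when its thickness
    is 0) and dermis.  The returned annotations are the same polylines the
    painter rasterizes, so a noise-free phantom round-trips its geometry
    to within one-pixel quantization.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    ax = spec.axial_spacing_mm_per_px
    cols = np.arange(w, dtype=float)

    rough = _smoothed_noise(
        rng, w, spec.roughness_amplitude_px, spec.roughness_correlation_len_px
    )
    # the surface cannot rise above the top of the frame
    upper = np.maximum(0.0, spec.surface_offset_px + rough)

    layer_stack = [("entry_echo", spec.entry_thickness_mm)]
    if spec.sleb_thickness_mm > 0:
        layer_stack.append(("sleb", spec.sleb_thickness_mm))
    layer_stack.append(("dermis", spec.dermis_thickness_mm))

    annotations: list[LayerAnnotation] = []
    boundaries = [upper]
    for layer, t_mm in layer_stack:
        jitter = _smoothed_noise(
            rng, w, spec.thickness_jitter_px, spec.roughness_correlation_len_px
        )
        t_px = np.maximum(1.0, t_mm / ax + jitter)
        lower = boundaries[-1] + t_px
        if lower.max() > h:
            raise ValueError(
                f"layer stack exceeds image height at layer {layer!r} "
                f"(row {lower.max():.1f} of {h})"
            )
        boundaries.append(lower)
        annotations.append(
            LayerAnnotation(
                layer,
                list(zip(cols, boundaries[-2])),
                list(zip(cols, lower)),
                (0, w),
            )
        )

    img = np.zeros((h, w), dtype=float)
    frame_stub = UltrasoundFrame(
        np.zeros((h, w), dtype=np.uint8), ax, spec.lateral_spacing_mm_per_px, frame_id
    )
    for ann in annotations:
        mask = rasterize_mask(ann, frame_stub)
        mu = spec.mean_intensity_per_layer[ann.layer_name]
        n_px = int(mask.sum())
        if spec.speckle_enabled:
            k = spec.speckle_shape
            img[mask] = mu * rng.gamma(k, 1.0 / k, n_px)
        else:
            img[mask] = mu
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    frame = UltrasoundFrame(pixels, ax, spec.lateral_spacing_mm_per_px, frame_id)
    return frame, annotations


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """A longitudinal phantom cohort: treated markers over visit weeks plus
    an untreated control arm.

    ``per_feature_effect`` maps ``(feature, layer, week)`` to a
    standardized paired shift: at that week the marker's latent parameter
    moves by ``effect x`` the between-marker baseline spread of that
    (feature, layer).  Valid features: ``thickness``, ``mpi``, ``sr``.
    AKASI severity scores are generated per patient as a uniform baseline
    on [1.2, 8.6] minus a treatment effect at the final visit, floored at
    zero.
    """

    n_markers: int = 56
    stage_counts: dict = field(default_factory=lambda: {1: 34, 2: 17, 3: 5})
    visits: list = field(default_factory=lambda: [0, 4, 8, 12])
    n_controls: int = 35
    per_feature_effect: dict = field(default_factory=dict)
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    akasi_effect_mean: float = 4.4
    akasi_effect_sd: float = 1.2
    control_sleb_absent_fraction: float = 0.29
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.stage_counts.values()) != self.n_markers:
            raise ValueError("stage_counts must sum to n_markers")
        if 0 not in self.visits:
            raise ValueError("week 0 must be present in visits")
        for key in self.per_feature_effect:
            feat, layer, week = key
            if feat not in EFFECT_FEATURES:
                raise ValueError(
                    f"unknown effect feature {feat!r}; valid features: "
                    f"{', '.join(EFFECT_FEATURES)}"
                )
            if layer not in LAYER_NAMES:
                raise ValueError(f"unknown layer {layer!r} in effect key {key}")
            if week not in self.visits:
                raise ValueError(f"effect week {week} not among visits {self.visits}")


@dataclass
class CohortBundle:
    """In-memory cohort: frames, ground-truth annotations and the visit table."""

    frames: dict  # frame_id -> UltrasoundFrame
    annotations: dict  # frame_id -> list[LayerAnnotation]
    table: pd.DataFrame
    cspec: CohortSpec


def _marker_latents(cspec: CohortSpec, rng: np.random.Generator) -> dict:
    base = cspec.base_spec
    lat = {
        ("thickness", "entry_echo"): base.entry_thickness_mm,
        ("thickness", "sleb"): base.sleb_thickness_mm,
        ("thickness", "dermis"): base.dermis_thickness_mm,
        ("mpi", "entry_echo"): base.mean_intensity_per_layer["entry_echo"],
        ("mpi", "sleb"): base.mean_intensity_per_layer["sleb"],
        ("mpi", "dermis"): base.mean_intensity_per_layer["dermis"],
        ("sr", "entry_echo"): base.roughness_amplitude_px,
    }
    out = {}
    for key, mu in lat.items():
        spread = BASELINE_SPREADS[key]
        out[key] = mu + rng.normal(0.0, spread)
    # a cohort built on a SLEB-free base spec stays structurally SLEB-free
    if base.sleb_thickness_mm == 0:
        out[("thickness", "sleb")] = 0.0
    return out


def _spec_from_latents(cspec: CohortSpec, latents: dict, week, seed: int) -> PhantomSpec:
    base = cspec.base_spec

    def val(feature: str, layer: str) -> float:
        v = latents[(feature, layer)]
        if week is not None:
            eff = cspec.per_feature_effect.get((feature, layer, week), 0.0)
            v += eff * BASELINE_SPREADS[(feature, layer)]
        return v

    mpi = {
        layer: float(np.clip(val("mpi", layer), 0.0, 255.0)) for layer in LAYER_NAMES
    }
    return replace(
        base,
        entry_thickness_mm=max(base.axial_spacing_mm_per_px, val("thickness", "entry_echo")),
        sleb_thickness_mm=max(0.0, val("thickness", "sleb")),
        dermis_thickness_mm=max(base.axial_spacing_mm_per_px, val("thickness", "dermis")),
        mean_intensity_per_layer=mpi,
        roughness_amplitude_px=max(0.0, val("sr", "entry_echo")),
        seed=seed,
    )


def generate_cohort(cspec: CohortSpec) -> CohortBundle:
    """Generate one frame per (marker, visit) and per control marker.

    Per-marker latent parameters are drawn once and shifted across weeks by
    ``per_feature_effect``; every frame uses an independent substream of
    the master seed, so the cohort is reproducible and frames are
    independent.  A latent SLEB thickness at or below zero makes the band
    absent from that frame.
    """
    master = np.random.SeedSequence(cspec.seed)
    lat_rng = np.random.default_rng(master.spawn(1)[0])
    frames: dict = {}
    annotations: dict = {}
    rows = []

    stages = []
    for stage, count in sorted(cspec.stage_counts.items()):
        stages.extend([stage] * count)

    frame_seed = np.random.default_rng(master.spawn(1)[0])
    last_week = max(cspec.visits)
    for i in range(cspec.n_markers):
        marker = f"M{i:03d}"
        patient = f"P{i:03d}"
        latents = _marker_latents(cspec, lat_rng)
        site = "face" if lat_rng.random() < 0.61 else "scalp"
        akasi0 = lat_rng.uniform(1.2, 8.6)
        akasi_drop = max(0.0, lat_rng.normal(cspec.akasi_effect_mean, cspec.akasi_effect_sd))
        akasi_last = max(0.0, akasi0 - akasi_drop)
        for week in cspec.visits:
            fid = f"{marker}_w{week:02d}"
            seed = int(frame_seed.integers(0, 2**31 - 1))
            spec = _spec_from_latents(cspec, latents, week, seed)
            frame, anns = generate_frame(spec, frame_id=fid)
            frames[fid] = frame
            annotations[fid] = anns
            frac = week / last_week if last_week > 0 else 0.0
            akasi = akasi0 + frac * (akasi_last - akasi0)
            rows.append(
                dict(
                    marker_id=marker,
                    patient_id=patient,
                    stage=stages[i],
                    week=week,
                    akasi=round(akasi, 4),
                    site=site,
                    arm="treated",
                    frame_id=fid,
                )
            )

    for i in range(cspec.n_controls):
        marker = f"C{i:03d}"
        fid = f"{marker}_ctrl"
        latents = _marker_latents(cspec, lat_rng)
        if lat_rng.random() < cspec.control_sleb_absent_fraction:
            latents[("thickness", "sleb")] = 0.0
        seed = int(frame_seed.integers(0, 2**31 - 1))
        spec = _spec_from_latents(cspec, latents, None, seed)
        frame, anns = generate_frame(spec, frame_id=fid)
        frames[fid] = frame
        annotations[fid] = anns
        rows.append(
            dict(
                marker_id=marker,
                patient_id=marker,
                stage=0,
                week=0,
                akasi=float("nan"),
                site="face" if lat_rng.random() < 0.61 else "scalp",
                arm="control",
                frame_id=fid,
            )
        )

    cols = ["marker_id", "patient_id", "stage", "week", "akasi", "site", "arm", "frame_id"]
    table = pd.DataFrame(rows, columns=cols)
    return CohortBundle(frames, annotations, table, cspec)


# ---------------------------------------------------------------------------
# Fixture I/O (PNG + CSV + manifest JSON, fully round-trippable)
# ---------------------------------------------------------------------------

def _cspec_to_dict(cspec: CohortSpec) -> dict:
    d = asdict(cspec)
    d["per_feature_effect"] = {
        f"{f}|{layer}|{w}": v for (f, layer, w), v in cspec.per_feature_effect.items()
    }
    d["stage_counts"] = {str(k): v for k, v in cspec.stage_counts.items()}
    return d


def _cspec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    eff = {}
    for key, v in d.get("per_feature_effect", {}).items():
        f, layer, w = key.split("|")
        eff[(f, layer, int(w))] = v
    d["per_feature_effect"] = eff
    d["stage_counts"] = {int(k): v for k, v in d.get("stage_counts", {}).items()}
    d["base_spec"] = PhantomSpec(**d["base_spec"])
    return CohortSpec(**d)


def write_fixture(bundle: CohortBundle, directory: str | Path) -> Path:
    """Write a cohort to disk: PNG frames, contour CSVs, cohort CSV and a
    manifest JSON carrying the generating spec (round-trippable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for fid, frame in bundle.frames.items():
        img_path = directory / f"{fid}.png"
        Image.fromarray(frame.pixels, mode="L").save(img_path)
        contour_path = directory / f"{fid}_contours.csv"
        write_contours(bundle.annotations[fid], contour_path)
        entries.append(
            dict(
                frame_id=fid,
                image=img_path.name,
                contours=contour_path.name,
                axial_spacing_mm_per_px=frame.axial_spacing_mm_per_px,
                lateral_spacing_mm_per_px=frame.lateral_spacing_mm_per_px,
            )
        )
    entries.sort(key=lambda e: e["frame_id"])
    table = bundle.table.copy()
    table["image_path"] = table["frame_id"].map(lambda f: f"{f}.png")
    table["contour_path"] = table["frame_id"].map(lambda f: f"{f}_contours.csv")
    cohort_path = directory / "cohort.csv"
    table.to_csv(cohort_path, index=False)
    manifest = dict(
        format="sonoderm-fixture-v1",
        cohort_table=cohort_path.name,
        frames=entries,
        cohort_spec=_cspec_to_dict(bundle.cspec),
    )
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def load_fixture(manifest_path: str | Path) -> CohortBundle:
    """Reload a fixture written by :func:`write_fixture`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    frames: dict = {}
    annotations: dict = {}
    for entry in manifest["frames"]:
        fid = entry["frame_id"]
        pixels = np.asarray(Image.open(directory / entry["image"]).convert("L"))
        frames[fid] = UltrasoundFrame(
            pixels,
            entry["axial_spacing_mm_per_px"],
            entry["lateral_spacing_mm_per_px"],
            fid,
        )
        annotations[fid] = read_contours(directory / entry["contours"])
    table = pd.read_csv(directory / manifest["cohort_table"])
    cspec = _cspec_from_dict(manifest["cohort_spec"])
    return CohortBundle(frames, annotations, table, cspec)


def fixture_hashes(directory: str | Path) -> dict:
    """SHA-256 of every fixture file, for determinism checks."""
    directory = Path(directory)
    out = {}
    for p in sorted(directory.iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
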