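"""Synthetic two-photon movie generator with ground-truth sidecar.

Emulates in vivo microglial calcium recordings: a dim constitutive
morphology signal (soma brighter than processes) modulated by sparse,
slow calcium transients per microdomain, programmed process
extension/retraction ramps, rigid frame-to-frame jitter, and additive
noise.  Every injected feature is logged in a :class:`GroundTruth`
sidecar so downstream stages can be validated without experimental data.

Geometry and acquisition defaults follow a typical cortical layer-I
recording: 1 Hz frame rate, 512x512 px covering 300x300 um
(0.586 um/px), 600 frames.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import disk, line
from skimage.morphology import dilation, disk as disk_footprint

from .stack import ImageStack

__all__ = [
    "SensorPreset",
    "SENSOR_PRESETS",
    "MotilitySpec",
    "SimulationConfig",
    "CalciumEventRecord",
    "MotilityEventRecord",
    "GroundTruth",
    "PlacementError",
    "Morphology",
    "generate_morphology",
    "generate_calcium_events",
    "calcium_kernel",
    "render_stack",
    "simulate",
    "save_simulation",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap at the requested density."""


@dataclass(frozen=True)
class SensorPreset:
    """Calcium-indicator kinetics: linear rise then single-exponential decay."""

    rise_frames: int
    tau_s: float
    amplitude_scale: float


#: Kinetic presets for a slow cytosolic indicator (GCaMP6s-like) and a fast
#: membrane-tethered one (Lck-GCaMP6f-like).  The decay constants are free
#: simulator parameters chosen to reproduce the qualitative contrast between
#: the two sensors (slower decay => larger integrated signal per event).
SENSOR_PRESETS: dict[str, SensorPreset] = {
    "cytosolic_slow": SensorPreset(rise_frames=2, tau_s=8.0, amplitude_scale=1.0),
    "membrane_fast": SensorPreset(rise_frames=2, tau_s=1.5, amplitude_scale=0.5),
}


@dataclass(frozen=True)
class MotilitySpec:
    """A programmed extension (positive change) or retraction (negative)."""

    process_id: str
    start_frame: int
    ramp_frames: int
    fractional_change: float

    @property
    def klass(self) -> str:
        return "extension" if self.fractional_change >= 0 else "retraction"

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.ramp_frames


@dataclass
class SimulationConfig:
    image_shape: tuple[int, int] = (512, 512)
    n_frames: int = 600
    frame_rate_hz: float = 1.0
    pixel_size_um: float = 300.0 / 512.0
    n_cells: int = 6
    soma_radius_um: float = 4.0
    processes_per_cell: int = 4
    branch_depth: int = 1
    baseline_intensity: float = 1000.0       # soma fluorescence, a.u.
    process_intensity_frac: float = 0.35     # process brightness relative to soma
    background_intensity: float = 100.0
    event_rate_soma_hz: float = 0.002
    event_rate_process_hz: float = 0.004
    # lognormal peak dF/F: (median, sigma of log)
    event_amplitude_dff: tuple[float, float] = (1.0, 0.4)
    sensor_preset: str = "cytosolic_slow"
    motility_spec: list[MotilitySpec] = field(default_factory=list)
    jitter_px: float = 0.0
    jitter_subpixel: bool = False
    noise_sigma_frac: float = 0.02           # Gaussian sigma / soma intensity
    poisson_scale: float | None = None
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 1 or w < 1 or self.n_frames < 1:
            raise ValueError("image_shape and n_frames must be >= 1")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_hz and pixel_size_um must be > 0")
        for name in (
            "n_cells", "soma_radius_um", "processes_per_cell", "branch_depth",
            "event_rate_soma_hz", "event_rate_process_hz", "jitter_px",
            "noise_sigma_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.event_amplitude_dff[0] < 0:
            raise ValueError("event amplitude median must be >= 0")
        if self.sensor_preset not in SENSOR_PRESETS:
            raise ValueError(f"unknown sensor_preset {self.sensor_preset!r}")

    @property
    def preset(self) -> SensorPreset:
        return SENSOR_PRESETS[self.sensor_preset]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["event_amplitude_dff"] = list(self.event_amplitude_dff)
        d["motility_spec"] = [dataclasses.asdict(m) for m in self.motility_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["image_shape"] = tuple(d.get("image_shape", (512, 512)))
        if "event_amplitude_dff" in d:
            d["event_amplitude_dff"] = tuple(d["event_amplitude_dff"])
        d["motility_spec"] = [
            m if isinstance(m, MotilitySpec) else MotilitySpec(**m)
            for m in d.get("motility_spec", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class CalciumEventRecord:
    cell_id: str
    domain_id: str
    onset_frame: int
    peak_frame: int
    peak_dff: float
    area_dff_s: float


@dataclass(frozen=True)
class MotilityEventRecord:
    process_id: str
    klass: str
    start_frame: int
    end_frame: int
    initial_area_um2: float
    final_area_um2: float


@dataclass
class GroundTruth:
    """Sidecar log of everything the simulator injected (the test oracle)."""

    calcium_events: list[CalciumEventRecord] = field(default_factory=list)
    motility_events: list[MotilityEventRecord] = field(default_factory=list)
    shifts: np.ndarray | None = None          # (T, 2) per-frame (dy, dx), px
    soma_masks: dict[str, np.ndarray] = field(default_factory=dict)
    process_masks: dict[str, np.ndarray] = field(default_factory=dict)
    true_dff: dict[str, np.ndarray] = field(default_factory=dict)  # in-memory only

    def domain_events(self, domain_id: str) -> list[CalciumEventRecord]:
        return [e for e in self.calcium_events if e.domain_id == domain_id]

    def to_json_dict(self) -> dict:
        return {
            "calcium_events": [dataclasses.asdict(e) for e in self.calcium_events],
            "motility_events": [dataclasses.asdict(e) for e in self.motility_events],
            "shifts": self.shifts.tolist() if self.shifts is not None else None,
        }


@dataclass
class Morphology:
    """Static cell layout: per-compartment boolean masks plus the base image."""

    soma_masks: dict[str, np.ndarray]
    process_masks: dict[str, np.ndarray]
    static_image: np.ndarray
    config: SimulationConfig

    @property
    def domain_ids(self) -> list[str]:
        return list(self.soma_masks) + list(self.process_masks)

    def domain_mask(self, domain_id: str) -> np.ndarray:
        if domain_id in self.soma_masks:
            return self.soma_masks[domain_id]
        return self.process_masks[domain_id]


def _random_walk_process(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: float,
    length_px: int,
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Polyline of a process as short jittered-heading segments."""

    pts = [tuple(np.round(start).astype(int))]
    pos = start.astype(float)
    heading = direction
    remaining = length_px
    while remaining > 0:
        seg = min(remaining, int(rng.integers(5, 12)))
        heading += rng.normal(0.0, 0.35)
        step = np.array([np.sin(heading), np.cos(heading)]) * seg
        pos = pos + step
        pos[0] = np.clip(pos[0], 1, shape[0] - 2)
        pos[1] = np.clip(pos[1], 1, shape[1] - 2)
        pts.append(tuple(np.round(pos).astype(int)))
        remaining -= seg
    return pts


def _draw_polyline(pts, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def generate_morphology(config: SimulationConfig, rng: np.random.Generator | None = None) -> Morphology:
    """Place disk somata and branched random-walk processes.

    Somata are disks; primary processes are random-walk polylines dilated
    to ~3 px width, with optional one-level 1-px-wide branches.  Masks are
    disjoint per compartment (first writer wins) and the static image puts
    soma pixels above process pixels above background.
    """

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    soma_r_px = config.soma_radius_um / config.pixel_size_um
    occupied = np.zeros((h, w), dtype=bool)
    soma_masks: dict[str, np.ndarray] = {}
    process_masks: dict[str, np.ndarray] = {}

    margin = soma_r_px + 4
    min_sep = 4 * soma_r_px + 8  # centre-to-centre, leaves room for processes
    centers: list[np.ndarray] = []
    for i in range(config.n_cells):
        placed = False
        for _ in range(500):
            c = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
            if all(np.hypot(*(c - c2)) >= min_sep for c2 in centers):
                centers.append(c)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i} of {config.n_cells} without overlap; "
                "reduce n_cells or enlarge image_shape"
            )

    for i, center in enumerate(centers):
        cell_id = f"cell{i}"
        rr, cc = disk(tuple(center), soma_r_px, shape=(h, w))
        soma = np.zeros((h, w), dtype=bool)
        soma[rr, cc] = True
        soma &= ~occupied
        soma_masks[f"{cell_id}_soma"] = soma
        occupied |= soma

        base_angle = rng.uniform(0, 2 * np.pi)
        for j in range(config.processes_per_cell):
            angle = base_angle + 2 * np.pi * j / max(config.processes_per_cell, 1)
            angle += rng.normal(0.0, 0.2)
            start = center + np.array([np.sin(angle), np.cos(angle)]) * (soma_r_px + 1)
            length = int(rng.integers(30, 60))
            pts = _random_walk_process(rng, start, angle, length, (h, w))
            pmask = _draw_polyline(pts, (h, w))
            pmask = dilation(pmask, disk_footprint(1))  # ~3 px wide
            if config.branch_depth >= 1 and rng.random() < 0.5 and len(pts) >= 3:
                bstart = np.array(pts[len(pts) // 2], dtype=float)
                bangle = angle + rng.choice([-1, 1]) * rng.uniform(0.5, 1.1)
                bpts = _random_walk_process(rng, bstart, bangle, length // 2, (h, w))
                pmask |= _draw_polyline(bpts, (h, w))  # 1 px wide branch
            pmask &= ~occupied
            process_masks[f"{cell_id}_proc{j}"] = pmask
            occupied |= pmask

    static = np.full((h, w), config.background_intensity, dtype=np.float64)
    p_int = config.baseline_intensity * config.process_intensity_frac
    for m in process_masks.values():
        static[m] = config.background_intensity + p_int
    for m in soma_masks.values():
        static[m] = config.background_intensity + config.baseline_intensity
    return Morphology(soma_masks, process_masks, static, config)


def calcium_kernel(
    peak_dff: float,
    preset: SensorPreset,
    frame_rate_hz: float,
    cutoff_frac: float = 0.01,
) -> np.ndarray:
    """Sampled dF/F kernel: linear rise to the peak, then exponential decay.

    Truncated once the decay falls below ``cutoff_frac`` of the peak; the
    kernel's analytic area is its sample sum times the frame interval.
    """

    rise = np.linspace(0, peak_dff, preset.rise_frames + 1)[1:]
    n_decay = int(np.ceil(-preset.tau_s * np.log(cutoff_frac) * frame_rate_hz))
    t = np.arange(1, n_decay + 1) / frame_rate_hz
    decay = peak_dff * np.exp(-t / preset.tau_s)
    kern = np.concatenate([rise, decay[decay >= cutoff_frac * peak_dff]])
    return kern


def generate_calcium_events(
    config: SimulationConfig,
    morphology: Morphology,
    rng: np.random.Generator | None = None,
) -> tuple[list[CalciumEventRecord], dict[str, np.ndarray]]:
    """Draw Poisson event trains per microdomain and build true dF/F traces.

    Returns the ground-truth event log and a ``domain_id -> dF/F(t)`` map.
    Overlapping events superpose additively.
    """

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    preset = config.preset
    T = config.n_frames
    duration_s = T / config.frame_rate_hz
    med, sig = config.event_amplitude_dff
    events: list[CalciumEventRecord] = []
    true_dff: dict[str, np.ndarray] = {}

    for domain_id in morphology.domain_ids:
        is_soma = domain_id in morphology.soma_masks
        rate = config.event_rate_soma_hz if is_soma else config.event_rate_process_hz
        cell_id = domain_id.split("_")[0]
        dff = np.zeros(T)
        n_ev = rng.poisson(rate * duration_s)
        onsets = np.sort(rng.uniform(0, T, size=n_ev).astype(int))
        for onset in onsets:
            peak = med * np.exp(rng.normal(0.0, sig)) if sig > 0 else med
            peak *= preset.amplitude_scale
            kern = calcium_kernel(peak, preset, config.frame_rate_hz)
            stop = min(T, onset + len(kern))
            dff[onset:stop] += kern[: stop - onset]
            events.append(
                CalciumEventRecord(
                    cell_id=cell_id,
                    domain_id=domain_id,
                    onset_frame=int(onset),
                    peak_frame=int(min(onset + preset.rise_frames - 1, T - 1)),
                    peak_dff=float(peak),
                    area_dff_s=float(kern[: stop - onset].sum() / config.frame_rate_hz),
                )
            )
        true_dff[domain_id] = dff
    return events, true_dff


def _ramped_masks(
    base_mask: np.ndarray,
    spec: MotilitySpec,
    blocked: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested mask family for a motility ramp, by signed-distance ordering.

    Growth adds nearest unblocked background pixels (uniform dilation);
    retraction removes outermost mask pixels (uniform erosion).  Pixel
    counts follow the linear ramp exactly, so programmed area ratios are
    honoured to rounding.
    Returns (sorted pixel index array, signed distance order base count,
    final mask) packaged as (flat_order, n0, final_mask).
    """

    inside = ndimage.distance_transform_edt(base_mask)
    outside = ndimage.distance_transform_edt(~base_mask)
    sd = np.where(base_mask, -inside, outside).astype(np.float64)
    sd[blocked & ~base_mask] = np.inf  # cannot grow into other compartments
    flat_order = np.argsort(sd.ravel(), kind="stable")
    n0 = int(base_mask.sum())
    n_final = max(0, int(round(n0 * (1.0 + spec.fractional_change))))
    n_final = min(n_final, int(np.isfinite(sd).sum()))
    final = np.zeros(base_mask.size, dtype=bool)
    final[flat_order[:n_final]] = True
    return flat_order, n0, final.reshape(base_mask.shape)


def render_stack(
    config: SimulationConfig,
    morphology: Morphology,
    events_and_dff: tuple[list[CalciumEventRecord], dict[str, np.ndarray]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render the movie: frame = static x (1 + dF/F) per compartment,
    motility ramps resizing process masks linearly, rigid jitter, noise.
    """

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if events_and_dff is None:
        events_and_dff = generate_calcium_events(config, morphology, rng)
    events, true_dff = events_and_dff
    h, w = config.image_shape
    T = config.n_frames
    bg = config.background_intensity
    px_area = config.pixel_size_um**2

    known = set(morphology.process_masks)
    for spec in config.motility_spec:
        if spec.process_id not in known:
            raise ValueError(f"motility_spec references unknown process id {spec.process_id!r}")

    stack = np.full((T, h, w), bg, dtype=np.float32)

    motile_ids = {s.process_id for s in config.motility_spec}
    occupied = np.zeros((h, w), dtype=bool)
    for m in morphology.soma_masks.values():
        occupied |= m
    for m in morphology.process_masks.values():
        occupied |= m

    soma_val = bg + config.baseline_intensity
    proc_val = bg + config.baseline_intensity * config.process_intensity_frac

    def paint_static_domain(domain_id: str, mask: np.ndarray, value: float) -> None:
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            return
        dff = true_dff.get(domain_id, np.zeros(T))
        # frame value = static compartment intensity x (1 + dF/F); the
        # background under the cell scales too, mirroring the uncorrected
        # constitutive contribution to F0
        vals = value * (1.0 + dff)[:, None]
        stack[:, ys, xs] = vals.astype(np.float32)

    for domain_id, mask in morphology.soma_masks.items():
        paint_static_domain(domain_id, mask, soma_val)
    for domain_id, mask in morphology.process_masks.items():
        if domain_id not in motile_ids:
            paint_static_domain(domain_id, mask, proc_val)

    gt = GroundTruth(
        calcium_events=list(events),
        soma_masks={k: v.copy() for k, v in morphology.soma_masks.items()},
        process_masks={k: v.copy() for k, v in morphology.process_masks.items()},
        true_dff={k: v.copy() for k, v in true_dff.items()},
    )

    for spec in config.motility_spec:
        base = morphology.process_masks[spec.process_id]
        blocked = occupied & ~base
        flat_order, n0, final = _ramped_masks(base, spec, blocked)
        n_final = int(final.sum())
        dff = true_dff.get(spec.process_id, np.zeros(T))
        vals_t = proc_val * (1.0 + dff)
        for t in range(T):
            if t <= spec.start_frame:
                frac = 0.0
            elif t >= spec.end_frame:
                frac = 1.0
            else:
                frac = (t - spec.start_frame) / spec.ramp_frames
            n_t = int(round(n0 + (n_final - n0) * frac))
            idx = flat_order[:n_t]
            ys, xs = np.unravel_index(idx, (h, w))
            stack[t, ys, xs] = np.float32(vals_t[t])
        gt.motility_events.append(
            MotilityEventRecord(
                process_id=spec.process_id,
                klass=spec.klass,
                start_frame=spec.start_frame,
                end_frame=spec.end_frame,
                initial_area_um2=n0 * px_area,
                final_area_um2=n_final * px_area,
            )
        )

    # rigid jitter
    shifts = np.zeros((T, 2))
    if config.jitter_px > 0:
        raw = rng.uniform(-config.jitter_px, config.jitter_px, size=(T, 2))
        shifts = raw if config.jitter_subpixel else np.round(raw)
        for t in range(T):
            if np.any(shifts[t] != 0):
                stack[t] = ndimage.shift(
                    stack[t], shifts[t], order=0 if not config.jitter_subpixel else 1,
                    mode="constant", cval=bg,
                )
    gt.shifts = shifts

    if config.noise_sigma_frac > 0:
        sigma = config.noise_sigma_frac * config.baseline_intensity
        stack += rng.normal(0.0, sigma, size=stack.shape).astype(np.float32)
    if config.poisson_scale is not None:
        stack = (
            rng.poisson(np.clip(stack, 0, None) * config.poisson_scale) / config.poisson_scale
        ).astype(np.float32)

    image = ImageStack(
        data=stack,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
        registered=config.jitter_px == 0,
        provenance=[f"simulated seed={config.seed}"],
    )
    return image, gt


def simulate(config: SimulationConfig) -> tuple[ImageStack, GroundTruth, Morphology]:
    """One-call simulation: morphology, events, rendered stack + sidecar.

    Deterministic: identical config (including seed) gives bit-identical
    pixel data and ground truth.
    """

    config.validate()
    rng = np.random.default_rng(config.seed)
    morph = generate_morphology(config, rng)
    ev = generate_calcium_events(config, morph, rng)
    stack, gt = render_stack(config, morph, ev, rng)
    return stack, gt, morph


def save_simulation(
    out_dir: str | Path,
    stack: ImageStack,
    gt: GroundTruth,
    config: SimulationConfig,
) -> None:
    """Write TIFF movie (16-bit), ground-truth JSON, labelled masks, config YAML."""

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack.to_tiff(out / "movie.tif", dtype=np.uint16)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt.to_json_dict(), fh, indent=1)
    h, w = stack.data.shape[1:]
    labels = np.zeros((h, w), dtype=np.uint16)
    catalogue = {}
    for i, (name, m) in enumerate(
        list(gt.soma_masks.items()) + list(gt.process_masks.items()), start=1
    ):
        labels[m] = i
        catalogue[name] = i
    np.save(out / "roi_labels.npy", labels)
    with open(out / "roi_labels.json", "w") as fh:
        json.dump(catalogue, fh, indent=1)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
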