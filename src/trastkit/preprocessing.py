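"""Camera image-stack preprocessing: background subtraction, bleach
correction from interleaved reference frames, ROI binning, and irradiance
calibration from a reference-dye image.

One frame per pulse train; the acquisition order is a randomized
permutation of the pulse-width schedule, with reference frames at a fixed
pulse width interleaved throughout to track photobleaching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .trast import TrastCurve


@dataclass
class ImageStack:
    frames: np.ndarray                    # (nf, h, w) float
    frame_w_s: np.ndarray                 # (nf,) pulse width per frame
    acquisition_index: np.ndarray         # (nf,) position in acquisition
    reference_frames: np.ndarray          # (nr, h, w)
    reference_positions: np.ndarray       # (nr,) acquisition positions
    reference_w_s: float
    background: float | np.ndarray = 0.0  # static frame or scalar
    pixel_size_um: float = 1.0
    t_ill_s: float = 0.1
    duty_cycle: float = 0.01
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_w_s = np.asarray(self.frame_w_s, dtype=float)
        self.acquisition_index = np.asarray(self.acquisition_index)
        self.reference_frames = np.asarray(self.reference_frames, dtype=float)
        self.reference_positions = np.asarray(self.reference_positions)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, h, w)")
        if self.reference_frames.ndim == 3 and \
                self.reference_frames.shape[1:] != self.frames.shape[1:]:
            raise ValueError("frame shapes must match")
        if len(self.frame_w_s) != len(self.frames):
            raise ValueError("one pulse width per frame required")

    @property
    def pulses_per_train(self) -> np.ndarray:
        return np.maximum(1, np.round(self.t_ill_s / self.frame_w_s)).astype(int)

    # -- persistence ------------------------------------------------------
    def write_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames)
            f.create_dataset("frame_w_s", data=self.frame_w_s)
            f.create_dataset("acquisition_index", data=self.acquisition_index)
            f.create_dataset("reference_frames", data=self.reference_frames)
            f.create_dataset("reference_positions", data=self.reference_positions)
            f.create_dataset("background", data=np.asarray(self.background))
            f.attrs["reference_w_s"] = self.reference_w_s
            f.attrs["pixel_size_um"] = self.pixel_size_um
            f.attrs["t_ill_s"] = self.t_ill_s
            f.attrs["duty_cycle"] = self.duty_cycle
            f.attrs["meta_json"] = json.dumps(self.meta, sort_keys=True)

    def write_tiff(self, path: str | Path) -> None:
        """Multi-page TIFF (regular frames then reference frames) with a
        JSON metadata sidecar."""
        import tifffile
        path = Path(path)
        pages = np.concatenate([self.frames, self.reference_frames], axis=0)
        # float64 pages: the TRAST signal can ride on a much larger static
        # background, where float32 quantization would corrupt it
        tifffile.imwrite(path, pages.astype(np.float64))
        sidecar = {
            "frame_w_s": self.frame_w_s.tolist(),
            "acquisition_index": self.acquisition_index.tolist(),
            "reference_positions": self.reference_positions.tolist(),
            "reference_w_s": self.reference_w_s,
            "background": (float(self.background)
                           if np.ndim(self.background) == 0
                           else np.asarray(self.background).tolist()),
            "pixel_size_um": self.pixel_size_um,
            "t_ill_s": self.t_ill_s,
            "duty_cycle": self.duty_cycle,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, sort_keys=True))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        import tifffile
        path = Path(path)
        pages = tifffile.imread(path).astype(float)
        sc = json.loads(path.with_suffix(".json").read_text())
        n_regular = len(sc["frame_w_s"])
        bg = sc["background"]
        return cls(
            frames=pages[:n_regular], frame_w_s=np.array(sc["frame_w_s"]),
            acquisition_index=np.array(sc["acquisition_index"]),
            reference_frames=pages[n_regular:],
            reference_positions=np.array(sc["reference_positions"]),
            reference_w_s=sc["reference_w_s"],
            background=bg if np.ndim(bg) == 0 else np.asarray(bg),
            pixel_size_um=sc["pixel_size_um"], t_ill_s=sc["t_ill_s"],
            duty_cycle=sc["duty_cycle"], meta=sc["meta"])

    @classmethod
    def read_h5(cls, path: str | Path) -> "ImageStack":
        with h5py.File(path, "r") as f:
            bg = f["background"][()]
            return cls(
                frames=f["frames"][()], frame_w_s=f["frame_w_s"][()],
                acquisition_index=f["acquisition_index"][()],
                reference_frames=f["reference_frames"][()],
                reference_positions=f["reference_positions"][()],
                reference_w_s=float(f.attrs["reference_w_s"]),
                background=float(bg) if np.ndim(bg) == 0 else bg,
                pixel_size_um=float(f.attrs["pixel_size_um"]),
                t_ill_s=float(f.attrs["t_ill_s"]),
                duty_cycle=float(f.attrs["duty_cycle"]),
                meta=json.loads(f.attrs["meta_json"]))


@dataclass(frozen=True)
class IrradianceMap:
    irradiance_W_cm2: np.ndarray   # (h, w)
    total_power_W: float
    pixel_size_um: float

    @property
    def pixel_area_cm2(self) -> float:
        return (self.pixel_size_um * 1e-4) ** 2


def irradiance_map(reference_image: np.ndarray, total_power_W: float,
                   pixel_size_um: float) -> IrradianceMap:
    """Convert a non-saturating reference-dye image into a per-pixel
    irradiance map scaled to the known total laser power."""
    img = np.asarray(reference_image, dtype=float)
    if np.any(img < 0):
        raise ValueError("reference image must be non-negative")
    total = img.sum()
    if total <= 0:
        raise ValueError("reference image is empty")
    if total_power_W <= 0:
        raise ValueError("total power must be positive")
    area = (pixel_size_um * 1e-4) ** 2
    irr = total_power_W * img / (total * area)
    return IrradianceMap(irr, total_power_W, pixel_size_um)


def fit_gaussian_waist(irr: IrradianceMap) -> tuple[float, tuple[float, float]]:
    """1/e² radius (µm) of a Gaussian profile, from a linear fit of
    ln(I) against r² about the intensity-weighted centroid."""
    img = irr.irradiance_W_cm2
    cy, cx = _centroid(img)
    yy, xx = np.indices(img.shape)
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * irr.pixel_size_um ** 2
    mask = img > 1e-3 * img.max()
    slope, _ = np.polyfit(r2[mask], np.log(img[mask]), 1)
    if slope >= 0:
        raise ValueError("profile is not a decaying Gaussian")
    waist = np.sqrt(-2.0 / slope)
    return float(waist), (float(cy), float(cx))


def _centroid(img: np.ndarray) -> tuple[float, float]:
    img = np.clip(img, 0, None)
    tot = img.sum()
    yy, xx = np.indices(img.shape)
    return float((yy * img).sum() / tot), float((xx * img).sum() / tot)


def bleach_correct(stack: ImageStack, warn_threshold: float = 0.10) -> ImageStack:
    """Divide each regular frame by a bleaching factor interpolated (in
    acquisition order) between reference-frame intensities, normalized to
    the first reference frame."""
    if len(stack.reference_frames) < 2:
        raise ValueError("need at least 2 reference frames")
    ref_means = stack.reference_frames.mean(axis=(1, 2))
    if np.any(ref_means <= 0):
        raise ValueError("non-positive reference frame intensity")
    order = np.argsort(stack.reference_positions)
    pos = np.asarray(stack.reference_positions, dtype=float)[order]
    factors = (ref_means / ref_means[order[0]])[order]
    total_bleach = 1.0 - factors.min()
    if total_bleach > warn_threshold:
        warnings.warn(f"inferred total bleaching {total_bleach:.1%} exceeds "
                      f"{warn_threshold:.0%}", RuntimeWarning)
    interp = np.interp(stack.acquisition_index.astype(float), pos, factors)
    corrected = stack.frames / interp[:, None, None]
    return replace(stack, frames=corrected)


def stack_to_trast_curve(stack: ImageStack, irr: Optional[IrradianceMap] = None,
                         roi_radius_um: float = 15.0,
                         correct_bleaching: bool = True) -> TrastCurve:
    """Reduce an image stack to a normalized TRAST curve.

    Static background is subtracted, frames are bleach-corrected, pixels
    inside a circular ROI centered on the beam centroid are summed, each
    sum is divided by its pulse count times pulse duration (per unit
    illumination time), and the result is normalized by the shortest-pulse
    (w0) frame. The ROI-mean irradiance is attached when a map is given.
    """
    frames = stack.frames - np.asarray(stack.background, dtype=float)
    refs = stack.reference_frames - np.asarray(stack.background, dtype=float)
    work = replace(stack, frames=frames, reference_frames=refs)
    if correct_bleaching and len(work.reference_frames) >= 2:
        work = bleach_correct(work)

    mean_img = work.frames.mean(axis=0)
    cy, cx = _centroid(mean_img)
    yy, xx = np.indices(mean_img.shape)
    r_um = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) * stack.pixel_size_um
    mask = r_um <= roi_radius_um
    if not mask.any():
        raise ValueError("ROI lies outside the image")

    sums = work.frames[:, mask].sum(axis=1)
    n_pulses = work.pulses_per_train
    per_time = sums / (n_pulses * work.frame_w_s)

    i0 = int(np.argmin(work.frame_w_s))
    w0 = float(work.frame_w_s[i0])
    if per_time[i0] <= 0:
        raise ValueError("w0 frame has non-positive intensity")
    values = per_time / per_time[i0]

    order = np.argsort(work.frame_w_s)
    meta = dict(stack.meta)
    meta.update({"w0_s": w0, "roi_radius_um": roi_radius_um,
                 "roi_center_px": [cy, cx]})
    if irr is not None:
        meta["irradiance_W_cm2"] = float(irr.irradiance_W_cm2[mask].mean())
    return TrastCurve(work.frame_w_s[order], values[order], None, meta)
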