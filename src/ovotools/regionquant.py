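"""Region-based normalized fluorescence quantification.

Fluorescence in live abdominal imaging drifts with depth, anesthesia state and
acquisition settings, so every reported intensity is a ratio against the
follicle-cell signal of the *same* frame: any global per-frame gain (exposure
change, bleaching) cancels exactly. Quantification always reads raw voxels;
blur or display filtering never enters a measurement.

Named regions follow the egg-chamber anatomy during nurse-cell dumping:

* ``NCN`` - nurse-cell nuclei (total intensity, and concentration = total/volume);
* ``NCC`` - nurse-cell cytoplasm: a nuclear-free box near the oocyte border;
* ``AO``  - anterior oocyte cytoplasm: within 17 um of the nurse-oocyte border;
* ``PO``  - posterior oocyte cytoplasm: within 17 um of the posterior pole;
* ``FOLLICLE_REF`` - the follicle-nucleus reference used for normalization;
* ``OOCYTE_TOTAL`` - whole-oocyte total (yolk-uptake measurements).

Square ROIs (default 20 x 20 px) sample three z-slices starting 9 um below the
follicle border, stepping 3 um. Placement is deterministic: among candidate
positions satisfying a region's constraints, the one farthest from any
nuclear voxel wins, ties broken by smallest (y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment3d import ImageStack, LabelVolume

__all__ = [
    "RegionSpec",
    "RegionROI",
    "oocyte_total_intensity",
    "normalize_by_follicle",
    "place_region_roi",
    "region_timeseries",
    "nuclear_concentration_series",
]

REGIONS = ("NCN", "NCC", "AO", "PO", "FOLLICLE_REF", "OOCYTE_TOTAL")


@dataclass(frozen=True)
class RegionSpec:
    """Geometry of one sampling region.

    ``max_distance_um`` is the border-proximity constraint (17 um = 100 px at
    the 0.17 um pixel pitch); ``z_offset_um`` and ``slice_step_um`` define the
    sampled z-slices below the follicle border.
    """

    region: str
    roi_edge_px: int = 20
    max_distance_um: float = 17.0
    z_offset_um: float = 9.0
    n_slices: int = 3
    slice_step_um: float = 3.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; one of {REGIONS}")
        if self.roi_edge_px <= 0:
            raise ValueError("roi_edge_px must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if min(self.max_distance_um, self.z_offset_um, self.slice_step_um) < 0:
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class RegionROI:
    """A placed square ROI: ``edge``-pixel box at (y0, x0) over ``z_slices``."""

    region: str
    z_slices: tuple[int, ...]
    y0: int
    x0: int
    edge: int

    def mean_intensity(self, volume: np.ndarray) -> float:
        sub = volume[
            list(self.z_slices),
            self.y0 : self.y0 + self.edge,
            self.x0 : self.x0 + self.edge,
        ]
        return float(sub.mean())

    def contains_any(self, mask: np.ndarray) -> bool:
        sub = mask[
            list(self.z_slices),
            self.y0 : self.y0 + self.edge,
            self.x0 : self.x0 + self.edge,
        ]
        return bool(sub.any())


# ---------------------------------------------------------------------------
# totals and normalization
# ---------------------------------------------------------------------------

def oocyte_total_intensity(
    stack: ImageStack,
    oocyte_mask: np.ndarray,
    midsection_z: int,
    channel: str,
) -> float:
    """Total raw intensity over the oocyte in the top half of the chamber.

    Deep slices of vitellogenic chambers are not imageable, so quantification
    uses slices from the top surface (z = 0) through ``midsection_z``
    inclusive; the sum runs over oocyte-mask voxels in those slices.
    """
    vol = stack.data[channel]
    if oocyte_mask.shape != vol.shape:
        raise ValueError("oocyte mask must be congruent with the stack")
    if not 0 <= midsection_z < vol.shape[0]:
        raise ValueError("midsection_z outside the stack")
    half = oocyte_mask[: midsection_z + 1]
    if not half.any():
        raise ValueError("oocyte mask is empty in the top half-stack")
    return float(vol[: midsection_z + 1][half].sum())


def normalize_by_follicle(
    raw: float,
    follicle: LabelVolume | np.ndarray,
    frame: np.ndarray,
    mode: str = "mean",
) -> float:
    """Divide ``raw`` by the same-frame follicle intensity statistic.

    ``mode='total'`` (yolk totals) divides by the summed follicle intensity;
    ``mode='mean'`` (regional concentrations) by the mean follicle-voxel
    intensity.
    """
    mask = follicle.mask() if isinstance(follicle, LabelVolume) else np.asarray(
        follicle, dtype=bool
    )
    if not mask.any():
        raise ValueError("follicle reference is empty")
    vals = np.asarray(frame, dtype=np.float64)[mask]
    ref = float(vals.sum() if mode == "total" else vals.mean())
    if ref <= 0:
        raise ValueError("follicle reference intensity is not positive")
    return raw / ref


# ---------------------------------------------------------------------------
# deterministic ROI placement
# ---------------------------------------------------------------------------

def _border(mask_from: np.ndarray, mask_to: np.ndarray) -> np.ndarray:
    """Voxels of ``mask_from`` adjacent (26-conn) to ``mask_to``."""
    grown = ndi.binary_dilation(mask_to, structure=np.ones((3, 3, 3), bool))
    return mask_from & grown


def _distance_um(border_mask: np.ndarray, voxel: tuple[float, float, float]) -> np.ndarray:
    """Euclidean distance (um) from every voxel to the border set."""
    if not border_mask.any():
        return np.full(border_mask.shape, np.inf)
    return ndi.distance_transform_edt(~border_mask, sampling=voxel)


def place_region_roi(
    frame_shape: tuple[int, int, int],
    spec: RegionSpec,
    geometry: dict,
) -> RegionROI:
    """Deterministically place a region's ROI given the frame geometry.

    ``geometry`` must provide ``nuclei`` (bool, all nuclei), ``compartments``
    (int8: 1 nurse cytoplasm, 2 oocyte, 3 follicle shell),
    ``follicle_border_z`` (top chamber slice index) and ``voxel_size``
    (z, y, x um). Candidate boxes must lie wholly inside the region's
    compartment across all sampled z-slices, contain zero nuclear voxels, and
    have their centroid within ``max_distance_um`` of the region's defining
    border. The winner maximizes distance to the nearest nuclear voxel.
    """
    voxel = geometry["voxel_size"]
    dz = voxel[0]
    nz, ny, nx = frame_shape
    z_start = geometry["follicle_border_z"] + int(round(spec.z_offset_um / dz))
    z_slices = tuple(
        z_start + int(round(i * spec.slice_step_um / dz))
        for i in range(spec.n_slices)
    )
    if z_slices[-1] >= nz or z_slices[0] < 0:
        raise ValueError(f"{spec.region}: sampled z-slices fall outside the stack")

    comp = geometry["compartments"]
    nuclei = geometry["nuclei"]
    if spec.region == "NCC":
        allowed = comp == 1
        border = _border(comp == 1, comp == 2)  # oocyte border, nurse side
    elif spec.region == "AO":
        allowed = comp == 2
        border = _border(comp == 2, comp == 1)  # nurse-oocyte border
    elif spec.region == "PO":
        allowed = comp == 2
        # posterior border of the egg in each slice: the posterior-most
        # oocyte pixels of that slice (the 3D pole may lie below the
        # sampled depth)
        border = np.zeros(frame_shape, bool)
        ooc = comp == 2
        for z in range(nz):
            xs = np.nonzero(ooc[z].any(axis=0))[0]
            if len(xs):
                border[z] = ooc[z] & (
                    np.arange(nx)[None, :] >= xs[-1] - 1
                )
    elif spec.region == "FOLLICLE_REF":
        allowed = comp == 3
        border = np.zeros(frame_shape, bool)
    else:
        raise ValueError(
            f"{spec.region} is not a box region; NCN uses nuclear labels and "
            "OOCYTE_TOTAL the oocyte mask"
        )

    e = spec.roi_edge_px
    # a box is admissible where every voxel of the box, in every sampled
    # slice, is in the compartment and nucleus-free
    allowed_2d = np.ones((ny, nx), bool)
    free_2d = np.ones((ny, nx), bool)
    for z in z_slices:
        allowed_2d &= allowed[z]
        free_2d &= ~nuclei[z]
    box_ok = (
        ndi.minimum_filter(allowed_2d, size=e, mode="constant", cval=False)
        & ndi.minimum_filter(free_2d, size=e, mode="constant", cval=False)
    )
    # minimum_filter windows are centered; convert center-ok to corner coords
    half = e // 2

    # proximity is judged in-plane on the middle sampled slice, as the
    # region definitions are drawn on a slice
    mid_z = z_slices[len(z_slices) // 2]
    if border[mid_z].any():
        dist2d = ndi.distance_transform_edt(
            ~border[mid_z], sampling=voxel[1:]
        )
        near = dist2d <= spec.max_distance_um
    elif border.any():
        near = _distance_um(border, voxel)[mid_z] <= spec.max_distance_um
    else:
        near = np.ones((ny, nx), bool)

    dist_nuc = _distance_um(nuclei, voxel)
    score = np.minimum.reduce([dist_nuc[z] for z in z_slices])

    candidates = box_ok & near
    if not candidates.any():
        raise ValueError(
            f"no admissible {spec.region} ROI position: no nuclear-free "
            f"{e}x{e} box satisfies the compartment and distance constraints"
        )
    score = np.where(candidates, score, -np.inf)
    best = np.argwhere(score == score.max())
    cy, cx = min(map(tuple, best))  # ties: smallest (y, x)
    return RegionROI(
        region=spec.region,
        z_slices=z_slices,
        y0=int(cy) - half,
        x0=int(cx) - half,
        edge=e,
    )


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def region_timeseries(
    frames: list[ImageStack],
    specs: list[RegionSpec],
    geometry: list[dict] | dict,
    frame_stride: int = 5,
    channel: str = "histone",
) -> pd.DataFrame:
    """Normalized per-region intensity series over a sampled time-lapse.

    Every ``frame_stride``-th frame is quantified (default: every fifth).
    Box regions report the ROI mean normalized by the mean follicle-nucleus
    intensity of the same frame. ``NCN`` reports the total nurse-nuclear
    intensity (normalized the same way) plus the nuclear concentration
    (total / nuclear volume). Returns a tidy frame with columns
    (frame, t_h, region, raw, reference, normalized, extra...).
    """
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    rows = []
    for i in range(0, len(frames), frame_stride):
        stack = frames[i]
        geo = geometry[i] if isinstance(geometry, list) else geometry
        if geo is None:
            raise ValueError(f"missing geometry for sampled frame {i}")
        vol = stack.data[channel]
        follicle = geo.get("follicle_nuclei")
        if follicle is None:
            follicle = geo["nuclei"] & ~geo["nurse_nuclei"]
        ref_mean = float(vol[follicle].mean())
        if ref_mean <= 0:
            raise ValueError(f"frame {i}: follicle reference is not positive")
        voxvol = float(np.prod(geo["voxel_size"]))
        for spec in specs:
            if spec.region == "NCN":
                nmask = geo["nurse_nuclei"]
                total = float(vol[nmask].sum()) if nmask.any() else 0.0
                volume = float(nmask.sum()) * voxvol
                rows.append(
                    {
                        "frame": i,
                        "t_h": stack.t_hours,
                        "region": "NCN",
                        "raw": total,
                        "reference": ref_mean,
                        "normalized": total / ref_mean,
                        "nuclear_volume_um3": volume,
                        "concentration": total / volume if volume > 0 else np.nan,
                    }
                )
                continue
            roi = place_region_roi(vol.shape, spec, geo)
            raw = roi.mean_intensity(vol)
            rows.append(
                {
                    "frame": i,
                    "t_h": stack.t_hours,
                    "region": spec.region,
                    "raw": raw,
                    "reference": ref_mean,
                    "normalized": raw / ref_mean,
                    "roi_y0": roi.y0,
                    "roi_x0": roi.x0,
                }
            )
    return pd.DataFrame(rows)


def nuclear_concentration_series(
    totals: np.ndarray | list[float],
    volumes_um3: np.ndarray | list[float],
    t_h: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """Per-frame nuclear total, volume and concentration (total/volume).

    The series terminates (``terminated`` flag set on the last row) at the
    first frame whose nuclear volume has vanished; later frames are dropped
    since concentration is undefined once the nucleus is gone.
    """
    totals = np.asarray(totals, dtype=float)
    volumes = np.asarray(volumes_um3, dtype=float)
    if totals.shape != volumes.shape:
        raise ValueError("totals and volumes must have equal length")
    t = np.arange(len(totals), dtype=float) if t_h is None else np.asarray(t_h, float)
    gone = np.nonzero(volumes <= 0)[0]
    end = int(gone[0]) if len(gone) else len(totals)
    df = pd.DataFrame(
        {
            "t_h": t[:end],
            "total": totals[:end],
            "volume_um3": volumes[:end],
            "concentration": totals[:end] / volumes[:end],
            "terminated": False,
        }
    )
    if len(gone) and len(df):
        df.loc[df.index[-1], "terminated"] = True
    return df
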