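"""Synthetic data with known ground truth for the analysis pipeline.

No raw microscopy is distributed with this package; instead, every analysis
path is exercised on generated data whose generative parameters are known
exactly:

* fixed-sample surveys (ovariole counts, stage calls, fecundity, midsection
  areas) whose areas follow the standard exponential growth curve;
* 3D egg-chamber phantoms: an ellipsoidal chamber with a follicle-nucleus
  shell, nurse-nucleus spheres in the anterior compartment and an oocyte
  occupying a prescribed fraction of the midsection;
* nurse-cell dumping series: a linear four-compartment chain
  nuclei -> nurse cytoplasm -> anterior oocyte -> posterior oocyte, integrated
  exactly (matrix exponential) and rendered into image frames;
* follicle-cell rotation tracks matching the projection geometry assumed by
  the angular-displacement estimator.

Determinism: every generator takes a seed and identical seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .kinematics import CellTrack
from .segment3d import ImageStack, LabelVolume
from .timeline import (
    STAGES,
    STANDARD_AREA_CURVE,
    STANDARD_OOCYTE_CURVE,
    FixedSurvey,
    GrowthCurve,
    StageTimeline,
    compute_epr,
    compute_total_duration,
    predict,
)

__all__ = [
    "DEFAULT_STAGE_FREQUENCIES",
    "SurveyParams",
    "simulate_survey",
    "ChamberPhantomParams",
    "ChamberPhantom",
    "simulate_chamber_stack",
    "DumpingFlowParams",
    "DumpingSeries",
    "compartment_totals",
    "euler_compartment_totals",
    "simulate_dumping_series",
    "simulate_rotation_track",
]

#: Default stage-frequency distribution over stages 2-14 (sums to 1). Stage 8
#: carries the observed 7.7%; early pre-vitellogenic stages are somewhat more
#: frequent (longer-lived relative to the fast dumping stages 11-13).
DEFAULT_STAGE_FREQUENCIES: dict[int, float] = {
    2: 0.120, 3: 0.105, 4: 0.095, 5: 0.085, 6: 0.080, 7: 0.078, 8: 0.077,
    9: 0.080, 10: 0.095, 11: 0.035, 12: 0.045, 13: 0.050, 14: 0.055,
}

#: Generative means matching the fixed-sample survey conditions.
DEFAULT_EGGS_PER_DAY = 51.5
DEFAULT_OVARIOLES_PER_FEMALE = 35.63
DEFAULT_CHAMBERS_PER_OVARIOLE = 5.2

#: Default voxel size (z, y, x) um: 3-um z-steps, 0.17-um pixels.
DEFAULT_VOXEL_SIZE = (3.0, 0.17, 0.17)

#: Oocyte fractions are clipped here: the midsection never becomes all oocyte
#: because the follicle layer and residual nurse material persist.
MAX_OOCYTE_FRACTION = 0.95


def _default_timeline() -> StageTimeline:
    epr = compute_epr(DEFAULT_EGGS_PER_DAY, DEFAULT_OVARIOLES_PER_FEMALE)
    g = compute_total_duration(DEFAULT_CHAMBERS_PER_OVARIOLE, epr)
    return StageTimeline(dict(DEFAULT_STAGE_FREQUENCIES), g)


# ---------------------------------------------------------------------------
# fixed-sample surveys
# ---------------------------------------------------------------------------

@dataclass
class SurveyParams:
    """Generative parameters for a fixed-sample survey.

    Counts are Poisson around the stated means; chamber stages are drawn from
    ``stage_frequencies``; each chamber's midsection area is the growth-curve
    prediction at its stage's midpoint age times multiplicative lognormal
    noise with coefficient of variation ``area_noise_cv`` (mean 1). For
    vitellogenic chambers (stage >= 8) an oocyte fraction is generated from
    the oocyte-percent curve, whose time origin is stage-9 onset.
    """

    n_females: int = 16
    mean_ovarioles: float = DEFAULT_OVARIOLES_PER_FEMALE
    mean_chambers_per_ovariole: float = DEFAULT_CHAMBERS_PER_OVARIOLE
    mean_eggs_per_day: float = DEFAULT_EGGS_PER_DAY
    stage_frequencies: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_FREQUENCIES)
    )
    area_curve: GrowthCurve = STANDARD_AREA_CURVE
    oocyte_curve: GrowthCurve = STANDARD_OOCYTE_CURVE
    area_noise_cv: float = 0.1
    ovarioles_sampled_per_female: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.array([self.stage_frequencies.get(s, 0.0) for s in STAGES])
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(
                "stage_frequencies must be non-negative and sum to 1"
            )
        if min(
            self.mean_ovarioles,
            self.mean_chambers_per_ovariole,
            self.mean_eggs_per_day,
        ) <= 0:
            raise ValueError("generative means must be positive")
        if self.area_noise_cv < 0:
            raise ValueError("area_noise_cv must be non-negative")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def simulate_survey(params: SurveyParams) -> FixedSurvey:
    """Draw a fixed-sample survey with ground-truth stage and age per chamber."""
    rng = np.random.default_rng(params.seed)
    epr = compute_epr(params.mean_eggs_per_day, params.mean_ovarioles)
    g = compute_total_duration(params.mean_chambers_per_ovariole, epr)
    tl = StageTimeline(dict(params.stage_frequencies), g)

    females = pd.DataFrame(
        {
            "female_id": np.arange(params.n_females),
            "ovariole_count": rng.poisson(
                params.mean_ovarioles, params.n_females
            ),
            "eggs_24h": rng.poisson(
                params.mean_eggs_per_day, params.n_females
            ),
        }
    )

    stages_avail = np.array(STAGES)
    probs = np.array([params.stage_frequencies.get(s, 0.0) for s in STAGES])
    probs = probs / probs.sum()
    rows = []
    ovariole_id = 0
    t9 = tl.cumulative_start[9]
    for female in range(params.n_females):
        for _ in range(params.ovarioles_sampled_per_female):
            n_ch = rng.poisson(params.mean_chambers_per_ovariole)
            stage_draw = rng.choice(stages_avail, size=n_ch, p=probs)
            noise = _lognormal_factor(rng, params.area_noise_cv, n_ch)
            for stage, fac in zip(stage_draw, noise):
                age = tl.midpoint_age(int(stage))
                area = predict(params.area_curve, age) * fac
                if stage >= 8:
                    frac = min(
                        predict(params.oocyte_curve, age - t9),
                        MAX_OOCYTE_FRACTION,
                    )
                else:
                    frac = np.nan
                rows.append(
                    {
                        "female_id": female,
                        "ovariole_id": ovariole_id,
                        "stage": int(stage),
                        "midsection_area_um2": area,
                        "oocyte_fraction": frac,
                        "true_age_h": age,
                    }
                )
            ovariole_id += 1
    chambers = pd.DataFrame(
        rows,
        columns=[
            "female_id",
            "ovariole_id",
            "stage",
            "midsection_area_um2",
            "oocyte_fraction",
            "true_age_h",
        ],
    )
    return FixedSurvey(females=females, chambers=chambers)


# ---------------------------------------------------------------------------
# chamber phantoms
# ---------------------------------------------------------------------------

@dataclass
class ChamberPhantomParams:
    """Geometry and rendering parameters for one egg-chamber phantom.

    ``stage_or_age``: an integer in 2..14 is interpreted as a stage (the
    chamber gets that stage's midpoint age under the default timeline); a
    float is an age in hours. The midsection area then follows the standard
    area curve; the chamber is a prolate ellipsoid with the
    anterior-posterior axis along x (``aspect_ratio`` = a/b) and circular
    cross-section (c = b).
    """

    stage_or_age: int | float = 8
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_nurse_nuclei: int = 15
    follicle_nucleus_radius: float = 2.0
    nurse_nucleus_radius: float = 5.0
    oocyte_fraction: float = 0.30
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"histone": 100.0, "yolk": 100.0}
    )
    noise_sd: float = 0.0
    seed: int = 0
    include_follicle: bool = True
    aspect_ratio: float = 1.5
    z_axis_scale: float = 1.0
    margin_um: float = 4.0
    area_curve: GrowthCurve = STANDARD_AREA_CURVE

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.oocyte_fraction <= 1.0:
            raise ValueError("oocyte_fraction must lie in [0, 1]")
        if not 0 <= self.n_nurse_nuclei <= 15:
            raise ValueError("a 16-cell cyst has at most 15 nurse cells")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def age_h(self) -> float:
        v = self.stage_or_age
        if isinstance(v, (int, np.integer)) and STAGES[0] <= v <= STAGES[-1]:
            return _default_timeline().midpoint_age(int(v))
        return float(v)


@dataclass
class ChamberPhantom:
    """Rendered phantom plus its ground truth.

    ``compartments`` codes 0 background, 1 nurse cytoplasm, 2 oocyte,
    3 follicle shell. ``geometry`` is the mask dictionary consumed by the
    region-quantification ROI placer.
    """

    stack: ImageStack
    labels: LabelVolume
    truth: pd.DataFrame
    compartments: np.ndarray
    geometry: dict


def _semi_axes(
    area_um2: float, aspect: float, z_scale: float = 1.0
) -> tuple[float, float, float]:
    """(a, b, c) um of an ellipsoid whose equatorial section has the area.

    ``z_scale`` < 1 flattens the chamber along z, emulating compression
    between the coverslip-side cuticle and neighbouring chambers.
    """
    b = float(np.sqrt(area_um2 / (np.pi * aspect)))
    return aspect * b, b, z_scale * b


def _paint_sphere(
    target: np.ndarray,
    center_um: tuple[float, float, float],
    radius_um: float,
    voxel: tuple[float, float, float],
    value: int,
) -> int:
    """Paint a voxelized sphere label into ``target``; returns voxel count."""
    dz, dy, dx = voxel
    cz, cy, cx = center_um
    z0 = max(int(np.floor((cz - radius_um) / dz)), 0)
    z1 = min(int(np.ceil((cz + radius_um) / dz)) + 1, target.shape[0])
    y0 = max(int(np.floor((cy - radius_um) / dy)), 0)
    y1 = min(int(np.ceil((cy + radius_um) / dy)) + 1, target.shape[1])
    x0 = max(int(np.floor((cx - radius_um) / dx)), 0)
    x1 = min(int(np.ceil((cx + radius_um) / dx)) + 1, target.shape[2])
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return 0
    zz = (np.arange(z0, z1) * dz - cz)[:, None, None]
    yy = (np.arange(y0, y1) * dy - cy)[None, :, None]
    xx = (np.arange(x0, x1) * dx - cx)[None, None, :]
    inside = zz * zz + yy * yy + xx * xx <= radius_um * radius_um
    if not inside.any() and radius_um > 0:
        # sub-voxel sphere: occupy the voxel holding the centre so a
        # shrinking nucleus never silently disappears mid-series
        iz = min(max(int(round(cz / dz)), 0), target.shape[0] - 1)
        iy = min(max(int(round(cy / dy)), 0), target.shape[1] - 1)
        ix = min(max(int(round(cx / dx)), 0), target.shape[2] - 1)
        target[iz, iy, ix] = value
        return 1
    sub = target[z0:z1, y0:y1, x0:x1]
    sub[inside] = value
    return int(inside.sum())


def _follicle_ring_centers(
    a: float, b: float, c: float,
    center_um: tuple[float, float, float],
    dz: float, nz: int, r_f: float,
) -> list[tuple[float, float, float]]:
    """Follicle-nucleus centers: per-z rings just inside the ellipsoid surface."""
    cz, cy, cx = center_um
    centers = []
    for k in range(nz):
        z = k * dz
        u = (z - cz) / c
        if abs(u) >= 1.0:
            continue
        scale = np.sqrt(1.0 - u * u)
        ak, bk = a * scale, b * scale
        if min(ak, bk) < 2.0 * r_f:
            continue
        # Ramanujan perimeter of the cross-section ellipse
        per = np.pi * (3 * (ak + bk) - np.sqrt((3 * ak + bk) * (ak + 3 * bk)))
        n_k = max(3, int(per / (3.0 * r_f)))
        ang = 2 * np.pi * np.arange(n_k) / n_k
        for th in ang:
            centers.append(
                (z, cy + 0.98 * bk * np.sin(th), cx + 0.98 * ak * np.cos(th))
            )
    return centers


def simulate_chamber_stack(params: ChamberPhantomParams) -> ChamberPhantom:
    """Render one egg-chamber phantom with exact ground truth.

    The chamber is an ellipsoid whose equatorial cross-section area follows
    the standard growth curve at the phantom's age. Follicle nuclei sit in
    rings on the surface (one ring per z-slice), nurse nuclei are placed
    without overlap in the anterior interior, and the oocyte occupies
    ``oocyte_fraction`` of the chamber's midsection area (posterior cap).
    Channels: ``histone`` marks all nuclei, ``yolk`` the oocyte. Ground truth
    lists every nucleus with centroid, radius, voxelized volume and
    noise-free integrated histone intensity.
    """
    rng = np.random.default_rng(params.seed)
    dz, dy, dx = params.voxel_size
    area = predict(params.area_curve, params.age_h)
    a, b, c = _semi_axes(area, params.aspect_ratio, params.z_axis_scale)
    m = params.margin_um
    nz = int(np.ceil((2 * c + 2 * m) / dz)) + 1
    ny = int(np.ceil((2 * b + 2 * m) / dy)) + 1
    nx = int(np.ceil((2 * a + 2 * m) / dx)) + 1
    center = ((nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2)
    cz, cy, cx = center

    zz = (np.arange(nz) * dz - cz)[:, None, None]
    yy = (np.arange(ny) * dy - cy)[None, :, None]
    xx = (np.arange(nx) * dx - cx)[None, None, :]
    ell = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2
    chamber = ell <= 1.0
    interior = ell < 0.88  # inside the follicle layer
    shell = chamber & ~interior

    # posterior cut so the oocyte takes the requested midsection-area fraction
    mid_z = int(round(cz / dz))
    xs_um = np.arange(nx) * dx - cx
    ch_mid = chamber[mid_z]
    in_mid = interior[mid_z]
    n_target = int(round(params.oocyte_fraction * ch_mid.sum()))
    xs_interior = np.sort(xs_um[np.nonzero(in_mid)[1]])
    if n_target > len(xs_interior):
        raise ValueError(
            "oocyte_fraction exceeds the interior fraction of the midsection"
        )
    if n_target == 0:
        x_cut = np.inf
    else:
        # candidate cuts sit at pixel columns; pick the one whose posterior
        # pixel count is closest to the target (a vertical cut can only move
        # in column-sized steps)
        uniq, first_idx = np.unique(xs_interior, return_index=True)
        counts_ge = len(xs_interior) - first_idx
        k = int(np.argmin(np.abs(counts_ge - n_target)))
        x_cut = float(uniq[k])
    x_grid = np.broadcast_to(xx, ell.shape)
    oocyte = interior & (x_grid >= x_cut)
    nurse_cyt = interior & (x_grid < x_cut)

    compartments = np.zeros(ell.shape, dtype=np.int8)
    compartments[nurse_cyt] = 1
    compartments[oocyte] = 2
    compartments[shell] = 3

    labels = np.zeros(ell.shape, dtype=np.int32)
    rows = []
    next_label = 1

    # nurse nuclei: rejection-sampled, non-overlapping, anterior interior
    r_n = params.nurse_nucleus_radius
    placed: list[tuple[float, float, float]] = []
    for i in range(params.n_nurse_nuclei):
        ok = False
        for _ in range(5000):
            pz = rng.uniform(cz - c + r_n, cz + c - r_n)
            py = rng.uniform(cy - b + r_n, cy + b - r_n)
            px = rng.uniform(cx - a + r_n, min(cx + a - r_n, cx + x_cut - r_n - 0.5))
            rho = ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 + ((pz - cz) / c) ** 2
            margin = max(1.0 - r_n / min(a, b, c) - 0.06, 0.1)
            if rho > margin**2:
                continue
            if (px - cx) + r_n + 0.5 > x_cut:
                continue
            if any(
                (pz - q[0]) ** 2 + (py - q[1]) ** 2 + (px - q[2]) ** 2
                < (2 * r_n + 0.5) ** 2
                for q in placed
            ):
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place nurse nucleus {i + 1}/{params.n_nurse_nuclei} "
                "without overlap in the anterior compartment; reduce the "
                "nucleus radius or count, or enlarge the chamber"
            )
        placed.append((pz, py, px))
        count = _paint_sphere(labels, (pz, py, px), r_n, params.voxel_size, next_label)
        rows.append(
            {
                "nucleus_id": next_label,
                "kind": "nurse",
                "centroid_z_um": pz,
                "centroid_y_um": py,
                "centroid_x_um": px,
                "radius_um": r_n,
                "voxel_count": count,
                "volume_um3": count * dz * dy * dx,
            }
        )
        next_label += 1

    if params.include_follicle:
        r_f = params.follicle_nucleus_radius
        for fz, fy, fx in _follicle_ring_centers(a, b, c, center, dz, nz, r_f):
            count = _paint_sphere(
                labels, (fz, fy, fx), r_f, params.voxel_size, next_label
            )
            if count == 0:
                continue
            rows.append(
                {
                    "nucleus_id": next_label,
                    "kind": "follicle",
                    "centroid_z_um": fz,
                    "centroid_y_um": fy,
                    "centroid_x_um": fx,
                    "radius_um": r_f,
                    "voxel_count": count,
                    "volume_um3": count * dz * dy * dx,
                }
            )
            next_label += 1

    gain_h = params.channel_gains.get("histone", 0.0)
    gain_y = params.channel_gains.get("yolk", 0.0)
    histone = np.where(labels > 0, gain_h, 0.0)
    yolk = np.where(oocyte, gain_y, 0.0)
    truth = pd.DataFrame(rows)
    if len(truth):
        truth["histone_total"] = truth["voxel_count"] * gain_h
    if params.noise_sd > 0:
        histone = histone + rng.normal(0.0, params.noise_sd, histone.shape)
        yolk = yolk + rng.normal(0.0, params.noise_sd, yolk.shape)

    stack = ImageStack(
        data={"histone": histone, "yolk": yolk}, voxel_size=params.voxel_size
    )
    table = truth.rename(columns={"nucleus_id": "label"}).assign(
        total_intensity=lambda d: d["voxel_count"] * gain_h,
        mean_intensity=gain_h,
    ) if len(truth) else pd.DataFrame()
    label_volume = LabelVolume(labels, params.voxel_size, table)
    z_top = int(np.nonzero(chamber.any(axis=(1, 2)))[0][0])
    geometry = {
        "nuclei": labels > 0,
        "nurse_nuclei": (labels > 0)
        & np.isin(labels, truth.loc[truth["kind"] == "nurse", "nucleus_id"])
        if len(truth)
        else np.zeros_like(labels, dtype=bool),
        "compartments": compartments,
        "follicle_border_z": z_top,
        "voxel_size": params.voxel_size,
        "x_cut_um": x_cut,
        "semi_axes_um": (a, b, c),
        "center_um": center,
    }
    return ChamberPhantom(stack, label_volume, truth, compartments, geometry)


# ---------------------------------------------------------------------------
# nurse-cell dumping series
# ---------------------------------------------------------------------------

@dataclass
class DumpingFlowParams:
    """First-order compartment chain for histone flux during dumping.

    Signal flows nuclei -> nurse cytoplasm -> anterior oocyte -> posterior
    oocyte with rate constants (1/h) ``k_nuc_out``, ``k_ncc_ao`` and
    ``k_ao_po``; total signal is conserved (no degradation). Independently,
    nuclear *volume* decays at ``nuclear_shrink_rate`` (1/h); a shrink rate
    exceeding ``k_nuc_out`` produces the transiently rising nuclear
    concentration seen during dumping.
    """

    k_nuc_out: float = 1.5
    k_ncc_ao: float = 2.0
    k_ao_po: float = 1.2
    nuclear_shrink_rate: float = 2.0
    duration: float = 4.0
    dt: float = 0.2
    initial_nuclear_total: float = 1.0e6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.k_nuc_out, self.k_ncc_ao, self.k_ao_po,
                 self.nuclear_shrink_rate)
        if any(k < 0 for k in rates):
            raise ValueError("rates must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one dt")
        # nuclear shrink is applied analytically, so only the transfer rates
        # constrain the integration step
        if max(self.k_nuc_out, self.k_ncc_ao, self.k_ao_po) * self.dt >= 1.0:
            raise ValueError(
                "rate*dt >= 1: time step too large for a stable explicit "
                "integration of the compartment chain"
            )

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.dt + 1e-9)) + 1
        return np.arange(n) * self.dt

    def rate_matrix(self) -> np.ndarray:
        k1, k2, k3 = self.k_nuc_out, self.k_ncc_ao, self.k_ao_po
        return np.array(
            [
                [-k1, 0.0, 0.0, 0.0],
                [k1, -k2, 0.0, 0.0],
                [0.0, k2, -k3, 0.0],
                [0.0, 0.0, k3, 0.0],
            ]
        )


def compartment_totals(params: DumpingFlowParams) -> pd.DataFrame:
    """Exact compartment totals at the frame times (matrix exponential).

    Columns: t_h, nuclear_total, ncc_total, ao_total, po_total. The rate
    matrix has zero column sums, so the row sum is conserved exactly.
    """
    step = expm(params.rate_matrix() * params.dt)
    state = np.array([params.initial_nuclear_total, 0.0, 0.0, 0.0])
    rows = [state]
    for _ in params.times[1:]:
        state = step @ state
        rows.append(state)
    arr = np.array(rows)
    return pd.DataFrame(
        {
            "t_h": params.times,
            "nuclear_total": arr[:, 0],
            "ncc_total": arr[:, 1],
            "ao_total": arr[:, 2],
            "po_total": arr[:, 3],
        }
    )


def euler_compartment_totals(params: DumpingFlowParams) -> pd.DataFrame:
    """Forward-Euler integration of the same chain (cross-check only)."""
    m = params.rate_matrix()
    state = np.array([params.initial_nuclear_total, 0.0, 0.0, 0.0])
    rows = [state]
    for _ in params.times[1:]:
        state = state + params.dt * (m @ state)
        rows.append(state)
    arr = np.array(rows)
    return pd.DataFrame(
        {
            "t_h": params.times,
            "nuclear_total": arr[:, 0],
            "ncc_total": arr[:, 1],
            "ao_total": arr[:, 2],
            "po_total": arr[:, 3],
        }
    )


@dataclass
class DumpingSeries:
    """Rendered dumping time-lapse plus exact ground truth.

    ``truth`` extends the compartment totals with per-frame nuclear volume
    (um^3). ``geometry`` holds one ROI-placement dictionary per frame (the
    nuclear mask shrinks over time).
    """

    frames: list[ImageStack]
    truth: pd.DataFrame
    geometry: list[dict]


def simulate_dumping_series(
    params: DumpingFlowParams,
    phantom: ChamberPhantomParams | None = None,
) -> DumpingSeries:
    """Render the compartment chain into an image time series.

    Each frame paints every compartment at uniform concentration
    (total / voxel count), so zero-noise frame sums match the exact ODE
    totals. Nurse nuclei shrink isotropically at ``nuclear_shrink_rate``
    (volume ~ exp(-rate*t)); follicle nuclei keep constant intensity and act
    as the normalization reference.
    """
    if phantom is None:
        phantom = ChamberPhantomParams(
            stage_or_age=80.0,
            voxel_size=(3.0, 2.0, 2.0),
            n_nurse_nuclei=6,
            nurse_nucleus_radius=6.0,
            follicle_nucleus_radius=2.0,
            z_axis_scale=0.35,
            seed=params.seed,
        )
    base = simulate_chamber_stack(phantom)
    rng = np.random.default_rng(params.seed + 1)
    voxel = phantom.voxel_size
    dzv = voxel[0] * voxel[1] * voxel[2]
    totals = compartment_totals(params)

    comp = base.compartments
    oocyte = comp == 2
    x_grid = np.broadcast_to(
        np.arange(comp.shape[2])[None, None, :] * voxel[2], comp.shape
    )
    ooc_x = x_grid[oocyte]
    # anterior oocyte takes the anterior 40% of the oocyte's AP extent, so
    # box ROIs near the nurse-oocyte border (AO) and near the per-slice
    # posterior border (PO) each fall inside their own rendered compartment
    x_split = ooc_x.min() + 0.4 * (ooc_x.max() - ooc_x.min())
    ao_region = oocyte & (x_grid < x_split)
    po_region = oocyte & (x_grid >= x_split)

    nurse_truth = base.truth[base.truth["kind"] == "nurse"]
    nurse_centers = nurse_truth[
        ["centroid_z_um", "centroid_y_um", "centroid_x_um"]
    ].to_numpy()
    r0 = float(phantom.nurse_nucleus_radius)
    follicle_mask = (
        base.labels.labels > 0
    ) & ~base.geometry["nurse_nuclei"]
    gain_f = phantom.channel_gains.get("histone", 100.0)

    frames, geoms, vols = [], [], []
    for i, t in enumerate(params.times):
        shrink = float(np.exp(-params.nuclear_shrink_rate * t))
        r_t = r0 * shrink ** (1.0 / 3.0)
        nuc_labels = np.zeros(comp.shape, dtype=np.int32)
        for j, (pz, py, px) in enumerate(nurse_centers, start=1):
            _paint_sphere(nuc_labels, (pz, py, px), r_t, voxel, j)
        nuc_mask = nuc_labels > 0
        n_nuc = int(nuc_mask.sum())
        ncc_region = (comp == 1) & ~nuc_mask
        row = totals.iloc[i]
        frame = np.zeros(comp.shape, dtype=np.float64)
        if n_nuc:
            frame[nuc_mask] = row["nuclear_total"] / n_nuc
        if ncc_region.any():
            frame[ncc_region] = row["ncc_total"] / ncc_region.sum()
        if ao_region.any():
            frame[ao_region] = row["ao_total"] / ao_region.sum()
        if po_region.any():
            frame[po_region] = row["po_total"] / po_region.sum()
        frame[follicle_mask] = gain_f
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, frame.shape)
        frames.append(
            ImageStack(data={"histone": frame}, voxel_size=voxel, t_hours=float(t))
        )
        geoms.append(
            {
                "nuclei": nuc_mask | follicle_mask,
                "nurse_nuclei": nuc_mask,
                "nurse_nucleus_labels": nuc_labels,
                "follicle_nuclei": follicle_mask,
                "compartments": comp,
                "ao_region": ao_region,
                "po_region": po_region,
                "follicle_border_z": base.geometry["follicle_border_z"],
                "voxel_size": voxel,
            }
        )
        vols.append(n_nuc * dzv)

    truth = totals.copy()
    truth["nuclear_volume_um3"] = vols
    return DumpingSeries(frames, truth, geoms)


# ---------------------------------------------------------------------------
# rotation tracks
# ---------------------------------------------------------------------------

def simulate_rotation_track(
    omega: float,
    r: float,
    duration: float,
    dt: float,
    speed_noise_sd: float = 0.0,
    n_cells: int = 5,
    y_mid: float = 0.0,
    seed: int = 0,
) -> list[CellTrack]:
    """Tracks of cells carried by uniform chamber rotation.

    The chamber rotates about the anterior-posterior (x) axis at ``omega``
    degrees/hour; a cell at phase phi projects to y = y_mid + r*sin(phi), x
    constant, matching the geometry assumed by the angular-displacement
    estimator. Initial phases are placed symmetrically about the midline so
    tracks stay in the small-angle regime for moderate durations.
    ``speed_noise_sd`` (um/min) adds Gaussian positional jitter scaled by the
    sampling interval.
    """
    if r <= 0:
        raise ValueError("chamber radius must be positive")
    if dt <= 0 or duration < dt:
        raise ValueError("need duration >= dt > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-9, dt)
    omega_rad = np.radians(omega)
    pos_noise = speed_noise_sd * dt * 60.0
    tracks = []
    for i in range(n_cells):
        phi0 = -0.5 * omega_rad * duration + np.radians(2.0 * i)
        phi = phi0 + omega_rad * t
        x = np.full_like(t, 10.0 * i)
        y = y_mid + r * np.sin(phi)
        if pos_noise > 0:
            x = x + rng.normal(0.0, pos_noise, t.shape)
            y = y + rng.normal(0.0, pos_noise, t.shape)
        tracks.append(
            CellTrack(
                cell_id=f"cell{i}",
                t_h=t,
                x_um=x,
                y_um=y,
                y_mid_um=y_mid,
                r_um=r,
            )
        )
    return tracks
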