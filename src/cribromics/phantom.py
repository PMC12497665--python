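"""Seeded synthetic phantom cohort with IVIM-form DWI signal.

The generator emulates the data structure the downstream analysis assumes:
per case a T2-weighted volume, a multi-b diffusion-weighted stack following
the biexponential intravoxel-incoherent-motion (IVIM) signal model with
Rician noise, ground-truth ADC / fractional-blood-volume maps, and one to
three labeled Gleason-pattern region masks (GP3, GP4Crib-, GP4Crib+) inside
an ellipsoidal prostate.  Cribriform (GP4Crib+) tissue is simulated with
lower diffusion than the other patterns, the contrast the classifier is
meant to pick up.

Everything is a pure function of (spec, seed): per-case random streams are
derived from (master seed, case index) so any case can be regenerated
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GLEASON_LABELS, GridGeometry, RegionMask, VolumeGrid, save_mask_nifti, save_nifti


class PhantomGenerationError(RuntimeError):
    """Raised when a region cannot be placed inside the prostate."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Diffusion protocol and grid geometry of the simulated acquisition."""

    b_values: tuple[float, ...] = (0.0, 200.0, 800.0)
    dwi_spacing: tuple[float, float, float] = (1.03, 1.03, 2.73)
    t2w_spacing: tuple[float, float, float] = (0.27, 0.27, 3.0)
    noise_sigma: float = 2.0
    field_label: str = "3T"

    def __post_init__(self) -> None:
        b = tuple(self.b_values)
        if list(b) != sorted(b):
            raise ValueError("b_values must be sorted ascending")
        if 0.0 not in b:
            raise ValueError("b_values must contain 0")
        if sum(1 for v in b if v >= 200) < 2:
            raise ValueError("b_values must contain at least two values >= 200 s/mm^2")
        if any(s <= 0 for s in self.dwi_spacing + self.t2w_spacing):
            raise ValueError("spacings must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


# The alternative scheme present in the emulated cohort.
FOUR_B_SCHEME = (0.0, 50.0, 300.0, 800.0)


@dataclass(frozen=True)
class TissueClassParams:
    """Per-tissue generative parameters.

    Diffusion coefficients are in mm^2/s; the defaults encode the
    qualitative ordering of interest (cribriform < other GP4 < GP3 <
    benign) and are synthetic stand-ins, not measured values.
    """

    label: str
    D_mean: float
    D_sd: float
    f_mean: float
    f_sd: float
    Dstar_mean: float
    t2w_mean: float
    t2w_sd: float
    volume_median_cc: float = 0.0

    def __post_init__(self) -> None:
        if self.D_mean <= 0:
            raise ValueError("D_mean must be positive")
        if not 0 <= self.f_mean < 1:
            raise ValueError("f_mean must be in [0, 1)")
        if self.Dstar_mean <= self.D_mean:
            raise ValueError("Dstar_mean must exceed D_mean")
        if self.volume_median_cc < 0:
            raise ValueError("volume_median_cc must be nonnegative")


def default_tissue_params() -> dict[str, TissueClassParams]:
    return {
        "GP4Crib+": TissueClassParams(
            label="GP4Crib+", D_mean=0.85e-3, D_sd=0.10e-3, f_mean=0.06, f_sd=0.02,
            Dstar_mean=20e-3, t2w_mean=75.0, t2w_sd=12.0, volume_median_cc=0.08,
        ),
        "GP4Crib-": TissueClassParams(
            label="GP4Crib-", D_mean=1.05e-3, D_sd=0.10e-3, f_mean=0.07, f_sd=0.02,
            Dstar_mean=20e-3, t2w_mean=85.0, t2w_sd=12.0, volume_median_cc=0.20,
        ),
        "GP3": TissueClassParams(
            label="GP3", D_mean=1.20e-3, D_sd=0.10e-3, f_mean=0.08, f_sd=0.02,
            Dstar_mean=20e-3, t2w_mean=95.0, t2w_sd=12.0, volume_median_cc=0.16,
        ),
        "benign": TissueClassParams(
            label="benign", D_mean=1.60e-3, D_sd=0.15e-3, f_mean=0.10, f_sd=0.02,
            Dstar_mean=20e-3, t2w_mean=120.0, t2w_sd=15.0, volume_median_cc=0.0,
        ),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort; the cohort is a pure function of it."""

    n_cases: int = 50
    # Class mix of the emulated region population: 52% GP3, 38% GP4Crib-, 10% GP4Crib+.
    class_proportions: tuple[tuple[str, float], ...] = (
        ("GP3", 0.52), ("GP4Crib-", 0.38), ("GP4Crib+", 0.10),
    )
    # Distribution over the number of regions per case.
    regions_per_case: tuple[tuple[int, float], ...] = ((1, 1 / 3), (2, 1 / 3), (3, 1 / 3))
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    tissue_params: tuple[tuple[str, TissueClassParams], ...] = field(
        default_factory=lambda: tuple(default_tissue_params().items())
    )
    seed: int = 0
    dwi_shape: tuple[int, int, int] = (64, 64, 20)
    # Spread (log-space sd) of the log-normal region-volume distribution.
    volume_log_sd: float = 1.0
    s0_prostate: float = 100.0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        total = sum(p for _, p in self.class_proportions)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        labels = [lab for lab, _ in self.class_proportions]
        if any(lab not in GLEASON_LABELS for lab in labels):
            raise ValueError(f"class labels must be from {GLEASON_LABELS}")

    @property
    def tissue(self) -> dict[str, TissueClassParams]:
        return dict(self.tissue_params)


@dataclass
class PhantomCase:
    case_id: str
    t2w: VolumeGrid
    dwi: dict[float, VolumeGrid]
    truth_adc: VolumeGrid
    truth_fbv: VolumeGrid
    regions: list[RegionMask]
    prostate_mask: RegionMask


def ivim_signal(S0, b, D, Dstar, f):
    """Biexponential IVIM forward model.

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

    All arguments may be scalars or broadcastable arrays.  D, D* in mm^2/s,
    b in s/mm^2, f the perfusion fraction in [0, 1].
    """
    S0, b, D, Dstar, f = (np.asarray(x, dtype=float) for x in (S0, b, D, Dstar, f))
    if np.any(S0 < 0) or np.any(b < 0) or np.any(D < 0):
        raise ValueError("S0, b and D must be nonnegative")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f must lie in [0, 1]")
    if np.any(Dstar < D):
        raise ValueError("Dstar must be >= D (pseudo-diffusion is the fast compartment)")
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D))


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |signal + N(0,s) + i N(0,s)|."""
    if sigma == 0:
        return np.asarray(signal, dtype=float)
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, case_index]))


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    geometry: GridGeometry,
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
) -> np.ndarray:
    """Rasterize an axis-aligned ellipsoid: voxel centres strictly inside."""
    out = np.zeros(shape, dtype=bool)
    # bounding box in voxel indices
    lo, hi = [], []
    for ax in range(3):
        c = (center_mm[ax] - geometry.origin[ax]) / geometry.spacing[ax]
        r = semi_axes_mm[ax] / geometry.spacing[ax]
        lo.append(max(0, int(math.floor(c - r)) - 1))
        hi.append(min(shape[ax], int(math.ceil(c + r)) + 2))
    if any(l >= h for l, h in zip(lo, hi)):
        return out
    xs = geometry.voxel_centers(shape, 0)[lo[0]:hi[0]]
    ys = geometry.voxel_centers(shape, 1)[lo[1]:hi[1]]
    zs = geometry.voxel_centers(shape, 2)[lo[2]:hi[2]]
    dx = ((xs - center_mm[0]) / semi_axes_mm[0]) ** 2
    dy = ((ys - center_mm[1]) / semi_axes_mm[1]) ** 2
    dz = ((zs - center_mm[2]) / semi_axes_mm[2]) ** 2
    inside = dx[:, None, None] + dy[None, :, None] + dz[None, None, :] <= 1.0
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    return out


def sample_region_volume(
    rng: np.random.Generator, median_cc: float, log_sd: float,
    lo_cc: float = 0.006, hi_cc: float = 3.0,
) -> float:
    """Log-normal region volume with the given median, clipped to a sane range."""
    return float(np.clip(median_cc * math.exp(rng.normal(0.0, log_sd)), lo_cc, hi_cc))


def _sample_semi_axes(rng: np.random.Generator, volume_cc: float) -> np.ndarray:
    """Random-anisotropy semi-axes (mm) with 4/3*pi*a*b*c = volume."""
    vol_mm3 = volume_cc * 1000.0
    aniso = np.exp(rng.uniform(np.log(0.6), np.log(1.6), size=3))
    r0 = (3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    axes = r0 * aniso
    # renormalize so the product matches the target volume exactly
    axes *= (3.0 * vol_mm3 / (4.0 * math.pi * np.prod(axes))) ** (1.0 / 3.0)
    return axes


def generate_phantom_case(spec: PhantomSpec, case_index: int) -> PhantomCase:
    """Generate one phantom case; deterministic given (spec.seed, case_index)."""
    if case_index >= spec.n_cases:
        raise ValueError(f"case_index {case_index} out of range for n_cases={spec.n_cases}")
    rng = _case_rng(spec.seed, case_index)
    case_id = f"case{case_index:04d}"
    proto = spec.protocol
    tissue = spec.tissue

    dwi_geom = GridGeometry(spacing=proto.dwi_spacing)
    t2w_geom = GridGeometry(spacing=proto.t2w_spacing)
    dwi_shape = spec.dwi_shape
    fov_mm = np.array(dwi_shape) * np.array(proto.dwi_spacing)
    t2w_shape = tuple(int(math.ceil(fov_mm[ax] / proto.t2w_spacing[ax])) for ax in range(3))

    # Prostate: centred ellipsoid with mild per-case size jitter.
    center = fov_mm / 2.0
    base_semi = 0.38 * fov_mm
    prostate_semi = base_semi * rng.uniform(0.9, 1.1, size=3)
    prostate = _ellipsoid_mask(dwi_shape, dwi_geom, center, prostate_semi)

    # Draw regions: labels, volumes, placements.
    n_choices = [k for k, _ in spec.regions_per_case]
    n_probs = [p for _, p in spec.regions_per_case]
    n_regions = int(rng.choice(n_choices, p=n_probs))
    labels = list(
        rng.choice(
            [lab for lab, _ in spec.class_proportions],
            size=n_regions,
            p=[p for _, p in spec.class_proportions],
        )
    )

    occupied = np.zeros(dwi_shape, dtype=bool)
    regions: list[RegionMask] = []
    region_shapes: list[tuple[np.ndarray, np.ndarray]] = []  # (center, semi_axes) for T2w pass
    for k, lab in enumerate(labels):
        params = tissue[lab]
        vol = sample_region_volume(rng, params.volume_median_cc, spec.volume_log_sd)
        placed = False
        for _ in range(200):
            semi = _sample_semi_axes(rng, vol)
            cand = center + rng.uniform(-0.6, 0.6, size=3) * prostate_semi
            vox = _ellipsoid_mask(dwi_shape, dwi_geom, cand, semi)
            if not vox.any():
                # region smaller than a voxel: force the centre voxel
                idx = tuple(
                    int(round((cand[ax] - dwi_geom.origin[ax]) / dwi_geom.spacing[ax]))
                    for ax in range(3)
                )
                if all(0 <= idx[ax] < dwi_shape[ax] for ax in range(3)):
                    vox[idx] = True
            if vox.any() and np.all(prostate[vox]) and not occupied[vox].any():
                occupied |= vox
                regions.append(
                    RegionMask(voxels=vox, geometry=dwi_geom, label=lab,
                               region_id=f"{case_id}_r{k}", case_id=case_id)
                )
                region_shapes.append((cand, semi))
                placed = True
                break
        if not placed:
            raise PhantomGenerationError(
                f"could not place a {lab} region of {vol:.3f} cc inside the prostate of {case_id}"
            )

    # Voxelwise tissue parameter fields on the DWI grid.
    D = np.zeros(dwi_shape)
    f = np.zeros(dwi_shape)
    Dstar = np.zeros(dwi_shape)
    ben = tissue["benign"]
    D[prostate] = np.maximum(rng.normal(ben.D_mean, ben.D_sd, size=int(prostate.sum())), 0.05e-3)
    f[prostate] = np.clip(rng.normal(ben.f_mean, ben.f_sd, size=int(prostate.sum())), 0.0, 0.5)
    Dstar[prostate] = ben.Dstar_mean
    for reg in regions:
        p = tissue[reg.label]
        n = reg.n_voxels
        D[reg.voxels] = np.maximum(rng.normal(p.D_mean, p.D_sd, size=n), 0.05e-3)
        f[reg.voxels] = np.clip(rng.normal(p.f_mean, p.f_sd, size=n), 0.0, 0.5)
        Dstar[reg.voxels] = p.Dstar_mean
    Dstar = np.maximum(Dstar, D + 1e-6)

    S0 = np.where(prostate, spec.s0_prostate, 0.0)
    dwi: dict[float, VolumeGrid] = {}
    for b in proto.b_values:
        clean = ivim_signal(S0, b, D, Dstar, f)
        noisy = rician_noise(clean, proto.noise_sigma, rng)
        dwi[float(b)] = VolumeGrid(data=noisy, geometry=dwi_geom)

    truth_adc = VolumeGrid(data=np.where(prostate, D, 0.0), geometry=dwi_geom)
    truth_fbv = VolumeGrid(data=np.where(prostate, f, 0.0), geometry=dwi_geom)

    # T2w: analytic re-rasterization of prostate and regions on the fine grid.
    t2w = rng.normal(20.0, 5.0, size=t2w_shape)
    prost_t2 = _ellipsoid_mask(t2w_shape, t2w_geom, center, prostate_semi)
    t2w[prost_t2] = rng.normal(ben.t2w_mean, ben.t2w_sd, size=int(prost_t2.sum()))
    for reg, (c, semi) in zip(regions, region_shapes):
        p = tissue[reg.label]
        vox_t2 = _ellipsoid_mask(t2w_shape, t2w_geom, c, semi)
        t2w[vox_t2] = rng.normal(p.t2w_mean, p.t2w_sd, size=int(vox_t2.sum()))
    t2w_vol = VolumeGrid(data=t2w, geometry=t2w_geom)

    return PhantomCase(
        case_id=case_id,
        t2w=t2w_vol,
        dwi=dwi,
        truth_adc=truth_adc,
        truth_fbv=truth_fbv,
        regions=regions,
        prostate_mask=RegionMask(voxels=prostate, geometry=dwi_geom, label="GP3",
                                 region_id=f"{case_id}_prostate", case_id=case_id),
    )


def cohort_manifest(cases: list[PhantomCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        for reg in case.regions:
            rows.append(
                {
                    "case_id": case.case_id,
                    "region_id": reg.region_id,
                    "label": reg.label,
                    "volume_cc": reg.volume_cc,
                    "n_voxels": reg.n_voxels,
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(spec: PhantomSpec, out_dir=None) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate the full cohort; optionally write NIfTI volumes and a CSV manifest.

    Returns the in-memory cases and the manifest table (one row per region).
    For large cohorts prefer iterating :func:`generate_phantom_case` and
    discarding cases after use; this function keeps everything in memory.
    """
    cases = [generate_phantom_case(spec, i) for i in range(spec.n_cases)]
    manifest = cohort_manifest(cases)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for case in cases:
            cdir = out / case.case_id
            cdir.mkdir(exist_ok=True)
            save_nifti(case.t2w, cdir / "t2w.nii.gz")
            for b, vol in case.dwi.items():
                save_nifti(vol, cdir / f"dwi_b{int(b)}.nii.gz")
            save_nifti(case.truth_adc, cdir / "truth_adc.nii.gz")
            save_nifti(case.truth_fbv, cdir / "truth_fbv.nii.gz")
            save_mask_nifti(case.prostate_mask, cdir / "prostate_mask.nii.gz")
            (cdir / "bvals.txt").write_text(
                "\n".join(str(int(b)) for b in spec.protocol.b_values) + "\n"
            )
            for reg in case.regions:
                save_mask_nifti(reg, cdir / f"{reg.region_id}.nii.gz")
        for case in cases:
            for reg in case.regions:
                paths.append(str(Path(out) / case.case_id / f"{reg.region_id}.nii.gz"))
        manifest = manifest.assign(path=paths)
        manifest.to_csv(out / "manifest.csv", index=False)
    return cases, manifest
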