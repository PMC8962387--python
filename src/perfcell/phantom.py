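"""Digital phantom: ground-truth perfusion fields, DSC bolus series, SWI cell spots.

The phantom emulates a selective intra-arterial perfusion study in the rat:

* smooth, spatially correlated CBF and MTT fields inside an ellipsoidal
  brain, with CBV tied to them by the central volume theorem
  (CBV = CBF * MTT / 60, units mL/100g with CBF in mL/100g/min and MTT in s);
* an optional unilateral ischemic lesion (CBF scaled down, MTT prolonged);
* a gamma-variate arterial input function and the standard tracer-kinetic
  tissue model C(t) = (CBF/6000) * (AIF (*) R)(t) with an exponential
  residue function, mapped to T2*-weighted signal
  S(t) = S0 * exp(-TE * k * C(t)) + noise;
* a pre/post SWI magnitude pair in which iron-labeled cells appear as focal
  hypointense spots, placed with a tunable rank correlation ("coupling")
  between local spot density and CBV.

Every generator is a pure function of its arguments including the seed.

Discretisation of the residue function
--------------------------------------
On the TR grid the residue keeps the exponential shape exp(-k*TR/MTT) with
R[0] = 1 (so the peak of the deconvolved residue equals the true flow), but
the k >= 1 tail is rescaled by a constant so that TR * sum(R) = MTT exactly.
With that normalisation the discrete tracer mass balance
AUC(C) / AUC(AIF) = CBF * MTT / 6000 = CBV / 100 holds voxelwise to
floating-point accuracy, i.e. kappa = 100 relates the relative CBV map to
the ground-truth field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz
from scipy.ndimage import gaussian_filter
from scipy.stats import norm, rankdata, spearmanr

from .io import affine_from_voxel_size, save_json, save_volume
from .perfusion import DynamicSeries

__all__ = [
    "AcquisitionParams",
    "AIF",
    "GroundTruthPhantom",
    "CellPlacementSpec",
    "gamma_variate_aif",
    "generate_phantom",
    "discrete_residue",
    "simulate_dynamic_series",
    "simulate_swi_pair",
    "realized_coupling",
    "generate_cohort",
    "CBV_KAPPA",
]

#: AUC(C)/AUC(AIF) = cbv / CBV_KAPPA for the noiseless simulator (see module docstring)
CBV_KAPPA = 100.0

#: Gaussian smoothing FWHM (in voxels) of the seeded white noise behind the fields
FIELD_FWHM_VOX = 4.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AcquisitionParams:
    """Dynamic-series acquisition parameters.

    Defaults follow a 220-frame EPI bolus protocol with TR/TE = 1500/15 ms.
    ``noise_sd`` is the additive Gaussian noise SD on the magnitude signal;
    the default corresponds to SNR 20 at baseline (s0 / 20).
    """

    tr: float = 1.5
    te: float = 0.015
    n_frames: int = 220
    n_baseline: int = 10
    s0: float = 1000.0
    k_t2star: float = 140.0
    noise_sd: float = 50.0

    def __post_init__(self):
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("tr and te must be positive")
        if not (1 <= self.n_baseline < self.n_frames):
            raise ValueError("need 1 <= n_baseline < n_frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr


@dataclass
class AIF:
    """Arterial input function on the acquisition time grid (concentration, mM)."""

    times: np.ndarray
    concentration: np.ndarray
    params: dict

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.concentration = np.asarray(self.concentration, float)
        if self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must have equal length")
        if np.min(self.concentration) < 0:
            raise ValueError("AIF concentration must be non-negative")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("AIF concentration must be finite")


def gamma_variate_aif(
    acq: AcquisitionParams,
    t0: Optional[float] = None,
    alpha: float = 3.0,
    beta: float = 1.5,
    peak_conc: float = 5.0,
) -> AIF:
    """Gamma-variate input function A*(t-t0)^alpha*exp(-(t-t0)/beta), zero before t0.

    ``peak_conc`` (mM) fixes the amplitude via the analytic peak at
    t0 + alpha*beta.  The default delay puts the bolus arrival right at the
    end of the pre-bolus baseline, t0 = n_baseline * tr.
    """
    if t0 is None:
        t0 = acq.n_baseline * acq.tr
    t = acq.times
    amplitude = peak_conc / ((alpha * beta) ** alpha * np.exp(-alpha))
    dt = np.clip(t - t0, 0.0, None)
    conc = amplitude * dt**alpha * np.exp(-dt / beta)
    conc[t <= t0] = 0.0
    return AIF(
        times=t,
        concentration=conc,
        params={"t0": float(t0), "amplitude": float(amplitude), "alpha": alpha, "beta": beta},
    )


@dataclass
class GroundTruthPhantom:
    """Ground-truth perfusion fields and masks (the recovery oracle).

    Invariants: cbv = cbf * mtt / 60 voxelwise inside the brain; all fields
    non-negative and zero outside the brain; lesion inside the brain.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    voxel_size: tuple = (0.3, 0.3, 0.6)
    artery_mask: Optional[np.ndarray] = None
    true_cell_mask: Optional[np.ndarray] = None

    @property
    def affine(self) -> np.ndarray:
        return affine_from_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.cbf.shape

    def right_hemisphere(self) -> np.ndarray:
        """Boolean mask of the injected (right) hemisphere, split on axis 0."""
        m = np.zeros(self.shape, dtype=bool)
        m[self.shape[0] // 2 :] = True
        return m


MIN_INPLANE = 8
MIN_SLICES = 4


def generate_phantom(
    shape: Sequence[int],
    with_lesion: bool = False,
    seed: int = 0,
    voxel_size: tuple = (0.3, 0.3, 0.6),
    cbf_range: tuple = (30.0, 120.0),
    mtt_range: tuple = (1.5, 6.0),
    lesion_cbf_factor: float = 0.3,
    lesion_mtt_factor: float = 2.0,
    with_arteries: bool = True,
) -> GroundTruthPhantom:
    """Generate smooth ground-truth CBF/MTT fields in an ellipsoidal brain.

    CBF and MTT are independently seeded Gaussian-filtered white-noise fields
    (FWHM 4 voxels) mapped affinely into physiologic ranges; CBV follows from
    the central volume theorem.  ``with_lesion`` carves a contiguous
    unilateral lesion with CBF scaled by ``lesion_cbf_factor`` and MTT
    prolonged by ``lesion_mtt_factor``.  A small "arterial" voxel cluster is
    marked so that the dynamic simulator can give it an input-function-like
    curve, which the automatic AIF search can find.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3D")
    if shape[0] < MIN_INPLANE or shape[1] < MIN_INPLANE:
        raise ValueError(f"in-plane dimensions must be >= {MIN_INPLANE}, got {shape}")
    if shape[2] < MIN_SLICES:
        raise ValueError(f"need >= {MIN_SLICES} slices, got {shape}")

    rng = np.random.default_rng(seed)
    grid = np.indices(shape, dtype=np.float64)
    center = (np.array(shape, float) - 1.0) / 2.0
    semi = 0.42 * np.array(shape, float)
    dist2 = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    brain = dist2 <= 1.0

    sigma = FIELD_FWHM_VOX * _FWHM_TO_SIGMA

    def smooth_field(lo, hi):
        f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        vals = f[brain]
        span = vals.max() - vals.min()
        if span <= 0:
            span = 1.0
        return lo + (f - vals.min()) * (hi - lo) / span

    cbf = smooth_field(*cbf_range)
    mtt = smooth_field(*mtt_range)

    lesion = np.zeros(shape, dtype=bool)
    if with_lesion:
        # contiguous ball in the right hemisphere (the injected/occluded side)
        lc = np.array([0.72 * shape[0], 0.5 * shape[1], 0.5 * shape[2]])
        radius = max(2.0, min(shape) / 3.0)
        ldist2 = sum((grid[i] - lc[i]) ** 2 for i in range(3))
        lesion = (ldist2 <= radius**2) & brain
        cbf = np.where(lesion, cbf * lesion_cbf_factor, cbf)
        mtt = np.where(lesion, mtt * lesion_mtt_factor, mtt)

    artery = None
    if with_arteries:
        ac = np.array([shape[0] // 2, shape[1] // 2, max(1, shape[2] // 4)])
        adist2 = sum((grid[i] - ac[i]) ** 2 for i in range(3))
        artery = (adist2 <= 1.0**2) & brain
        if not artery.any():  # tiny grids: fall back to the center voxel
            artery = np.zeros(shape, dtype=bool)
            artery[tuple(int(c) for c in center)] = True

    cbf = np.where(brain, cbf, 0.0)
    mtt = np.where(brain, mtt, 0.0)
    cbv = cbf * mtt / 60.0

    return GroundTruthPhantom(
        cbf=cbf,
        cbv=cbv,
        mtt=mtt,
        brain_mask=brain,
        lesion_mask=lesion,
        voxel_size=tuple(voxel_size),
        artery_mask=artery,
    )


def discrete_residue(mtt: np.ndarray, tr: float, n_frames: int) -> np.ndarray:
    """Exponential-shape discrete residue with R[0]=1 and tr*sum(R) = mtt exactly.

    ``mtt`` may be any array shape; the result has one extra trailing time
    axis of length ``n_frames``.  Requires mtt >= tr (the tail weight is
    clipped at 0, in which case the discrete area is tr, for mtt < tr).
    """
    m = np.asarray(mtt, dtype=np.float64)[..., None]
    k = np.arange(n_frames, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x = tr / m
        kappa = np.clip((m / tr - 1.0) * (np.exp(x) - 1.0), 0.0, None)
        r = kappa * np.exp(-k * x)
    r[..., 0] = 1.0
    return np.where(np.isfinite(r), r, 0.0)


def simulate_dynamic_series(
    phantom: GroundTruthPhantom,
    aif: AIF,
    acq: AcquisitionParams,
    seed: int = 0,
    artery_conc_scale: float = 0.15,
    background_frac: float = 0.05,
) -> DynamicSeries:
    """Simulate the 4D bolus-passage series from the ground-truth fields.

    Per in-brain voxel, C(t) = (cbf/6000) * tr * (AIF (*) R)(t) on the TR
    grid, S(t) = s0 * exp(-te * k_t2star * C(t)) + Gaussian noise (clipped at
    0).  Arterial voxels carry ``artery_conc_scale * AIF`` directly; outside
    the brain the signal is a constant background of
    ``background_frac * s0`` (plus noise).
    """
    if aif.times.shape[0] != acq.n_frames or not np.allclose(aif.times, acq.times):
        raise ValueError("AIF is not sampled on the acquisition time grid")

    rng = np.random.default_rng(seed)
    nt = acq.n_frames
    brain = phantom.brain_mask
    conc = np.zeros(phantom.shape + (nt,), dtype=np.float64)

    A = toeplitz(aif.concentration, np.zeros(nt))  # A[i, k] = AIF[i - k]
    mtt_vox = phantom.mtt[brain]
    cbf_vox = phantom.cbf[brain]
    flow = cbf_vox / 6000.0  # mL/100g/min -> 1/s
    resid = discrete_residue(mtt_vox, acq.tr, nt)
    conc[brain] = flow[:, None] * (acq.tr * (resid @ A.T))

    if phantom.artery_mask is not None and phantom.artery_mask.any():
        conc[phantom.artery_mask] = artery_conc_scale * aif.concentration

    signal = acq.s0 * np.exp(-acq.te * acq.k_t2star * conc)
    signal[~brain] = background_frac * acq.s0
    if acq.noise_sd > 0:
        signal = signal + rng.normal(0.0, acq.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    return DynamicSeries(
        signal=signal,
        tr=acq.tr,
        te=acq.te,
        affine=phantom.affine,
        brain_mask=brain,
    )


# --------------------------------------------------------------------------
# SWI cell-spot simulation with calibrated perfusion coupling
# --------------------------------------------------------------------------


@dataclass
class CellPlacementSpec:
    """Placement of hypointense cell spots on the post-transplantation SWI.

    ``coupling`` is the target rank correlation between local spot density
    and the CBV field, in [-1, 1]; ``spot_drop`` the fractional SWI signal
    reduction inside a spot; ``leak_frac`` the share of spots allowed into
    the contralateral hemisphere (cells injected via one carotid stay mostly
    ipsilateral).
    """

    n_cells: int = 2000
    coupling: float = 0.6
    spot_radius: int = 1
    spot_drop: float = 0.5
    seed: int = 0
    leak_frac: float = 0.05

    def __post_init__(self):
        if not (-1.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [-1, 1]")
        if not (0.0 < self.spot_drop <= 1.0):
            raise ValueError("spot_drop must lie in (0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.spot_radius < 0:
            raise ValueError("spot_radius must be >= 0")


# Mixing-weight calibration: realized Spearman(local spot density, cbv) as a
# function of the normal-score mixing weight w, measured at the generator's
# default geometry (32x32x12 phantom, 2x2x4 SWI refinement, 2000 spots,
# spot_radius 1, density kernel 0.45 mm).  Determined offline by bisection;
# interpolated monotonically and extended oddly for negative coupling.
_COUPLING_TABLE_RHO = np.array([0.0, 0.3, 0.6, 0.9])
_COUPLING_TABLE_W = np.array([0.0, 0.40, 0.74, 0.97])

#: sharpness of the exponential tilt turning the mixed score into placement odds
PLACEMENT_SHARPNESS = 3.0


def _coupling_to_weight(coupling: float) -> float:
    c = abs(float(coupling))
    w = float(np.interp(c, _COUPLING_TABLE_RHO, _COUPLING_TABLE_W))
    if c > _COUPLING_TABLE_RHO[-1]:  # extrapolate linearly toward w=1
        span = 1.0 - _COUPLING_TABLE_RHO[-1]
        w = _COUPLING_TABLE_W[-1] + (c - _COUPLING_TABLE_RHO[-1]) / span * (
            1.0 - _COUPLING_TABLE_W[-1]
        )
    return float(np.sign(coupling) * min(w, 1.0))


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = rankdata(values)
    return norm.ppf(ranks / (len(values) + 1.0))


def simulate_swi_pair(
    phantom: GroundTruthPhantom,
    spec: CellPlacementSpec,
    swi_shape: Sequence[int],
    s0: float = 1000.0,
    texture_frac: float = 0.08,
    snr: float = 40.0,
):
    """Simulate the pre/post SWI magnitude pair with spherical cell spots.

    ``swi_shape`` must be an integer per-axis refinement of the phantom grid.
    Spot centers are drawn (within the injected hemisphere, with a small
    contralateral leak) from a probability field built by mixing the
    normal-scores of CBV with an independent smooth field; the mixing weight
    is calibrated so that the realized rank correlation between local spot
    density and CBV approaches ``spec.coupling``.  Post = pre with spot
    voxels multiplied by (1 - spot_drop).

    Returns ``(pre, post, true_mask)`` with the volumes as
    :class:`~perfcell.cells.SWIVolume` and ``true_mask`` the boolean spot
    mask on the SWI grid.  The phantom's ``true_cell_mask`` is filled in.
    """
    from .cells import SWIVolume  # local import to avoid a module cycle

    swi_shape = tuple(int(s) for s in swi_shape)
    factors = []
    for a, (sw, ph) in enumerate(zip(swi_shape, phantom.shape)):
        if sw % ph != 0 or sw < ph:
            raise ValueError(
                f"swi_shape must be an integer refinement of the phantom grid; "
                f"axis {a}: {sw} vs {ph}"
            )
        factors.append(sw // ph)
    factors = tuple(factors)
    swi_voxel = tuple(v / f for v, f in zip(phantom.voxel_size, factors))
    affine = affine_from_voxel_size(swi_voxel)

    rng = np.random.default_rng(spec.seed)
    sigma = FIELD_FWHM_VOX * _FWHM_TO_SIGMA
    texture = gaussian_filter(rng.standard_normal(swi_shape), sigma=sigma)
    pre = s0 * (1.0 + texture_frac * texture)
    if snr > 0:
        pre = pre + rng.normal(0.0, s0 / snr, size=swi_shape)
    pre = np.clip(pre, 0.0, None)

    true_mask = np.zeros(swi_shape, dtype=bool)
    post = pre.copy()

    if spec.n_cells > 0:
        support = phantom.brain_mask & phantom.right_hemisphere()
        contra = phantom.brain_mask & ~phantom.right_hemisphere()
        if not support.any():
            raise ValueError("phantom has no brain voxels in the injected hemisphere")

        w = _coupling_to_weight(spec.coupling)
        u = _normal_scores(phantom.cbv[support])
        g_field = gaussian_filter(rng.standard_normal(phantom.shape), sigma=sigma)
        g = _normal_scores(g_field[support])
        z = w * u + np.sqrt(max(0.0, 1.0 - w**2)) * g
        logits = PLACEMENT_SHARPNESS * z
        p = np.exp(logits - logits.max())
        p /= p.sum()

        support_idx = np.argwhere(support)
        contra_idx = np.argwhere(contra)
        n_leak = int(round(spec.leak_frac * spec.n_cells)) if len(contra_idx) else 0
        n_main = spec.n_cells - n_leak

        chosen = support_idx[rng.choice(len(support_idx), size=n_main, p=p)]
        if n_leak:
            leak = contra_idx[rng.choice(len(contra_idx), size=n_leak)]
            chosen = np.vstack([chosen, leak])

        # phantom voxel -> uniformly random SWI voxel inside its block
        offsets = np.column_stack([rng.integers(0, f, size=len(chosen)) for f in factors])
        centers = chosen * np.array(factors) + offsets

        ball = _ball_offsets(spec.spot_radius)
        spots = centers[:, None, :] + ball[None, :, :]
        for a, n in enumerate(swi_shape):
            spots[..., a] = np.clip(spots[..., a], 0, n - 1)
        flat = np.ravel_multi_index(
            (spots[..., 0].ravel(), spots[..., 1].ravel(), spots[..., 2].ravel()), swi_shape
        )
        true_mask.ravel()[flat] = True
        post = np.where(true_mask, pre * (1.0 - spec.spot_drop), pre)

    phantom.true_cell_mask = true_mask
    return (
        SWIVolume(intensity=pre, affine=affine, label="pre"),
        SWIVolume(intensity=post, affine=affine, label="post"),
        true_mask,
    )


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    rng_ = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng_, rng_, rng_, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def realized_coupling(
    phantom: GroundTruthPhantom,
    true_mask: np.ndarray,
    kernel_radius: float = 0.45,
    median_radius: int = 1,
) -> float:
    """Measure the realized rank correlation between spot density and CBV.

    The true spot mask is turned into a density map exactly as the analysis
    arm does (spherical kernel convolution, mean pooling to the phantom grid,
    median filter) and correlated with the CBV field over the injected
    hemisphere inside the brain -- the blood-supply territory of the infusion,
    which is where the coupling is defined (the small contralateral leak is
    uniform by construction and carries no perfusion signal).
    """
    from .cells import CellMask, compute_density_map

    factors = tuple(sw // ph for sw, ph in zip(true_mask.shape, phantom.shape))
    swi_voxel = tuple(v / f for v, f in zip(phantom.voxel_size, factors))
    brain_swi = phantom.brain_mask
    for ax, f in enumerate(factors):
        brain_swi = np.repeat(brain_swi, f, axis=ax)
    mask = CellMask(mask=true_mask & brain_swi, n_components=0, min_component_kept=0)
    dens = compute_density_map(
        mask,
        target_shape=phantom.shape,
        voxel_size=swi_voxel,
        kernel_radius=kernel_radius,
        median_radius=median_radius,
    )
    region = phantom.brain_mask & phantom.right_hemisphere()
    if region.sum() < 3:
        return float("nan")
    rho, _ = spearmanr(dens.density[region], phantom.cbv[region])
    return float(rho)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "animal_id",
    "group",
    "series_path",
    "swi_pre_path",
    "swi_post_path",
    "mask_path",
    "seed",
]


def generate_cohort(
    n_intact: int,
    n_stroke: int,
    coupling: float,
    base_seed: int,
    out_dir,
    shape: Sequence[int] = (32, 32, 12),
    swi_factors: Sequence[int] = (2, 2, 4),
    acq: Optional[AcquisitionParams] = None,
    n_cells: int = 2000,
    spot_radius: int = 1,
    spot_drop: float = 0.5,
) -> pd.DataFrame:
    """Write a full synthetic study to disk and return its manifest.

    Per animal: the 4D dynamic series, pre/post SWI, brain mask (all NIfTI),
    ground-truth sidecars (CBF/CBV/MTT/true-cell NIfTIs plus a JSON with the
    AIF, acquisition parameters and seeds), one row in ``manifest.csv``.
    Deterministic given ``base_seed``.
    """
    if n_intact < 0 or n_stroke < 0:
        raise ValueError("group sizes must be >= 0")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out_dir} is not writable: {e}") from e

    if acq is None:
        acq = AcquisitionParams()
    shape = tuple(int(s) for s in shape)
    swi_shape = tuple(s * f for s, f in zip(shape, swi_factors))

    rows = []
    groups = ["intact"] * n_intact + ["stroke"] * n_stroke
    for i, group in enumerate(groups):
        animal_id = f"{group}_{i:02d}"
        seed = int((base_seed * 10007 + i * 131) % (2**31 - 1))
        adir = out_dir / animal_id
        adir.mkdir(parents=True, exist_ok=True)

        phantom = generate_phantom(shape, with_lesion=(group == "stroke"), seed=seed)
        aif = gamma_variate_aif(acq)
        series = simulate_dynamic_series(phantom, aif, acq, seed=seed + 1)
        spec = CellPlacementSpec(
            n_cells=n_cells,
            coupling=coupling,
            spot_radius=spot_radius,
            spot_drop=spot_drop,
            seed=seed + 2,
        )
        pre, post, true_mask = simulate_swi_pair(phantom, spec, swi_shape)

        series_path = save_volume(series.signal, phantom.affine, adir / "series.nii.gz")
        pre_path = save_volume(pre.intensity, pre.affine, adir / "swi_pre.nii.gz")
        post_path = save_volume(post.intensity, post.affine, adir / "swi_post.nii.gz")
        mask_path = save_volume(
            phantom.brain_mask.astype(np.uint8), phantom.affine, adir / "brain_mask.nii.gz"
        )
        save_volume(phantom.cbf, phantom.affine, adir / "gt_cbf.nii.gz")
        save_volume(phantom.cbv, phantom.affine, adir / "gt_cbv.nii.gz")
        save_volume(phantom.mtt, phantom.affine, adir / "gt_mtt.nii.gz")
        save_volume(
            phantom.lesion_mask.astype(np.uint8), phantom.affine, adir / "gt_lesion.nii.gz"
        )
        save_volume(true_mask.astype(np.uint8), pre.affine, adir / "gt_true_cells.nii.gz")
        if phantom.artery_mask is not None:
            save_volume(
                phantom.artery_mask.astype(np.uint8), phantom.affine, adir / "gt_arteries.nii.gz"
            )
        save_json(
            {
                "animal_id": animal_id,
                "group": group,
                "seed": seed,
                "coupling": coupling,
                "acq": {
                    "tr": acq.tr,
                    "te": acq.te,
                    "n_frames": acq.n_frames,
                    "n_baseline": acq.n_baseline,
                    "s0": acq.s0,
                    "k_t2star": acq.k_t2star,
                    "noise_sd": acq.noise_sd,
                },
                "aif_params": aif.params,
                "aif_concentration_mM": aif.concentration,
                "bolus_arrival_frame": acq.n_baseline,
                "voxel_size_mm": phantom.voxel_size,
                "swi_voxel_size_mm": [v / f for v, f in zip(phantom.voxel_size, swi_factors)],
            },
            adir / "ground_truth.json",
        )

        rows.append(
            {
                "animal_id": animal_id,
                "group": group,
                "series_path": str(series_path),
                "swi_pre_path": str(pre_path),
                "swi_post_path": str(post_path),
                "mask_path": str(mask_path),
                "seed": seed,
            }
        )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
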