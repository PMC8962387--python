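"""Perfusion parameter maps from a dynamic susceptibility-contrast (DSC) bolus series.

Eight parametric maps are computed from the 4D T2*-weighted bolus-passage
series.  Four "basemaps" are read directly off the signal/concentration
curves, before any deconvolution:

* TTP       -- time to the concentration peak, from bolus arrival (s);
* dSoverS   -- normalized maximal signal drop (S0 - min S)/S0, in [0, 1];
* MS        -- maximum signal downslope between consecutive frames
               (signal units per second);
* CBV-AUC   -- area under the concentration-time curve (relative CBV).

Four more come from deconvolving the tissue concentration with an arterial
input function (AIF) by truncated standard singular value decomposition
(sSVD), i.e. solving  c = A r  where A is the lower-triangular Toeplitz
convolution matrix built from the AIF:

* CBF-sSVD  -- max of the scaled residue function r(t) (relative flow, 1/s);
* CBV-sSVD  -- integral C dt / integral AIF dt (relative volume);
* MTT-sSVD  -- CBV / CBF, the mean transit time (s), by the central volume
               theorem (exactly by construction);
* Tmax-sSVD -- time of the residue-function maximum (s).

All maps are relative: the arbitrary proportionality constant between the
measured DR2* and true concentration cancels in every rank- or
regression-based statistic downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "DynamicSeries",
    "ConcentrationSeries",
    "PerfusionMapSet",
    "AIFSelection",
    "detect_bolus_and_baseline",
    "signal_to_concentration",
    "compute_basemaps",
    "select_aif",
    "ssvd_deconvolve",
    "median_filter_maps",
    "mask_maps",
    "compute_all_maps",
    "MAP_NAMES",
    "AMPLITUDE_MAPS",
    "TIMING_MAPS",
]

MAP_NAMES = (
    "ttp",
    "dsovers",
    "ms",
    "cbv_auc",
    "cbf_ssvd",
    "cbv_ssvd",
    "mtt_ssvd",
    "tmax_ssvd",
)
#: maps driven by bolus amplitude vs. maps driven by bolus timing
AMPLITUDE_MAPS = ("dsovers", "cbv_auc", "cbv_ssvd", "cbf_ssvd")
TIMING_MAPS = ("ttp", "mtt_ssvd", "tmax_ssvd")


@dataclass
class DynamicSeries:
    """4D dynamic signal S(x, t) with acquisition timing.

    Parameters
    ----------
    signal : (nx, ny, nz, nt) array, non-negative, arbitrary units.
    tr : repetition time / frame spacing, seconds.
    te : echo time, seconds.
    affine : 4x4 NIfTI world transform of the spatial grid.
    brain_mask : optional 3D boolean mask of intracranial voxels.
    """

    signal: np.ndarray
    tr: float
    te: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    brain_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 4:
            raise ValueError("signal must be a 4D (x, y, z, t) array")
        if self.signal.shape[-1] < 8:
            raise ValueError("need at least 8 time frames")
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("tr and te must be positive")
        if np.nanmin(self.signal) < 0:
            raise ValueError("signal must be non-negative")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.signal.shape[:3]:
                raise ValueError("brain_mask shape must match the spatial grid")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr


@dataclass
class ConcentrationSeries:
    """Relative tracer concentration C(x, t) derived from the signal drop."""

    conc: np.ndarray
    tr: float
    s0_map: np.ndarray
    bolus_frame: int

    @property
    def n_frames(self) -> int:
        return self.conc.shape[-1]


@dataclass
class PerfusionMapSet:
    """Container for the eight 3D perfusion maps (missing maps are None)."""

    ttp: Optional[np.ndarray] = None
    dsovers: Optional[np.ndarray] = None
    ms: Optional[np.ndarray] = None
    cbv_auc: Optional[np.ndarray] = None
    cbf_ssvd: Optional[np.ndarray] = None
    cbv_ssvd: Optional[np.ndarray] = None
    mtt_ssvd: Optional[np.ndarray] = None
    tmax_ssvd: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in MAP_NAMES if getattr(self, k) is not None}

    def merged_with(self, other: "PerfusionMapSet") -> "PerfusionMapSet":
        kwargs = {k: getattr(self, k) for k in MAP_NAMES}
        for k in MAP_NAMES:
            if getattr(other, k) is not None:
                kwargs[k] = getattr(other, k)
        return PerfusionMapSet(**kwargs)


@dataclass
class AIFSelection:
    """Arterial input function sampled on the series time grid."""

    voxel_list: list
    curve: np.ndarray
    method: str

    def __post_init__(self):
        self.curve = np.asarray(self.curve, dtype=np.float64)
        if np.nanmin(self.curve) < -1e-12:
            raise ValueError("AIF curve must be non-negative")
        if np.trapezoid(self.curve) <= 0:
            raise ValueError("AIF curve must have positive area")

    @classmethod
    def from_curve(cls, curve, method: str = "manual") -> "AIFSelection":
        return cls(voxel_list=[], curve=np.asarray(curve, float), method=method)


def detect_bolus_and_baseline(series: DynamicSeries) -> tuple[int, np.ndarray]:
    """Locate the bolus-arrival frame and compute the per-voxel baseline S0.

    The brain-mean signal is scanned forward; the first frame falling more
    than 3 running-baseline SDs (with a tiny relative floor, so a strict drop
    in noiseless data still triggers) below the running baseline mean marks
    the first post-arrival frame.  The returned ``bolus_frame`` is the frame
    *before* it -- the last pre-bolus frame -- and ``s0_map`` averages frames
    ``[0, bolus_frame)``.

    Raises
    ------
    ValueError
        If no drop is ever detected ("no bolus").
    """
    if series.brain_mask is not None and series.brain_mask.any():
        curve = series.signal[series.brain_mask].mean(axis=0)
    else:
        curve = series.signal.reshape(-1, series.n_frames).mean(axis=0)

    n = len(curve)
    first_drop = None
    for i in range(min(6, n - 1), n):
        mu = curve[:i].mean()
        sd = curve[:i].std()
        thresh = mu - max(3.0 * sd, 1e-9 * abs(mu))
        # require a sustained (two-frame) drop so a single noisy baseline
        # frame cannot truncate the baseline window
        if curve[i] < thresh and (i + 1 >= n or curve[i + 1] < thresh):
            first_drop = i
            break
    if first_drop is None:
        raise ValueError("no bolus")

    bolus_frame = first_drop - 1
    if bolus_frame < 4:
        warnings.warn(
            f"bolus arrives at frame {bolus_frame} (<4): baseline estimated "
            "from the few available pre-bolus frames",
            stacklevel=2,
        )
    n_base = max(bolus_frame, 1)
    s0_map = series.signal[..., :n_base].mean(axis=-1)
    return bolus_frame, s0_map


def signal_to_concentration(
    series: DynamicSeries, s0_map: np.ndarray, bolus_frame: int
) -> ConcentrationSeries:
    """Convert signal to relative concentration, C = -ln(S/S0)/TE, clamped at 0.

    Voxels with non-positive baseline are set to NaN.  The proportionality
    constant between DR2* and true contrast concentration is taken as 1:
    all downstream statistics are rank- or regression-based, so only relative
    perfusion is needed.
    """
    s0 = np.asarray(s0_map, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = series.signal / s0[..., None]
        conc = -np.log(ratio) / series.te
    conc = np.where(conc > 0, conc, 0.0)
    conc[(s0 <= 0) | ~np.isfinite(s0)] = np.nan
    return ConcentrationSeries(conc=conc, tr=series.tr, s0_map=s0, bolus_frame=int(bolus_frame))


def compute_basemaps(series: DynamicSeries, conc: ConcentrationSeries) -> PerfusionMapSet:
    """Pre-deconvolution maps: TTP, dSoverS, MS, CBV-AUC.

    TTP is the time of the concentration peak measured from the bolus-arrival
    frame, earliest frame winning ties; dSoverS = (S0 - min S)/S0 over the
    post-arrival window; MS is the maximum signal downslope between
    consecutive frames; CBV-AUC is the trapezoidal integral of C(t) from the
    bolus frame to the end of the series.
    """
    if conc.conc.shape != series.signal.shape:
        raise ValueError("concentration series is not aligned with the signal series")
    b = conc.bolus_frame
    tr = series.tr
    post_c = conc.conc[..., b:]
    post_s = series.signal[..., b:]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ttp = tr * np.nanargmax(_nan_to_neginf(post_c), axis=-1).astype(np.float64)
        s0 = conc.s0_map
        with np.errstate(divide="ignore", invalid="ignore"):
            dsovers = (s0 - np.nanmin(post_s, axis=-1)) / s0
        dsovers = np.clip(dsovers, 0.0, 1.0)
        downslope = -np.diff(series.signal, axis=-1) / tr
        ms = np.clip(np.nanmax(downslope, axis=-1), 0.0, None)
        cbv_auc = np.trapezoid(post_c, dx=tr, axis=-1)

    all_nan = np.isnan(conc.conc).all(axis=-1)
    for m in (ttp, dsovers, ms, cbv_auc):
        m[all_nan] = np.nan
    bad_s0 = (s0 <= 0) | ~np.isfinite(s0)
    dsovers[bad_s0] = np.nan
    return PerfusionMapSet(ttp=ttp, dsovers=dsovers, ms=ms, cbv_auc=cbv_auc)


def _nan_to_neginf(a):
    return np.where(np.isnan(a), -np.inf, a)


def select_aif(
    conc: ConcentrationSeries,
    mode="auto",
    brain_mask: Optional[np.ndarray] = None,
    n_candidates: int = 5,
) -> AIFSelection:
    """Select an arterial input function from the concentration volume.

    ``mode="auto"`` ranks in-mask voxels by score = peak height / (TTP + tr)
    (tall, early peaks first), then averages the curves of the top
    ``n_candidates``.  Passing a list of voxel index triples instead averages
    exactly those voxels' curves.
    """
    c = conc.conc
    if not isinstance(mode, str):
        voxels = [tuple(int(i) for i in v) for v in mode]
        if not voxels:
            raise ValueError("manual AIF selection needs at least one voxel")
        curves = np.stack([c[v] for v in voxels])
        return AIFSelection(voxel_list=voxels, curve=curves.mean(axis=0), method="manual")

    if mode != "auto":
        raise ValueError(f"unknown AIF mode: {mode!r}")
    if brain_mask is None:
        raise ValueError("auto AIF selection requires a brain mask")
    mask = np.asarray(brain_mask, bool)
    flat = c[mask]
    if flat.size == 0:
        raise ValueError("no AIF candidate")
    post = flat[:, conc.bolus_frame :]
    peak = np.nanmax(post, axis=1)
    if not np.any(peak > 0):
        raise ValueError("no AIF candidate")
    ttp = conc.tr * np.nanargmax(_nan_to_neginf(post), axis=1)
    with np.errstate(invalid="ignore"):
        score = peak / (ttp + conc.tr)
    score[~np.isfinite(score)] = -np.inf
    order = np.argsort(score)[::-1][: min(n_candidates, score.size)]
    idx = np.argwhere(mask)[order]
    curve = flat[order].mean(axis=0)
    return AIFSelection(voxel_list=[tuple(v) for v in idx], curve=curve, method="auto")


def ssvd_deconvolve(
    conc: ConcentrationSeries, aif: AIFSelection, trunc_frac: float = 0.2
) -> PerfusionMapSet:
    """Truncated standard-SVD deconvolution of the residue function.

    Builds the lower-triangular Toeplitz convolution matrix
    ``A[i, j] = tr * AIF[i - j]`` (i >= j), zeroes every singular value below
    ``trunc_frac * sigma_max``, and solves ``r = V S+ U^T c`` voxelwise.
    CBF = max r, Tmax = tr * argmax r (earliest tie), CBV = integral C /
    integral AIF, MTT = CBV/CBF (NaN where CBF = 0).
    """
    if not (0 <= trunc_frac < 1):
        raise ValueError("trunc_frac must be in [0, 1)")
    a = np.asarray(aif.curve, float)
    if a.shape[0] != conc.n_frames:
        raise ValueError("AIF is not sampled on the series time grid")
    nz = np.flatnonzero(a)
    if len(nz) == 0 or (len(nz) == 1 and nz[0] != 0):
        # a single nonzero sample off the origin makes A nilpotent-singular;
        # a discrete impulse at t=0 (A = tr*a0*I) is perfectly invertible
        raise ValueError("degenerate AIF: need more than one nonzero sample")

    tr = conc.tr
    A = tr * toeplitz(a, np.zeros_like(a))
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    # numerical floor: a delayed AIF makes A strictly singular (zero diagonal),
    # so even trunc_frac=0 must drop the null-space directions
    keep = s >= max(trunc_frac, 1e-10) * s[0]
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    A_pinv = (Vt.T * s_inv) @ U.T

    shape = conc.conc.shape[:3]
    flat = conc.conc.reshape(-1, conc.n_frames)
    finite = np.isfinite(flat).all(axis=1)
    r = np.full_like(flat, np.nan)
    r[finite] = flat[finite] @ A_pinv.T

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cbf = np.nanmax(r, axis=1)
        cbf = np.where(np.isfinite(cbf), np.clip(cbf, 0.0, None), np.nan)
        tmax = tr * np.nanargmax(_nan_to_neginf(np.where(np.isfinite(r), r, np.nan)), axis=1)
        tmax = np.where(np.isfinite(cbf), tmax, np.nan)
        # zero-signal voxels: residue identically 0 -> flow 0 at time 0
        zero = finite & ~(flat > 0).any(axis=1)
        cbf[zero] = 0.0
        tmax[zero] = 0.0

        aif_area = np.trapezoid(a, dx=tr)
        cbv = np.trapezoid(flat, dx=tr, axis=1) / aif_area
        cbv = np.where(np.isfinite(cbv), np.clip(cbv, 0.0, None), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            mtt = np.where(cbf > 0, cbv / cbf, np.nan)

    return PerfusionMapSet(
        cbf_ssvd=cbf.reshape(shape),
        cbv_ssvd=cbv.reshape(shape),
        mtt_ssvd=mtt.reshape(shape),
        tmax_ssvd=tmax.reshape(shape),
    )


def median_filter_maps(maps: PerfusionMapSet, radius: int = 1) -> PerfusionMapSet:
    """NaN-ignoring median filter over a (2r+1)^3 neighborhood, per map.

    ``radius=0`` returns an identical copy.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return replace(maps)
    kwargs = {}
    for name, arr in maps.as_dict().items():
        kwargs[name] = nanmedian_filter(arr, radius)
    return PerfusionMapSet(**kwargs)


def mask_maps(maps: PerfusionMapSet, brain_mask: np.ndarray) -> PerfusionMapSet:
    """Crop every map to the brain: voxels outside the mask become NaN.

    Applied before median filtering so that out-of-brain zeros never leak
    into edge-voxel medians.
    """
    mask = np.asarray(brain_mask, bool)
    kwargs = {}
    for name, arr in maps.as_dict().items():
        out = arr.astype(np.float64).copy()
        out[~mask] = np.nan
        kwargs[name] = out
    return PerfusionMapSet(**kwargs)


def nanmedian_filter(volume: np.ndarray, radius: int) -> np.ndarray:
    """Vectorized NaN-ignoring 3D median filter (NaN-padded at the edges)."""
    if radius == 0:
        return volume.copy()
    w = 2 * radius + 1
    padded = np.pad(volume.astype(np.float64), radius, constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (w, w, w))
    win = win.reshape(volume.shape + (w**3,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmedian(win, axis=-1)


def compute_all_maps(
    series: DynamicSeries,
    aif: Optional[AIFSelection] = None,
    trunc_frac: float = 0.2,
    median_radius: int = 1,
) -> tuple[PerfusionMapSet, dict]:
    """Convenience driver: bolus detection -> concentration -> all 8 maps.

    Returns the (median-filtered) map set and a provenance dict recording the
    bolus frame, AIF voxels and truncation threshold.
    """
    bolus_frame, s0_map = detect_bolus_and_baseline(series)
    conc = signal_to_concentration(series, s0_map, bolus_frame)
    base = compute_basemaps(series, conc)
    if aif is None:
        aif = select_aif(conc, "auto", brain_mask=series.brain_mask)
    ssvd = ssvd_deconvolve(conc, aif, trunc_frac=trunc_frac)
    maps = base.merged_with(ssvd)
    if series.brain_mask is not None:
        maps = mask_maps(maps, series.brain_mask)
    maps = median_filter_maps(maps, radius=median_radius)
    meta = {
        "bolus_frame": bolus_frame,
        "aif_method": aif.method,
        "aif_voxels": [list(v) for v in aif.voxel_list],
        "trunc_frac": trunc_frac,
        "median_radius": median_radius,
    }
    return maps, meta
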