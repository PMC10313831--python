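"""Synthetic TIRFM kymographs and the DNA-end tracking algorithm.

A kymograph is a position-by-time intensity image of one tethered molecule:
pixel 0 is the barrier/tether (5' end) and the bright segment extends to the
free 3' end.  The renderer produces such images from a physical length series
and a bound-molecule count series, with Gaussian point-spread blur, optional
shot noise and additive Gaussian camera noise, and records the ground-truth
end position of every frame.

End tracking follows a per-column (per-frame) procedure: several independent
edge detectors each propose an end position -- a two-plateau step-function
fit, the maximal drop of a lightly smoothed profile, the last crossing of the
profile mean, and the last crossing of a two-class (between-class-variance
maximizing, i.e. Otsu) threshold.  The candidates are sorted by position, the
variance of every window of three contiguous candidates is computed, and the
mean position of the minimal-variance window is the frame's end.  This keeps
a single outlier detector from corrupting the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = [
    "OpticsModel",
    "SyntheticKymograph",
    "EndTrace",
    "NoEdgeError",
    "render_kymograph",
    "end_candidates",
    "pick_end",
    "track_ends",
]


@dataclass(frozen=True)
class OpticsModel:
    """Imaging parameters of the synthetic microscope.

    px_size         nm per pixel,
    frame_dt        seconds per frame,
    psf_sigma       Gaussian point-spread sigma in pixels,
    signal_per_rpa  intensity units contributed per bound molecule (spread
                    along the bright segment),
    background      constant background level,
    noise_sd        additive Gaussian read-noise SD,
    shot_noise      Poisson resampling of the noiseless image when true.
    """

    px_size: float = 100.0
    frame_dt: float = 5.0
    psf_sigma: float = 1.5
    signal_per_rpa: float = 50.0
    background: float = 10.0
    noise_sd: float = 2.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if min(self.px_size, self.frame_dt, self.psf_sigma, self.signal_per_rpa) <= 0:
            raise ValueError("px_size, frame_dt, psf_sigma, signal_per_rpa must be > 0")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be >= 0")


@dataclass
class SyntheticKymograph:
    """Rendered intensity image (position px x frame) with ground truth."""

    intensity: np.ndarray
    optics: OpticsModel
    truth_end: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.intensity)) or (self.intensity < 0).any():
            raise ValueError("intensity must be finite and >= 0")
        n_px = self.intensity.shape[0]
        if ((self.truth_end < 0) | (self.truth_end >= n_px)).any():
            raise ValueError("truth_end outside image")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


@dataclass
class EndTrace:
    """Tracked end position per frame and its normalized length series."""

    end_px: np.ndarray
    norm_length: np.ndarray
    reference_frame: int
    failed_frames: list[int] = field(default_factory=list)


class NoEdgeError(ValueError):
    """A column profile carries no usable step (constant / no contrast)."""


def render_kymograph(
    lengths_nm: Sequence[float],
    bound_counts: Sequence[float],
    optics: OpticsModel,
    seed: int = 0,
    n_px: int | None = None,
) -> SyntheticKymograph:
    """Render frames from aligned length (nm) and bound-count series.

    Each frame is a uniform bright line from the tether (pixel 0) to
    ``length/px_size`` with per-pixel intensity proportional to
    ``bound_count / length``, blurred with the PSF, plus background and
    noise.  ``truth_end`` is recorded before any noise is applied.
    """
    lengths = np.asarray(lengths_nm, dtype=float)
    counts = np.asarray(bound_counts, dtype=float)
    if lengths.shape != counts.shape:
        raise ValueError("length and count series must be aligned")
    if (lengths < 0).any():
        raise ValueError("lengths must be >= 0")
    rng = np.random.default_rng(seed)
    end_px = lengths / optics.px_size
    if n_px is None:
        n_px = int(np.ceil(end_px.max())) + max(16, int(8 * optics.psf_sigma))
    img = np.zeros((n_px, lengths.size))
    px_grid = np.arange(n_px + 1, dtype=float)
    for j, (e, c) in enumerate(zip(end_px, counts)):
        if e <= 0 or c <= 0:
            continue
        line = optics.signal_per_rpa * c / e  # intensity per px of bright segment
        # fractional coverage of each pixel by [0, e)
        cover = np.clip(e - px_grid[:-1], 0.0, 1.0)
        col = line * cover
        img[:, j] = gaussian_filter1d(col, optics.psf_sigma, mode="nearest")
    truth = np.clip(end_px, 0.0, n_px - 1e-9)
    img += optics.background
    if optics.shot_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if optics.noise_sd > 0:
        img = img + rng.normal(0.0, optics.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return SyntheticKymograph(intensity=img, optics=optics, truth_end=truth, seed=seed)


# ---------------------------------------------------------------------------
# per-frame edge detection


def _best_step_split(profile: np.ndarray) -> float:
    """Least-squares two-plateau step fit; returns the split position.

    Positions use the continuous pixel coordinate where pixel ``i`` spans
    ``[i, i+1)``, so a bright segment ``[0, e)`` has its edge at ``e``.
    """
    n = profile.size
    csum = np.cumsum(profile)
    csum2 = np.cumsum(profile**2)
    ks = np.arange(1, n)  # left segment = [0, k)
    left_sum = csum[ks - 1]
    left_sq = csum2[ks - 1]
    right_sum = csum[-1] - left_sum
    right_sq = csum2[-1] - left_sq
    sse = (left_sq - left_sum**2 / ks) + (right_sq - right_sum**2 / (n - ks))
    return float(ks[np.argmin(sse)])


def _last_down_crossing(profile: np.ndarray, threshold: float, min_run: int = 5) -> float:
    """Downward crossing at the end of the last sustained bright run.

    Requiring ``min_run`` consecutive above-threshold pixels before the
    crossing keeps isolated noise excursions in the dark tail from hijacking
    the edge; the returned position interpolates between pixel centers.
    """
    above = profile >= threshold
    run = 0
    last_end = -1
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            last_end = i
    if last_end < 0:
        raise NoEdgeError("no sustained bright run above the threshold")
    if last_end + 1 >= profile.size:
        return float(last_end) + 1.0
    p0, p1 = profile[last_end], profile[last_end + 1]
    frac = (p0 - threshold) / (p0 - p1) if p0 > p1 else 0.5
    return last_end + 0.5 + float(min(max(frac, 0.0), 1.0))


def _otsu_threshold(profile: np.ndarray) -> float:
    """Two-class threshold maximizing between-class variance.

    Computed over splits of the sorted intensity values; among tied splits the
    middle one is taken and the returned threshold is the midpoint between the
    two class means, so an ideal two-level column yields the halfway level.
    """
    v = np.sort(np.asarray(profile, dtype=float))
    n = v.size
    ks = np.arange(1, n)  # low class = v[:k]
    csum = np.cumsum(v)
    mu_lo = csum[:-1] / ks
    mu_hi = (csum[-1] - csum[:-1]) / (n - ks)
    sigma_b = ks * (n - ks) * (mu_lo - mu_hi) ** 2
    best = sigma_b.max()
    tied = np.nonzero(sigma_b >= best * (1 - 1e-12))[0]
    k = int(ks[tied[len(tied) // 2]])
    return 0.5 * (csum[k - 1] / k + (csum[-1] - csum[k - 1]) / (n - k))


def end_candidates(profile: np.ndarray, smooth_width: int = 3) -> list[float]:
    """Candidate end positions from four independent detectors, sorted.

    Raises :class:`NoEdgeError` on a constant (contrast-free) profile.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 8:
        raise ValueError("profile too short (need >= 8 pixels)")
    if np.ptp(profile) == 0:
        raise NoEdgeError("constant profile")
    split = _best_step_split(profile)
    # contrast gate: the fitted step must rise clearly above the residual
    # noise around its two plateaus, and the tether (left) side must be bright
    k = int(round(split))
    mu_l, mu_r = profile[:k].mean(), profile[k:].mean()
    resid = np.concatenate([profile[:k] - mu_l, profile[k:] - mu_r])
    noise_sd = float(resid.std())
    if mu_l - mu_r <= 3.0 * noise_sd:
        raise NoEdgeError("no contrast: step depth within noise")
    candidates = [split]
    smoothed = uniform_filter1d(profile, smooth_width, mode="nearest")
    drops = smoothed[:-1] - smoothed[1:]
    # middle of the maximal-drop plateau (a blurred step spreads the drop
    # symmetrically over neighbouring pixel pairs)
    tied = np.nonzero(drops >= drops.max() * (1 - 1e-12))[0]
    candidates.append(float(tied[len(tied) // 2]) + 1.0)
    for threshold in (float(profile.mean()), _otsu_threshold(profile)):
        try:
            candidates.append(_last_down_crossing(smoothed, threshold))
        except NoEdgeError:
            pass  # a threshold can sit outside the smoothed range on pathological columns
    if len(candidates) < 3:
        raise NoEdgeError("fewer than 3 detectors produced a candidate")
    return sorted(candidates)


def pick_end(candidates: Sequence[float]) -> float:
    """Mean of the minimal-variance window of three position-sorted contiguous
    candidates; ties break toward the window nearer the tether."""
    cand = sorted(float(c) for c in candidates)
    if len(cand) < 3:
        raise ValueError("need at least 3 candidates")
    windows = [cand[i : i + 3] for i in range(len(cand) - 2)]
    variances = [float(np.var(w)) for w in windows]
    vmin = min(variances)
    # variances equal up to rounding count as ties; ties resolve toward the
    # window nearer the tether (smaller mean position)
    tol = vmin * 1e-9
    tied_means = [float(np.mean(w)) for w, v in zip(windows, variances)
                  if v <= vmin + tol]
    return min(tied_means)


def track_ends(kymo: SyntheticKymograph, reference_frame: int = 0) -> EndTrace:
    """Track the DNA end in every frame and normalize to a reference frame.

    Frames where no edge is detectable are reported as NaN and listed in
    ``failed_frames`` -- never interpolated or fabricated.
    """
    n_frames = kymo.n_frames
    ends = np.full(n_frames, np.nan)
    failed: list[int] = []
    for j in range(n_frames):
        try:
            ends[j] = pick_end(end_candidates(kymo.intensity[:, j]))
        except (NoEdgeError, ValueError):
            failed.append(j)
    ref = ends[reference_frame]
    if np.isnan(ref) or ref <= 0:
        norm = np.full(n_frames, np.nan)
    else:
        norm = (ends - ref) / ref
    return EndTrace(end_px=ends, norm_length=norm,
                    reference_frame=reference_frame, failed_frames=failed)


def write_tiff(path, kymo: SyntheticKymograph) -> None:
    """Write the kymograph as a single-channel 32-bit TIFF (position x time)."""
    import tifffile

    tifffile.imwrite(path, kymo.intensity.astype(np.float32))


def read_tiff(path, optics: OpticsModel | None = None) -> SyntheticKymograph:
    import tifffile

    img = np.asarray(tifffile.imread(path), dtype=float)
    return SyntheticKymograph(
        intensity=np.clip(img, 0.0, None),
        optics=optics or OpticsModel(),
        truth_end=np.zeros(img.shape[1]),
        seed=-1,
    )
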