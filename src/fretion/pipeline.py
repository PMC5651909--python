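"""Ratiometric sensitized-emission FRET quantification.

The chain mirrors a standard confocal three-channel workflow: per-channel
median blur, saturated-pixel removal, rolling-ball background subtraction
and maximum z-projection; an Otsu mask built from the CFP and YFP channels;
bleed-through (alpha) and cross-excitation (beta) correction factors
measured on donor-only / acceptor-only calibration samples; the sensitized
emission

    SE = I_FRET - alpha * I_CFP - beta * I_YFP

and the pixel-wise FRET index

    index = SE / (I_CFP + SE)

with negative-SE pixels deleted (excluded, not zeroed).  The index is a
semi-quantitative measure: intensity-independent in the ideal case, which
is exactly what the intensity-correlation diagnostic checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, restoration, transform

from .stack import ChannelStack

__all__ = [
    "CorrectionFactors",
    "FretMap",
    "PreprocessConfig",
    "preprocess",
    "subtract_background",
    "build_mask",
    "estimate_correction_factors",
    "sensitized_emission",
    "fret_index_map",
    "mean_fret_index",
    "intermolecular_fret_check",
    "intensity_fret_correlation",
    "analyze_stack",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """Spectral correction factors measured from calibration genotypes."""

    alpha: float
    beta: float
    n_pixels_used: int = 0
    method: str = "median_ratio"

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1 and 0 <= self.beta < 1):
            raise ValueError("alpha and beta must be in [0, 1)")


@dataclass
class FretMap:
    """Pixel-wise FRET index; undefined ("deleted") pixels are NaN."""

    index: np.ndarray
    mask: np.ndarray
    n_valid: int
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.index)

    def values(self) -> np.ndarray:
        return self.index[self.defined]


@dataclass(frozen=True)
class PreprocessConfig:
    median_radius: int = 1
    rolling_ball_radius: float | None = 50.0
    flag_saturation: bool = True


def subtract_background(img: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction.

    For large radii the background is estimated on a shrunken copy and
    rescaled back (the classic ImageJ speedup); the estimate is clipped so
    subtraction never produces negative counts.
    """
    img = np.asarray(img, dtype=float)
    if radius <= 16:
        bg = restoration.rolling_ball(img, radius=radius)
    else:
        shrink = int(np.ceil(radius / 16.0))
        small = transform.rescale(
            img, 1.0 / shrink, order=1, anti_aliasing=True, preserve_range=True
        )
        bg_small = restoration.rolling_ball(small, radius=radius / shrink)
        bg = transform.resize(
            bg_small, img.shape, order=1, preserve_range=True, anti_aliasing=False
        )
    bg = np.minimum(bg, img)
    return img - bg


def preprocess(
    stack: ChannelStack, config: PreprocessConfig | None = None
) -> ChannelStack:
    """Median blur, saturation flagging, background subtraction, max-projection.

    Saturation is detected on the raw counts (an isolated saturated pixel
    would otherwise be erased by the median) and the flags are propagated
    through the projection as an ``invalid`` mask on the result.
    """
    config = config or PreprocessConfig()
    if stack.cfp.size == 0:
        raise ValueError("empty stack")
    arrs = stack.channels()
    sat = stack.saturation_level
    out: dict[str, np.ndarray] = {}
    invalid = None
    size = 2 * config.median_radius + 1
    for name, arr in arrs.items():
        a = np.asarray(arr, dtype=float)
        if a.ndim == 2:
            a = a[None]
        flagged = np.any(a >= sat, axis=0) if config.flag_saturation else None
        slices = []
        for z in range(a.shape[0]):
            s = ndimage.median_filter(a[z], size=size, mode="nearest")
            if config.rolling_ball_radius is not None:
                s = subtract_background(s, config.rolling_ball_radius)
            slices.append(s)
        proj = np.max(np.stack(slices), axis=0)
        out[name] = proj
        if flagged is not None:
            invalid = flagged if invalid is None else (invalid | flagged)
    return ChannelStack(
        cfp=out["cfp"],
        yfp=out["yfp"],
        fret=out["fret"],
        bit_depth=stack.bit_depth,
        pixel_size=stack.pixel_size,
        invalid=invalid,
        meta={**stack.meta, "preprocess": config},
    )


def build_mask(
    cfp: np.ndarray, yfp: np.ndarray, combine: str = "and"
) -> np.ndarray:
    """Membrane mask from per-channel Otsu thresholds.

    The default combination requires both fluorophores to be present
    (logical AND); ``combine='or'`` is available for sparse samples.
    """
    masks = []
    for name, img in (("cfp", cfp), ("yfp", yfp)):
        img = np.asarray(img, dtype=float)
        if np.ptp(img) == 0:
            raise ValueError(f"Otsu threshold undefined: {name} channel is constant")
        masks.append(img >= filters.threshold_otsu(img))
    if combine == "and":
        return masks[0] & masks[1]
    if combine == "or":
        return masks[0] | masks[1]
    raise ValueError(f"unknown mask combination {combine!r}")


def _robust_ratio(num: np.ndarray, den: np.ndarray, method: str) -> tuple[float, int]:
    ok = den > 0
    if method == "median_ratio":
        val = float(np.median(num[ok] / den[ok]))
    elif method == "regression":
        val = float(np.sum(num[ok] * den[ok]) / np.sum(den[ok] ** 2))
    else:
        raise ValueError(f"unknown estimator {method!r}")
    return val, int(ok.sum())


def estimate_correction_factors(
    donor_only: ChannelStack,
    acceptor_only: ChannelStack,
    method: str = "median_ratio",
    min_pixels: int = 100,
) -> CorrectionFactors:
    """Measure alpha = I_FRET/I_CFP (donor-only) and beta = I_FRET/I_YFP
    (acceptor-only) over the expressing channel's Otsu mask.

    Both stacks must already be preprocessed (2-D).  The default estimator
    is the median of pixel-wise ratios, robust to residual background and
    Poisson outliers; a least-squares slope through the origin is available
    as ``method='regression'``.
    """
    for s, name in ((donor_only, "donor_only"), (acceptor_only, "acceptor_only")):
        if not s.is_projected:
            raise ValueError(f"{name} stack must be preprocessed (2-D) first")

    d_img = donor_only.cfp
    d_mask = d_img >= filters.threshold_otsu(d_img)
    if donor_only.invalid is not None:
        d_mask &= ~donor_only.invalid
    if d_mask.sum() < min_pixels:
        raise ValueError(
            f"donor-only calibration has only {int(d_mask.sum())} mask pixels"
        )
    alpha, n_d = _robust_ratio(donor_only.fret[d_mask], d_img[d_mask], method)

    a_img = acceptor_only.yfp
    a_mask = a_img >= filters.threshold_otsu(a_img)
    if acceptor_only.invalid is not None:
        a_mask &= ~acceptor_only.invalid
    if a_mask.sum() < min_pixels:
        raise ValueError(
            f"acceptor-only calibration has only {int(a_mask.sum())} mask pixels"
        )
    beta, n_a = _robust_ratio(acceptor_only.fret[a_mask], a_img[a_mask], method)

    return CorrectionFactors(
        alpha=max(alpha, 0.0),
        beta=max(beta, 0.0),
        n_pixels_used=min(n_d, n_a),
        method=method,
    )


def sensitized_emission(
    channels: ChannelStack, factors: CorrectionFactors
) -> np.ndarray:
    """SE = I_FRET - alpha * I_CFP - beta * I_YFP (may be negative here)."""
    if not channels.is_projected:
        raise ValueError("sensitized emission needs projected 2-D channels")
    return channels.fret - factors.alpha * channels.cfp - factors.beta * channels.yfp


def fret_index_map(
    se: np.ndarray, cfp: np.ndarray, mask: np.ndarray
) -> FretMap:
    """index = SE / (I_CFP + SE) inside the mask.

    Pixels with negative SE, or a non-positive denominator, are deleted:
    marked undefined and excluded from every downstream statistic (zeroing
    them would bias means downward).
    """
    if mask.sum() == 0:
        raise ValueError("empty mask: no pixels to quantify")
    se = np.asarray(se, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    denom = cfp + se
    index = np.full(se.shape, np.nan)
    valid = mask & (se >= 0) & (denom > 0)
    index[valid] = se[valid] / denom[valid]
    return FretMap(
        index=index,
        mask=np.asarray(mask, bool),
        n_valid=int(valid.sum()),
        meta={"n_deleted_negative": int((mask & ~valid).sum())},
    )


def mean_fret_index(fmap: FretMap) -> float:
    """Arithmetic mean index over defined pixels (the per-image summary)."""
    if fmap.n_valid < 1:
        raise ValueError("no defined pixels in FRET map")
    return float(np.nanmean(fmap.index))


def intermolecular_fret_check(
    coexpressed: ChannelStack,
    factors: CorrectionFactors,
    noise_floor: float = 0.01,
    config: PreprocessConfig | None = None,
) -> tuple[str, float]:
    """Test a donor+acceptor co-expression control for intermolecular FRET.

    Returns ``('not_detected', mean_index)`` when the mean corrected index
    stays below ``noise_floor``; anything above is reported as detected.
    """
    pre = preprocess(coexpressed, config) if not coexpressed.is_projected else coexpressed
    mask = build_mask(pre.cfp, pre.yfp)
    if pre.invalid is not None:
        mask &= ~pre.invalid
    se = sensitized_emission(pre, factors)
    fmap = fret_index_map(se, pre.cfp, mask)
    # deleting negative-SE pixels biases a zero-signal mean upward, so the
    # detection statistic keeps them at 0 instead
    idx = np.where(np.isfinite(fmap.index), fmap.index, 0.0)
    mean_idx = float(idx[mask].mean())
    call = "not_detected" if mean_idx < noise_floor else "detected"
    return call, mean_idx


def intensity_fret_correlation(fmap: FretMap, yfp: np.ndarray) -> float:
    """Pearson r between pixel index and acceptor intensity (artifact check).

    A clean ratiometric index is intensity-independent; a positive r flags
    unsubtracted background or other intensity coupling.  NaN when either
    variable has zero variance.
    """
    ok = fmap.defined
    if ok.sum() < 3:
        raise ValueError("need >= 3 defined pixels")
    x = fmap.index[ok]
    y = np.asarray(yfp, dtype=float)[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def analyze_stack(
    stack: ChannelStack,
    factors: CorrectionFactors,
    config: PreprocessConfig | None = None,
    mask_combine: str = "and",
) -> tuple[FretMap, dict]:
    """Full chain: preprocess -> mask -> SE -> index map, with diagnostics."""
    pre = preprocess(stack, config) if not stack.is_projected else stack
    mask = build_mask(pre.cfp, pre.yfp, combine=mask_combine)
    if pre.invalid is not None:
        mask &= ~pre.invalid
    se = sensitized_emission(pre, factors)
    fmap = fret_index_map(se, pre.cfp, mask)
    summary = {
        "mean_index": mean_fret_index(fmap),
        "n_valid": fmap.n_valid,
        "n_mask": int(mask.sum()),
        "excluded_fraction": 1.0 - fmap.n_valid / max(int(mask.sum()), 1),
        "saturated_fraction": float(pre.invalid.mean()) if pre.invalid is not None else 0.0,
        "alpha": factors.alpha,
        "beta": factors.beta,
        "r_intensity": intensity_fret_correlation(fmap, pre.yfp),
    }
    return fmap, summary
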