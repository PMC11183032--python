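"""Sliding-kernel radiomic feature maps (RFMs).

A k x k kernel (default 7) slides across a patch; the feature value of each
window is written to the window's centre pixel, producing one map per feature
with the same dimensions as the patch.  Maps are computed on the
native-resolution patch and resized afterwards, so interpolation never feeds
the texture statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize

from .texture_bank import (
    FEATURE_NAMES,
    MatrixConfig,
    QuantizedWindow,
    compute_features,
    quantize,
)

__all__ = ["KernelConfig", "RFMStack", "compute_rfms", "resize_map"]


@dataclass(frozen=True)
class KernelConfig:
    """Sliding-window configuration for RFM extraction."""

    kernel_size: int = 7
    padding: str = "reflect"  # reflect | edge | none
    n_bins: int = 16
    range_policy: str = "global"
    matrix: MatrixConfig = field(default_factory=MatrixConfig)

    def __post_init__(self) -> None:
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.padding not in ("reflect", "edge", "none"):
            raise ValueError(f"unknown padding {self.padding!r}")


@dataclass
class RFMStack:
    """Named per-feature maps congruent with the source patch."""

    maps: dict[str, np.ndarray]
    shape: tuple[int, int]
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, m in self.maps.items():
            if m.shape != self.shape:
                raise ValueError(f"map {name!r} shape {m.shape} != {self.shape}")
            if not np.isfinite(m).all():
                raise ValueError(f"map {name!r} contains non-finite values")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def stack(self) -> np.ndarray:
        return np.stack([self.maps[n] for n in self.maps])


def compute_rfms(
    patch: np.ndarray,
    cfg: KernelConfig | None = None,
    features: Sequence[str] | str = "all",
) -> RFMStack:
    """Evaluate texture features on every kernel-centred window of ``patch``.

    With the default global range policy the whole patch is quantized once, so
    window levels are comparable across positions.  ``features`` may be "all"
    (the canonical 75) or an explicit name subset.
    """
    a = np.asarray(patch, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("patch must be a nonempty 2D grid")
    cfg = cfg or KernelConfig()
    k = cfg.kernel_size
    half = k // 2
    names = tuple(FEATURE_NAMES) if features == "all" else tuple(features)

    if cfg.padding == "none":
        if a.shape[0] < k or a.shape[1] < k:
            raise ValueError("patch smaller than kernel with padding='none'")
        padded_vals = a
        out_off = half
    else:
        padded_vals = np.pad(a, half, mode=cfg.padding)
        out_off = 0

    if cfg.range_policy == "global":
        q = quantize(a, cfg.n_bins, "global")
        # re-quantize the padded grid with the patch's global endpoints
        qp = quantize(padded_vals, cfg.n_bins, "global",
                      intensity_range=(float(a.min()), float(a.max())))
        levels = qp.levels
        n_levels = q.n_levels
    else:
        levels = None
        n_levels = cfg.n_bins

    out = {n: np.zeros(a.shape) for n in names}
    valid = np.zeros(a.shape, dtype=bool) if cfg.padding == "none" else None

    if levels is not None:
        windows = sliding_window_view(levels, (k, k))
    else:
        windows = sliding_window_view(padded_vals, (k, k))
    n_rows, n_cols = windows.shape[:2]
    for wr in range(n_rows):
        for wc in range(n_cols):
            if levels is not None:
                w = QuantizedWindow(windows[wr, wc], n_levels, (wr, wc))
            else:
                w = quantize(windows[wr, wc], cfg.n_bins, "window")
            vals = compute_features(w, cfg.matrix, names)
            r, c = wr + out_off, wc + out_off
            for n in names:
                out[n][r, c] = vals[n]
            if valid is not None:
                valid[r, c] = True
    return RFMStack(out, a.shape, valid)


def resize_map(map_: np.ndarray, target: tuple[int, int], method: str = "bilinear") -> np.ndarray:
    """Resize a 2D map; bilinear by default, nearest available for masks."""
    a = np.asarray(map_, dtype=float)
    if target[0] <= 0 or target[1] <= 0:
        raise ValueError("target dimensions must be positive")
    if a.shape == tuple(target):
        return a.copy()
    order = {"bilinear": 1, "nearest": 0}[method]
    return _sk_resize(a, target, order=order, mode="edge",
                      anti_aliasing=False, preserve_range=True)
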