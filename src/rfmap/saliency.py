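"""Saliency maps and saliency-guided RFM selection.

The pilot classifier's input gradient marks which pixels drive the class
score.  Retained feature maps are then ranked by their average Pearson
correlation with the per-subject saliency maps across the training cohort,
and the top two become the extra channels of the boosted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patches import CompositeInput
from .rfm_engine import RFMStack, resize_map

__all__ = ["SaliencyMap", "saliency", "rank_rfms"]


@dataclass
class SaliencyMap:
    """Nonnegative per-pixel importance, max-normalized unless all-zero."""

    pixels: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or not np.isfinite(p).all() or (p < 0).any():
            raise ValueError("saliency map must be a finite nonnegative 2D grid")
        self.pixels = p


def saliency(model, input_: CompositeInput | np.ndarray, class_index: int = 1) -> SaliencyMap:
    """Gradient-magnitude saliency of ``model``'s class score w.r.t. the input.

    The channel dimension is reduced by taking the maximum absolute gradient
    per pixel, then the map is normalized to max 1 (skipped, and flagged
    ``normalized=False``, when the gradient is identically zero).
    """
    x = input_.channels if isinstance(input_, CompositeInput) else np.asarray(input_, float)
    grad_fn = getattr(model, "input_gradient", None)
    if grad_fn is None:
        raise TypeError("model does not expose input gradients "
                        "(needs an input_gradient(x, class_index) method)")
    g = np.abs(np.asarray(grad_fn(x, class_index), dtype=float))
    if g.ndim == 3:
        g = g.max(axis=0)
    peak = g.max()
    if peak > 0:
        return SaliencyMap(g / peak, True)
    return SaliencyMap(g, False)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0  # degenerate convention
    return float(np.corrcoef(a, b)[0, 1])


def rank_rfms(
    stacks: list[RFMStack],
    sms: list[SaliencyMap],
    retained: list[str],
    top: int = 2,
    absolute: bool = False,
) -> list[tuple[str, float]]:
    """Rank retained feature maps by mean per-subject correlation with the SM.

    ``stacks`` and ``sms`` are aligned by subject; maps are resized to each
    subject's SM dimensions before correlating.  Returns all ``(name, mean r)``
    pairs sorted descending; the first ``top`` entries are the selection.
    Set ``absolute`` to rank on |r| instead of signed r.
    """
    if len(stacks) != len(sms):
        raise ValueError("stacks and saliency maps must align by subject")
    if not stacks:
        raise ValueError("empty cohort")
    for st in stacks:
        missing = set(retained) - set(st.names)
        if missing:
            raise ValueError(f"stack missing retained maps: {sorted(missing)}")
    means = []
    for name in retained:
        rs = []
        for st, sm in zip(stacks, sms):
            m = resize_map(st.maps[name], sm.pixels.shape)
            rs.append(_pearson(m, sm.pixels))
        means.append((name, float(np.mean(rs))))
    key = (lambda t: abs(t[1])) if absolute else (lambda t: t[1])
    ranked = sorted(means, key=key, reverse=True)
    return ranked
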