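"""Render emitter trajectories to noisy fluorescence image stacks.

Each emitter becomes an isotropic 2D Gaussian of width ``psf_sigma`` (px)
evaluated at pixel centers, on a uniform background.  Shot noise is Poisson:
the ideal image is scaled by ``photon_scale`` (photons per count), Poisson
sampled, and scaled back; ``photon_scale = 0`` renders noise-free images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["render_frames", "add_gaussian_spot"]


def add_gaussian_spot(image: np.ndarray, x: float, y: float, amplitude: float,
                      sigma: float, truncate: float = 6.0) -> None:
    """Add one Gaussian spot to ``image`` in place (evaluated within
    ``truncate`` sigmas of the center; the truncated mass is < 1e-7)."""
    H, W = image.shape
    r = truncate * sigma
    x0, x1 = max(0, int(np.floor(x - r))), min(W, int(np.ceil(x + r)) + 1)
    y0, y1 = max(0, int(np.floor(y - r))), min(H, int(np.ceil(y + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    image[y0:y1, x0:x1] += amplitude * g


def render_frames(emitters: pd.DataFrame, cell, params,
                  rng: np.random.Generator | None = None) -> dict:
    """Render one cell's emitter table to per-channel image stacks.

    Parameters
    ----------
    emitters
        Columns ``frame, channel, axial_um, trans_um, amplitude``.
    cell
        A ``CellSeries`` providing geometry (``axial_to_px``; image size is
        taken from the boundary canvas).
    params
        ``ScenarioParams`` supplying ``psf_sigma``, ``background_level`` and
        ``photon_scale``.
    rng
        Source for shot noise; required when ``photon_scale > 0``.

    Returns
    -------
    dict
        ``channel -> (T, H, W) float32`` stack.

    Raises
    ------
    ValueError
        If an emitter falls outside the image bounds (the frame is named).
    """
    T = cell.n_frames
    H, W = cell.img_shape
    channels = sorted(set(emitters["channel"])) if len(emitters) else list(params.channels)

    if params.photon_scale > 0 and rng is None:
        raise ValueError("rng is required when photon_scale > 0")

    # pre-group emitters into plain tuples for speed
    grouped: dict = {}
    for e in emitters.itertuples(index=False):
        grouped.setdefault((e.channel, e.frame), []).append(
            (float(e.axial_um), float(e.trans_um), float(e.amplitude))
        )

    stacks = {}
    for channel in channels:
        stack = np.empty((T, H, W), dtype=np.float32)
        for f in range(T):
            img = np.full((H, W), params.background_level, dtype=np.float64)
            for axial, trans, amp in grouped.get((channel, f), ()):
                x, y = cell.axial_to_px(f, axial, trans)
                if not (0 <= x < W and 0 <= y < H):
                    raise ValueError(
                        f"emitter outside image bounds at frame {f} "
                        f"(channel {channel}): x={x:.1f}, y={y:.1f}"
                    )
                add_gaussian_spot(img, x, y, amp, params.psf_sigma)
            if params.photon_scale > 0:
                img = rng.poisson(img * params.photon_scale) / params.photon_scale
            stack[f] = img
        stacks[channel] = stack
    return stacks
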