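"""Pseudocolor rendering of saturation maps.

Saturation is displayed on a linear blue-to-red colormap: pure blue at 0%
oxygen saturation, pure red at 100%. Pixels without a saturation value
(sentinel NaN) show the underlying grayscale fundus band so the vessel
overlay stays anatomically readable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["saturation_to_rgb", "pseudocolor_image", "render_pseudocolor"]


def saturation_to_rgb(values) -> np.ndarray:
    """Map saturation fractions in [0, 1] to RGB on the linear blue-red ramp.

    0 -> (0, 0, 1), 1 -> (1, 0, 0), 0.5 -> (0.5, 0, 0.5). Values are clipped
    to [0, 1] first. Returns an array with a trailing RGB axis.
    """
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    return np.stack([v, np.zeros_like(v), 1.0 - v], axis=-1)


def pseudocolor_image(so2_map: np.ndarray, background: np.ndarray | None = None) -> np.ndarray:
    """Compose the RGB overlay: colormap where the map has data, gray elsewhere.

    ``background`` is a single-band grayscale image (normalized to its own
    max); without one, sentinel pixels render mid-gray.
    """
    so2_map = np.asarray(so2_map, dtype=float)
    valid = np.isfinite(so2_map)
    if background is not None:
        bg = np.asarray(background, dtype=float)
        if bg.shape != so2_map.shape:
            raise ValueError("background shape must match the saturation map")
        top = bg.max()
        gray = bg / top if top > 0 else np.zeros_like(bg)
    else:
        gray = np.full(so2_map.shape, 0.5)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    rgb[valid] = saturation_to_rgb(so2_map[valid])
    return rgb


def render_pseudocolor(
    so2_map: np.ndarray,
    path: str,
    background: np.ndarray | None = None,
    title: str = "Oxygen saturation",
) -> str:
    """Write a PNG of the pseudocolor map with a 0-100% color bar legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("oximetry", [(0, 0, 1), (1, 0, 0)])
    rgb = pseudocolor_image(so2_map, background)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_title(title)
    ax.set_axis_off()
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 100))
    fig.colorbar(sm, ax=ax, label="SO$_2$ (%)", shrink=0.85)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
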