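"""Optional plotting helpers: texture-map overlays and KM curves.

Texture maps are rendered with the conventional diverging palette — pink for
positive filtered responses (bright objects), blue for negative (dark
objects) — so fine/medium/coarse maps can be compared visually.
"""

from __future__ import annotations

import numpy as np

from .filtration import TextureMap
from .survival import KmCurve


def plot_texture_map(tmap: TextureMap, ax=None, mask=None):
    """Render a filtered map with pink = positive, blue = negative."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    if ax is None:
        _, ax = plt.subplots()
    cmap = LinearSegmentedColormap.from_list(
        "pinkblue", ["#2166ac", "#f7f7f7", "#e7298a"]
    )
    data = np.where(mask, tmap.pixels, np.nan) if mask is not None else tmap.pixels
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap=cmap, norm=TwoSlopeNorm(0.0, -vmax, vmax))
    ax.set_title(f"SSF {tmap.ssf_mm:g} mm" if tmap.ssf_mm else "unfiltered")
    ax.axis("off")
    return im


def plot_km(curves: dict[str, KmCurve], ax=None, title: str = ""):
    """Step-plot KM curves keyed by group label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, km in curves.items():
        t = np.concatenate([[0.0], km.timeline])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=f"{label} (median {km.median_label})")
    ax.set_xlabel("months")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
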