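"""AHA-17 bull's-eye display of segment-wise wall thickness."""

from __future__ import annotations

import numpy as np

# (inner radius, outer radius, start angle deg, sweep deg) per segment, apex
# innermost; theta=0 (anteroseptal centre) at the top, CCW viewed from apex.
_RING_RADII = {"basal": (2.0, 3.0), "mid": (1.0, 2.0), "apical": (0.5, 1.0)}


def bullseye(seg_thickness_mm, ax=None, cmap="viridis", vmin=None, vmax=None):
    """Draw the standard 17-segment bull's-eye for one thickness map.

    ``seg_thickness_mm`` is indexable by segment id offset (17 values,
    AHA order).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    values = np.asarray(seg_thickness_mm, dtype=float)
    if values.shape != (17,):
        raise ValueError("expected 17 segment values")
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vmin = values.min() if vmin is None else vmin
    vmax = values.max() if vmax is None else vmax
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)

    theta_fine = np.linspace(0, 2 * np.pi, 181)

    def _wedge(r0, r1, a0, sweep, value):
        angles = np.linspace(np.deg2rad(a0), np.deg2rad(a0 + sweep), 31)
        ax.fill_between(
            angles, r0, r1, color=mapper.to_rgba(value), edgecolor="k", linewidth=0.5
        )

    # basal 1-6 and mid 7-12: 60-degree sectors starting at the anteroseptal
    # centre minus 30 degrees, order 2,3,4,5,6,1 going CCW
    order6 = (2, 3, 4, 5, 6, 1)
    for ring, base in (("basal", 0), ("mid", 6)):
        r0, r1 = _RING_RADII[ring]
        for k, seg in enumerate(order6):
            _wedge(r0, r1, -30 + 60 * k, 60, values[seg + base - 1])
    order4 = (14, 15, 16, 13)
    r0, r1 = _RING_RADII["apical"]
    for k, seg in enumerate(order4):
        _wedge(r0, r1, -45 + 90 * k, 90, values[seg - 1])
    ax.fill_between(theta_fine, 0.0, 0.5, color=mapper.to_rgba(values[16]))

    ax.set_yticklabels([])
    ax.set_xticklabels([])
    ax.set_ylim(0, 3.0)
    ax.figure.colorbar(mapper, ax=ax, shrink=0.8, label="wall thickness (mm)")
    return ax
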