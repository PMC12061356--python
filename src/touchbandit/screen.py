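"""Touchscreen geometry constants.

The operant touchscreen reports touches on an 800 x 600 pixel grid (IR-beam
resolution matches the monitor). One pixel corresponds to 0.29 mm. Two
square response apertures of 240 x 240 px sit left and right of the screen
midline; the mask between them is dead space. Coordinates are screen-global
with the origin at the top-left (display convention), half-open ranges
[0, 800) x [0, 600).

The horizontal placement of the aperture windows is not part of the logged
data (global touch coordinates are); the offsets below define this
package's convention for converting aperture-local exports to global
coordinates and for the synthetic generator, chosen symmetric about the
midline with a 240 px centre gap.
"""

SCREEN_W_PX = 800
SCREEN_H_PX = 600
CENTER_X_PX = SCREEN_W_PX // 2  # 400

MM_PER_PX = 0.29

APERTURE_SIZE_PX = 240
# top-left corner of each aperture window, (x0, y0)
APERTURE_ORIGIN = {
    "left": (40, 180),
    "right": (520, 180),
}
# aperture centres, used as touch-distribution means by the generator
APERTURE_CENTER = {
    side: (x0 + APERTURE_SIZE_PX / 2, y0 + APERTURE_SIZE_PX / 2)
    for side, (x0, y0) in APERTURE_ORIGIN.items()
}


def px_to_mm(d):
    """Convert a nonnegative pixel distance to millimetres (1 px = 0.29 mm)."""
    import numpy as np

    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("pixel distances must be nonnegative")
    out = d * MM_PER_PX
    return float(out) if out.ndim == 0 else out
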