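"""Canonical developmental expression archetypes.

Five shape templates describe how cell-wall gene expression evolves along a
maize stem internode series, ordered youngest (highest internode number,
nearest the apex) to oldest (lowest number, at the base):

* ``Elongation``   — highest in young, elongating internodes; falls steeply as
  internodes mature and switch to secondary wall deposition.
* ``TransitionI``  — low during elongation, a mid-course rise as elongation
  ceases, then back to a low plateau in the oldest internodes.
* ``TransitionII`` — low during elongation, a shallow monotone rise that stays
  moderate in the oldest internodes.
* ``Secondary``    — mirror image of Elongation: near-silent in young
  internodes, strong induction during secondary wall formation.
* ``EarlyLate``    — high at both ends of the series with an interior minimum
  during peak secondary wall deposition.
* ``Flat``         — constant; background genes without a developmental trend.

The numeric anchors below are unit-scale (peak 1.0) vectors over eight
internodes; other series lengths are obtained by linear interpolation along a
normalized developmental axis.  The Transition anchors were placed so that
their secondary:elongation expression ratio falls in the middle of the
transitional band (~1.4) rather than near a class boundary; Elongation,
Secondary and EarlyLate sit far to one side of the bands.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

PATTERN_NAMES = ("Elongation", "TransitionI", "TransitionII", "Secondary", "EarlyLate")

# Anchor values over 8 internodes, youngest -> oldest.
_ANCHORS: dict[str, tuple[float, ...]] = {
    "Elongation":   (1.00, 0.95, 0.70, 0.45, 0.12, 0.08, 0.06, 0.05),
    "TransitionI":  (0.30, 0.30, 0.60, 0.85, 0.50, 0.42, 0.36, 0.30),
    "TransitionII": (0.30, 0.30, 0.33, 0.36, 0.40, 0.42, 0.46, 0.50),
    "Secondary":    (0.05, 0.06, 0.08, 0.12, 0.45, 0.70, 0.95, 1.00),
    "EarlyLate":    (0.95, 1.00, 0.55, 0.25, 0.20, 0.25, 0.60, 0.95),
    "Flat":         (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
}


def archetype(name: str, internodes: Sequence[int] | int) -> np.ndarray:
    """Unit-scale expression profile for a named archetype.

    Parameters
    ----------
    name:
        One of the pattern names above (or ``Flat``).
    internodes:
        Either an internode count or the ordered internode labels
        (youngest first); only the length is used.

    Returns
    -------
    Array of per-internode relative expression, peak value 1.0.
    """
    if name not in _ANCHORS:
        raise KeyError(
            f"unknown archetype {name!r}; expected one of {sorted(_ANCHORS)}"
        )
    n = internodes if isinstance(internodes, int) else len(internodes)
    if n < 2:
        raise ValueError("an archetype needs at least two internodes")
    anchor = np.asarray(_ANCHORS[name], dtype=float)
    x_old = np.linspace(0.0, 1.0, anchor.size)
    x_new = np.linspace(0.0, 1.0, n)
    return np.interp(x_new, x_old, anchor)
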