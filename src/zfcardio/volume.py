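"""Ventricular volume from ellipse semi-axes (prolate-spheroid model).

The embryonic ventricle is modelled as a spheroid of revolution about its
long axis, with semi-axes ``a`` (long) and ``b`` (short) taken from the
best-fitting ellipse of the imaged lumen.  Two variants are provided:

* the literal source formula ``V = 4 * a * b**2 / 3`` (default), and
* the geometric prolate-spheroid volume ``V = (4/3) * pi * a * b**2``
  via ``include_pi=True``.

Inputs are micrometres; the result is picolitres (1 pl = 1000 um^3).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["prolate_volume_pl", "UM3_PER_PL"]

#: cubic micrometres per picolitre
UM3_PER_PL = 1000.0


def prolate_volume_pl(a_um, b_um, include_pi: bool = False):
    """Volume in pl from long/short semi-axes in um (scalars or arrays)."""
    a = np.asarray(a_um, dtype=float)
    b = np.asarray(b_um, dtype=float)
    v_um3 = 4.0 * a * b * b / 3.0
    if include_pi:
        v_um3 = v_um3 * math.pi
    v_pl = v_um3 / UM3_PER_PL
    if np.isscalar(a_um) and np.isscalar(b_um):
        return float(v_pl)
    return v_pl
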