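"""Scalp montage helpers: standard 10-05 positions, regions, 2-D projection.

Positions come from the standard 10-05 template montage shipped with MNE;
they are projected to the plane with an azimuthal-equidistant projection
(vertex Cz at the origin, nose along +y), the usual flattening used for
scalp topographies.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: electrode groups used for region-level relevance statistics
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "Fp1", "Fp2", "Fpz", "AF1", "AF2", "AFz",
        "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "Fz",
    ),
    "temporal": ("FT9", "FT10", "T7", "T8", "TP9", "TP10"),
    "parietal": (
        "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "CPz",
        "P1", "P2", "P3", "P4", "P7", "P8", "Pz",
    ),
}

#: 60-channel TMS-compatible cap emulated by the synthetic generator
DEFAULT_60 = (
    REGIONS["frontal"]
    + REGIONS["temporal"]
    + REGIONS["parietal"]
    + ("FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FCz",
       "C1", "C2", "C3", "C4", "C5", "C6", "Cz",
       "PO3", "PO4", "POz", "PO7", "PO8",
       "O1", "O2", "Oz", "P5", "P6", "Iz")
)


@lru_cache(maxsize=1)
def _standard_positions_3d() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v, dtype=float) for k, v in mont.get_positions()["ch_pos"].items()}


def _flatten(p: np.ndarray) -> np.ndarray:
    # azimuthal-equidistant: radius = polar angle from the vertex, angle kept
    r = np.linalg.norm(p)
    if r == 0:
        return np.zeros(2)
    alpha = np.arccos(np.clip(p[2] / r, -1.0, 1.0))
    rho = np.hypot(p[0], p[1])
    if rho == 0:
        return np.zeros(2)
    return alpha * np.array([p[0] / rho, p[1] / rho])


@lru_cache(maxsize=1)
def standard_positions_2d() -> dict[str, np.ndarray]:
    """Flattened (x, y) scalp coordinates of every standard 10-05 electrode."""
    return {k: _flatten(p) for k, p in _standard_positions_3d().items()}


def positions_2d(labels, extra: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """(n, 2) flattened coordinates for the given labels.

    Unknown labels must be supplied through ``extra`` (already-flattened 2-D
    coordinates); otherwise an error names them.
    """
    std = standard_positions_2d()
    out = []
    for lab in labels:
        if extra is not None and lab in extra:
            out.append(np.asarray(extra[lab], dtype=float))
        elif lab in std:
            out.append(std[lab])
        else:
            raise ValueError(
                f"unknown channel label {lab!r} and no coordinates supplied for it"
            )
    return np.array(out)
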