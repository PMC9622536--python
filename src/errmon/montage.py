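"""Electrode montage on the unit sphere.

The recording setup is 63 active scalp electrodes in the extended 10-20
layout, referenced online to the left mastoid, plus two mastoid channels
(M1/M2) and bipolar horizontal/vertical EOG.  All spatial computation in
this package (spherical-spline Laplacian, Gaussian component topographies,
spatially correlated noise) works on unit-sphere electrode positions.

Positions are taken from MNE's standard 10-05 montage and projected onto
the unit sphere around the head centre.  The two non-standard primed
central sites (C3', C4') are placed as normalized midpoints of their
flanking standard sites.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 63 scalp labels of the recording cap, in cap order.
SCALP_63 = (
    "Fp1 Fp2 AF7 AF3 AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C3' C1 Cz C2 C4 C4' C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO3 POz PO4 PO8 PO9 O1 Oz O2 PO10"
).split()

MASTOIDS = ("M1", "M2")
EOG = ("hEOG", "vEOG")

#: (primed label, (flank a, flank b)) — primed sites halfway between flanks.
_PRIMED = {"C3'": ("C3", "C5"), "C4'": ("C4", "C6")}


@lru_cache(maxsize=4)
def _standard_positions() -> dict:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    # algebraic least-squares sphere fit: |x|^2 = 2 c.x + (r^2 - |c|^2)
    arr = np.array([p for p in pos.values()])
    A = np.c_[2 * arr, np.ones(len(arr))]
    b = (arr**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    out = {}
    for name, p in pos.items():
        v = np.asarray(p, float) - centre
        out[name] = v / np.linalg.norm(v)
    return out


def unit_positions(labels) -> np.ndarray:
    """Unit-sphere (x, y, z) positions for scalp/mastoid labels.

    EOG channels have no scalp position and are rejected here.
    """
    std = _standard_positions()
    alias = {"M1": "M1", "M2": "M2", "Fp1": "Fp1", "Fp2": "Fp2"}
    upper = {k.upper(): k for k in std}
    out = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        if lab in EOG:
            raise ValueError(f"channel {lab!r} has no scalp position")
        if lab in _PRIMED:
            a, b = _PRIMED[lab]
            v = std[upper[a.upper()]] + std[upper[b.upper()]]
            out[i] = v / np.linalg.norm(v)
            continue
        key = alias.get(lab, lab)
        if key not in std:
            key = upper.get(lab.upper())
            if key is None:
                raise KeyError(f"no standard position for channel {lab!r}")
        out[i] = std[key]
    return out


def cosine_distances(positions: np.ndarray) -> np.ndarray:
    """Matrix of cos(angle) between electrode pairs, clipped to [-1, 1]."""
    c = positions @ positions.T
    return np.clip(c, -1.0, 1.0)


def angular_distance(positions: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """Great-circle angle (radians) from each position to ``centre``."""
    c = np.clip(positions @ np.asarray(centre, float), -1.0, 1.0)
    return np.arccos(c)


def gaussian_topography(labels, centre_label: str, fwhm_deg: float = 70.0) -> np.ndarray:
    """Spherical Gaussian weights peaking (weight 1) at ``centre_label``.

    ``fwhm_deg`` is the full width at half maximum of the weight profile in
    great-circle degrees; ~70 deg mimics the spatial spread of a
    fronto-central ERP component on the scalp.
    """
    pos = unit_positions(labels)
    centre = pos[list(labels).index(centre_label)]
    theta = angular_distance(pos, centre)
    sigma = np.deg2rad(fwhm_deg) / 2.3548200450309493  # FWHM -> sigma
    return np.exp(-0.5 * (theta / sigma) ** 2)


def spatial_correlation(labels, decay_deg: float = 40.0) -> np.ndarray:
    """Exponential-decay inter-electrode correlation matrix.

    corr(i, j) = exp(-angle_ij / decay) — background EEG recorded at nearby
    sites is strongly correlated; ``decay_deg`` sets the e-folding angle.
    """
    pos = unit_positions(labels)
    ang = np.arccos(cosine_distances(pos))
    return np.exp(-ang / np.deg2rad(decay_deg))
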