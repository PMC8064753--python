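"""Object-based RNA-granule colocalization.

RNA spots detected on the smFISH channel are reduced to their
intensity-weighted centers of mass; a spot counts as granule-associated
when its center-of-mass pixel lies inside a granule particle's footprint
(both mapped to the raw grid).  The fraction of spots contained in
granules is the colocalization readout; condition values are normalized
to the mean of a control condition.  Pixel-correlation measures (Pearson,
Manders) are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .detect import DetectionParams, SPOT_PARAMS, GranuleSet, detect_particles, preprocess
from .image import ImageField

__all__ = [
    "SpotSet",
    "ColocResult",
    "detect_spots",
    "fraction_in_granules",
    "normalize_to_control",
]


@dataclass
class SpotSet:
    """RNA-spot centers of mass on the raw grid."""

    spots: pd.DataFrame  # columns: spot_id, row, col, area_px
    channel: str = ""

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def centers(self) -> np.ndarray:
        return self.spots[["row", "col"]].to_numpy(dtype=float)


class ColocResult(NamedTuple):
    fraction: float
    n_in: int
    n_total: int


def detect_spots(field: ImageField, params: DetectionParams = SPOT_PARAMS) -> SpotSet:
    """Detect smFISH spots and return raw-grid centers of mass.

    Runs the particle detector with spot defaults (relative threshold
    0.3434, minimum size 4, no antibody-channel size exclusion); centers
    of mass are weighted by the band-pass response and mapped back to the
    raw grid by the resize factor.  An empty result is valid.
    """
    det = preprocess(field, params)
    gset = detect_particles(det, params)
    f = float(params.resize_factor)
    # area-centered inverse of the xf upsampling (see GranuleSet.raw_centroids)
    spots = pd.DataFrame(
        {
            "spot_id": gset.particles["id"].to_numpy(),
            "row": (gset.particles["wcentroid_row"].to_numpy(dtype=float) + 0.5) / f - 0.5,
            "col": (gset.particles["wcentroid_col"].to_numpy(dtype=float) + 0.5) / f - 0.5,
            "area_px": gset.particles["area_px"].to_numpy(),
        }
    )
    h, w = gset.raw_shape
    spots["row"] = spots["row"].clip(0, h - 1)
    spots["col"] = spots["col"].clip(0, w - 1)
    return SpotSet(spots=spots, channel=field.channel)


def fraction_in_granules(
    spots: SpotSet, granules: GranuleSet, tolerance_px: int = 0
) -> ColocResult:
    """Fraction of spots whose center-of-mass pixel lies inside a granule.

    Membership is tested at the single center-of-mass pixel rounded to the
    nearest raw pixel; ``tolerance_px`` optionally dilates the granule
    footprints by that radius before the test (0 = strict membership).
    Raises when there are no spots (the fraction is undefined, not 0).
    """
    if spots.n_spots == 0:
        raise ValueError("fraction undefined: no spots detected")
    mask = granules.raw_footprint_mask()
    if tolerance_px > 0:
        rr, cc = np.mgrid[-tolerance_px : tolerance_px + 1, -tolerance_px : tolerance_px + 1]
        mask = ndi.binary_dilation(mask, structure=rr**2 + cc**2 <= tolerance_px**2)
    h, w = mask.shape
    centers = np.round(spots.centers()).astype(int)
    centers[:, 0] = np.clip(centers[:, 0], 0, h - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, w - 1)
    inside = mask[centers[:, 0], centers[:, 1]]
    n_in = int(inside.sum())
    return ColocResult(n_in / spots.n_spots, n_in, spots.n_spots)


def normalize_to_control(
    values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """Divide each value by the mean of the control values.

    The control set maps to mean 1; the result is invariant to a common
    rescaling of all raw fractions.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(values, dtype=float) / control.mean()
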