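"""Cuticular-brightness protocol: patch brightness, worker averaging,
pale/dark classification, and the pale-vs-dark group comparison.

Brightness B follows the HSB convention of image editors' color pickers:
per pixel, B = max(R, G, B) / 255 x 100 (for grayscale, the gray value
itself scaled to percent).  A patch's brightness is the mean over its
pixels; a worker's brightness is the mean over the three tagmata (head,
mesosoma, gaster); a species' brightness is the mean over its workers.

Two classification schemes are supported.  The main-study scheme has an
empirical gap: every dark species mean fell below 60 and every pale mean
above 65, so B > 65 is pale, B < 60 dark, and the gap indeterminate.  The
survey scheme is a single cut at B > 70.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .model import BrightnessResult, ConfigurationError, PixelPatch, ValidationError

__all__ = [
    "patch_brightness",
    "worker_brightness",
    "species_brightness",
    "classify_color",
    "brightness_group_test",
]

logger = logging.getLogger(__name__)

#: main-study thresholds: pale above, dark below, indeterminate between
PALE_THRESHOLD = 65.0
DARK_THRESHOLD = 60.0
#: single survey cutoff
SURVEY_THRESHOLD = 70.0


def patch_brightness(patch: PixelPatch) -> float:
    """Mean HSB brightness of a patch, in percent.

    Invariant to pixel permutation and monotone in every channel value.
    """
    if not isinstance(patch, PixelPatch):
        patch = PixelPatch(patch)
    v = patch.values
    if v.ndim == 3:
        per_pixel = v.max(axis=2)
    else:
        per_pixel = v
    return float(per_pixel.mean() / 255.0 * 100.0)


def worker_brightness(
    head_B: float | None,
    mesosoma_B: float | None,
    gaster_B: float | None,
) -> BrightnessResult:
    """Average the three tagma brightness values for one worker.

    Missing tagmata (``None``) are skipped with a logged warning; at least
    one value is required.  Values must lie in [0, 100].
    """
    per_tagma = {"head": head_B, "mesosoma": mesosoma_B, "gaster": gaster_B}
    present = {}
    for tagma, b in per_tagma.items():
        if b is None:
            logger.warning("worker_brightness: missing %s value, averaging rest", tagma)
            continue
        if not (0.0 <= b <= 100.0):
            raise ValidationError(f"{tagma} brightness {b} outside [0, 100]")
        present[tagma] = float(b)
    if not present:
        raise ValidationError("no tagma brightness values supplied")
    return BrightnessResult(
        per_tagma=present, worker_B=float(np.mean(list(present.values())))
    )


def species_brightness(worker_Bs: Sequence[float]) -> float:
    """Species brightness: mean over workers."""
    if len(worker_Bs) == 0:
        raise ValidationError("no worker brightness values supplied")
    return float(np.mean(worker_Bs))


def classify_color(species_B: float, scheme: str = "main_study") -> str:
    """Classify a species-mean brightness as pale/dark (/indeterminate)."""
    if not (0.0 <= species_B <= 100.0):
        raise ValidationError(f"brightness {species_B} outside [0, 100]")
    if scheme == "main_study":
        if species_B > PALE_THRESHOLD:
            return "pale"
        if species_B < DARK_THRESHOLD:
            return "dark"
        return "indeterminate"
    if scheme == "survey":
        return "pale" if species_B > SURVEY_THRESHOLD else "dark"
    raise ConfigurationError(f"unknown classification scheme {scheme!r}")


def brightness_group_test(pale_Bs: Sequence[float], dark_Bs: Sequence[float]) -> dict:
    """Pooled-variance two-sample t comparing dark vs pale species means.

    The statistic is oriented dark-minus-pale (ascending alphabetical group
    coding, the convention of string-coded factors in common statistical
    software), so pale > dark yields a negative t.  Returns
    ``{"t", "df", "p"}`` with df = n1 + n2 - 2 and a two-sided p.
    """
    pale = np.asarray(pale_Bs, dtype=float)
    dark = np.asarray(dark_Bs, dtype=float)
    if len(pale) < 2 or len(dark) < 2:
        raise ValidationError("each group needs at least 2 values")
    n1, n2 = len(dark), len(pale)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * dark.var(ddof=1) + (n2 - 1) * pale.var(ddof=1)) / df
    diff = dark.mean() - pale.mean()
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    from scipy import stats as _st

    p = float(2.0 * _st.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return {"t": float(t), "df": int(df), "p": p}
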