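"""PAD (pleasure-arousal-dominance) coordinates and the induction filter.

Per-minute self-reports are scored on a 0-100 scale per axis and mapped to
the original PAD cube [-1, 1]^3 by ``x = score / 50 - 1``.  A report counts
as *effectively induced* when its Euclidean distance to the target emotion's
reference point, measured in the original cube, is strictly below 0.25 (one
step of the pictorial scale).  Windows belonging to an ineffective minute are
excluded from that emotion's training data; natural-state data bypass the
filter (no reference point exists for it).
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: strict effectiveness radius in the original PAD cube
EFFECTIVENESS_RADIUS = 0.25

ORIGINAL = "original"
CONVERTED = "converted"


def _load_reference() -> dict[str, tuple[float, float, float]]:
    text = resources.files("emodrive").joinpath("data/pad_reference.yaml").read_text()
    raw = yaml.safe_load(text)
    return {k: tuple(float(x) for x in v) for k, v in raw.items()}


#: converted-scale (0-100) reference coordinates per emotion
PAD_REFERENCE_CONVERTED: dict[str, tuple[float, float, float]] = _load_reference()


def convert_scale(coords, to: str):
    """Affine map between the 0-100 report scale and the [-1, 1] cube.

    ``to="original"`` applies ``x/50 - 1``; ``to="converted"`` its inverse.
    Inputs outside the source scale's bounds raise.
    """
    x = np.asarray(coords, dtype=float)
    if to == ORIGINAL:
        if np.any(x < 0) or np.any(x > 100):
            raise ValueError("converted-scale PAD values must lie in [0, 100]")
        return x / 50.0 - 1.0
    if to == CONVERTED:
        if np.any(x < -1) or np.any(x > 1):
            raise ValueError("original-scale PAD values must lie in [-1, 1]")
        return (x + 1.0) * 50.0
    raise ValueError(f"unknown scale tag {to!r}")


def reference_original(emotion: str,
                       reference: Mapping[str, tuple] | None = None) -> np.ndarray:
    """Target emotion's reference point in the original cube."""
    table = PAD_REFERENCE_CONVERTED if reference is None else reference
    if emotion not in table:
        raise KeyError(f"unknown emotion {emotion!r}")
    return convert_scale(table[emotion], to=ORIGINAL)


def effectiveness_filter(
    reports,
    emotion: str,
    reference: Mapping[str, tuple] | None = None,
    threshold: float = EFFECTIVENESS_RADIUS,
) -> tuple[pd.DataFrame, float]:
    """Score per-minute PAD reports against a target emotion.

    Parameters
    ----------
    reports
        (n, 3) array-like of original-scale PAD triples, one per minute,
        in temporal order.
    emotion
        Target emotion; must exist in the reference table.
    reference
        Optional converted-scale reference table overriding the built-in one.
    threshold
        Strict distance threshold; the default mirrors one scale step.

    Returns
    -------
    records, fraction
        ``records`` has columns ``minute, P, A, D, distance, effective`` in
        input order; ``fraction`` is the effective share.
    """
    target = reference_original(emotion, reference)
    x = np.asarray(reports, dtype=float).reshape(-1, 3)
    if x.shape[0] == 0:
        raise ValueError("no PAD reports supplied")
    dist = np.linalg.norm(x - target, axis=1)
    effective = dist < threshold
    records = pd.DataFrame(
        {
            "minute": np.arange(x.shape[0]),
            "P": x[:, 0],
            "A": x[:, 1],
            "D": x[:, 2],
            "distance": dist,
            "effective": effective,
        }
    )
    return records, float(effective.mean())
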