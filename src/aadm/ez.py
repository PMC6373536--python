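"""EZ-diffusion: closed-form mapping between Wiener-process parameters and
observable response moments, and its exact algebraic inverse.

For a symmetric starting point z = a/2 and scaling s, with
``y = exp(-v a / s^2)``:

    Pc  = 1 / (1 + y)
    MDT = (a / 2v) * (1 - y) / (1 + y)          (mean decision time)
    MRT = Ter + MDT
    VRT = (a s^2 / 2 v^3) * (2 w e^w - e^{2w} + 1) / (e^w + 1)^2,  w = -v a / s^2

The inverse recovers (v, a, Ter) exactly from (Pc, MRT, VRT):

    L   = logit(Pc)
    v   = sign(Pc - 1/2) * s * [ L (L Pc^2 - L Pc + Pc - 1/2) / VRT ]^{1/4}
    a   = s^2 L / v
    Ter = MRT - MDT(v, a)

Observed cells with Pc in {0, 1/2, 1} are undefined under the inverse;
``edge_correct`` nudges them by the minimal-perturbation 1/(2n) convention
before inversion. With an unbiased start and no inter-trial variability
the correct- and error-response decision-time distributions coincide, so
moments of correct RTs alone identify the parameters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import DiffusionParams

__all__ = ["ez_forward", "edge_correct", "ez_inverse", "estimate_all", "EZError"]

ESTIMATE_COLUMNS = [
    "participant_id",
    "participant_gender",
    "expression",
    "required_response",
    "face_gender",
    "v",
    "a",
    "ter",
    "s",
    "edge_corrected",
    "degenerate",
    "n_basis",
]


class EZError(ValueError):
    """Raised when EZ moments or estimates are undefined for the input."""


def ez_forward(params: DiffusionParams) -> tuple[float, float, float]:
    """Population (Pc, MRT in s, VRT in s^2) of the symmetric-start process."""
    v, a, ter, s = params.v, params.a, params.ter, params.s
    if v == 0:
        raise EZError("moments are undefined at v = 0 (Pc would be exactly 1/2)")
    w = -v * a / (s * s)
    y = math.exp(w)
    pc = 1.0 / (1.0 + y)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    vrt = (a * s * s / (2.0 * v**3)) * (2.0 * w * y - y * y + 1.0) / (y + 1.0) ** 2
    return pc, ter + mdt, vrt


def edge_correct(pc: float, n: int) -> tuple[float, bool]:
    """Nudge degenerate accuracies off {0, 1/2, 1} by 1/(2n).

    Returns the (possibly corrected) accuracy and a flag saying whether a
    correction was applied.
    """
    if not 0.0 <= pc <= 1.0:
        raise ValueError(f"pc must lie in [0, 1], got {pc}")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = 1.0 / (2.0 * n)
    if pc == 1.0:
        return 1.0 - half, True
    if pc == 0.0:
        return half, True
    if pc == 0.5:
        return 0.5 + half, True
    return pc, False


def ez_inverse(
    pc: float, mrt_s: float, vrt_s2: float, s: float = 1.0
) -> tuple[float, float, float]:
    """Recover (v, a, ter) from observed moments; exact inverse of ez_forward."""
    if any(map(math.isnan, (pc, mrt_s, vrt_s2))):
        raise EZError("moments contain NaN (degenerate cell)")
    if not 0.0 < pc < 1.0 or pc == 0.5:
        raise EZError(
            f"pc={pc} is outside the invertible range (apply edge_correct first)"
        )
    if vrt_s2 <= 0:
        raise EZError(f"RT variance must be positive, got {vrt_s2}")
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt_s2
    v = math.copysign(s * x**0.25, pc - 0.5)
    a = s * s * L / v
    y = math.exp(-v * a / (s * s))
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    return v, a, mrt_s - mdt


def estimate_all(summaries: pd.DataFrame, s: float = 1.0) -> pd.DataFrame:
    """EZ estimates for every cell-summary row; failures flagged, not dropped.

    Negative ter estimates are retained (clamping would bias downstream
    ANOVAs); cells whose accuracy needed the 1/(2n) edge correction carry
    ``edge_corrected=True``; cells that remain uninvertible (e.g. zero RT
    variance) carry ``degenerate=True`` with NaN parameters.
    """
    rows = []
    for rec in summaries.to_dict("records"):
        out = {
            k: rec[k]
            for k in (
                "participant_id",
                "participant_gender",
                "expression",
                "required_response",
                "face_gender",
            )
        }
        out.update({"s": s, "n_basis": rec["n_total"]})
        try:
            pc, corrected = edge_correct(rec["pc"], rec["n_total"])
            v, a, ter = ez_inverse(pc, rec["mrt_s"], rec["vrt_s2"], s=s)
            out.update(
                {"v": v, "a": a, "ter": ter, "edge_corrected": corrected,
                 "degenerate": False}
            )
        except (EZError, ValueError, TypeError):
            out.update(
                {"v": np.nan, "a": np.nan, "ter": np.nan, "edge_corrected": False,
                 "degenerate": True}
            )
        rows.append(out)
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
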