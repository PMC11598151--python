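"""Confusion-matrix accuracy assessment for binary extraction maps.

From TP/TN/FP/FN over valid pixels:

    OA    = (TP + TN) / N
    AA    = 1/2 (TP/(TP+FN) + TN/(TN+FP))
    PA    = TP / (TP + FP)
    Kappa = (p0 - pe) / (1 - pe),  p0 = OA,
    pe    = ((TP+FP)(TP+FN) + (FN+TN)(FP+TN)) / N^2

Note on PA: the convention followed here defines producer's accuracy as
TP/(TP+FP) (positive predictive value). The more common remote-sensing
convention is TP/(TP+FN); pass ``pa_convention="standard"`` for that form.
Metrics whose denominator is empty are reported as NaN and flagged, never
silently zeroed. The positive class is the target (mask value 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import BinaryMask

__all__ = ["ConfusionCounts", "confusion", "confusion_from_counts"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    oa: float = float("nan")
    aa: float = float("nan")
    pa: float = float("nan")
    kappa: float = float("nan")
    p0: float = float("nan")
    pe: float = float("nan")
    undefined: tuple[str, ...] = field(default_factory=tuple)
    pa_convention: str = "ppv"

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "oa": self.oa, "aa": self.aa, "pa": self.pa, "kappa": self.kappa,
            "p0": self.p0, "pe": self.pe,
            "undefined": list(self.undefined), "pa_convention": self.pa_convention,
        }


def confusion_from_counts(
    tp: int, tn: int, fp: int, fn: int, pa_convention: str = "ppv"
) -> ConfusionCounts:
    """Derive OA/AA/PA/Kappa from raw counts."""
    if pa_convention not in ("ppv", "standard"):
        raise ValueError("pa_convention must be 'ppv' or 'standard'")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    undefined = []
    oa = p0 = (tp + tn) / n

    recall_den, spec_den = tp + fn, tn + fp
    if recall_den and spec_den:
        aa = 0.5 * (tp / recall_den + tn / spec_den)
    else:
        aa = float("nan")
        undefined.append("aa")

    pa_den = (tp + fp) if pa_convention == "ppv" else (tp + fn)
    if pa_den:
        pa = tp / pa_den
    else:
        pa = float("nan")
        undefined.append("pa")

    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe != 1.0:
        kappa = (p0 - pe) / (1.0 - pe)
    else:
        kappa = float("nan")
        undefined.append("kappa")

    return ConfusionCounts(tp, tn, fp, fn, oa, aa, pa, kappa, p0, pe,
                           tuple(undefined), pa_convention)


def confusion(
    pred: BinaryMask,
    truth: BinaryMask,
    valid: BinaryMask | np.ndarray | None = None,
    pa_convention: str = "ppv",
) -> ConfusionCounts:
    """Confusion counts and accuracy metrics over valid pixels."""
    p, t = pred.data, truth.data
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if valid is None:
        v = np.ones(p.shape, dtype=bool)
    else:
        v = valid.data if isinstance(valid, BinaryMask) else np.asarray(valid, dtype=bool)
        if v.shape != p.shape:
            raise ValueError("valid mask shape mismatch")
    if not v.any():
        raise ValueError("no valid pixels to evaluate")
    p, t = p[v], t[v]
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return confusion_from_counts(tp, tn, fp, fn, pa_convention)
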