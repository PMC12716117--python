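"""Cross-run retention-time alignment and median-ppm mass recalibration.

Retention times of each acquisition are mapped onto a reference acquisition
(the one with the most distinct proteoforms) by a robust locally weighted
(LOESS, degree 1) regression fitted to the retention times of proteoforms
shared with the reference.  Masses are recalibrated per dataset by the
median ppm error of confidently identified records:
``corrected = observed / (1 + median_ppm * 1e-6)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import ProteoformKey
from .ingest import decode_mod_shifts

logger = logging.getLogger("proformquant")

DEFAULT_SPAN = 0.5
DEFAULT_MIN_ANCHORS = 10
LOWESS_ROBUST_ITERS = 2


def _key_columns(frame: pd.DataFrame) -> pd.Series:
    """Canonical proteoform key tuple per row (targets only make sense)."""
    sigs = frame["mod_shifts"].map(
        lambda s: tuple(sorted((round(d, 2), loc)
                               for d, loc in decode_mod_shifts(s))))
    return pd.Series(
        list(zip(frame["gene"], frame["accession"], frame["first_aa"],
                 frame["last_aa"], sigs)),
        index=frame.index, name="pf_key")


def choose_reference(frame: pd.DataFrame) -> str:
    """Dataset with the most distinct proteoform keys (ties: first id)."""
    targets = frame[~frame["is_decoy"]]
    counts = (targets.assign(pf_key=_key_columns(targets))
              .groupby("dataset_id")["pf_key"].nunique())
    if counts.empty:
        raise ValueError("no identified records to choose a reference from")
    counts = counts.sort_index()
    return str(counts.index[int(np.argmax(counts.to_numpy()))])


def find_anchors(frame: pd.DataFrame, dataset_id: str,
                 reference_id: str) -> np.ndarray:
    """Paired (rt_local, rt_ref) for proteoforms shared with the reference.

    One pair per shared key, using the best-E-value observation of that key
    in each dataset.
    """
    targets = frame[~frame["is_decoy"]].copy()
    targets["pf_key"] = _key_columns(targets)
    best = (targets.sort_values("evalue", kind="mergesort")
            .drop_duplicates(["dataset_id", "pf_key"]))
    local = best[best["dataset_id"] == dataset_id][["pf_key", "rt_min"]]
    ref = best[best["dataset_id"] == reference_id][["pf_key", "rt_min"]]
    merged = local.merge(ref, on="pf_key", suffixes=("_local", "_ref"))
    return merged[["rt_min_local", "rt_min_ref"]].to_numpy(float)


class LoessCurve:
    """Monotone-ish RT mapping fitted by robust LOESS with linear tails."""

    def __init__(self, anchors: np.ndarray, span: float = DEFAULT_SPAN):
        if not (0 < span <= 1):
            raise ValueError("span must be in (0, 1]")
        anchors = np.asarray(anchors, dtype=float)
        x, y = anchors[:, 0], anchors[:, 1]
        if np.ptp(x) == 0:
            raise ValueError("degenerate anchors: all local RTs equal")
        fitted = lowess(y, x, frac=span, it=LOWESS_ROBUST_ITERS,
                        return_sorted=True)
        fx, fy = fitted[:, 0], fitted[:, 1]
        # collapse duplicate x for interpolation
        ux, inv = np.unique(fx, return_inverse=True)
        uy = np.zeros_like(ux)
        cnt = np.bincount(inv)
        np.add.at(uy, inv, fy)
        uy /= cnt
        self._x, self._y = ux, uy
        self.span = span
        self.n_anchors = len(x)

    def __call__(self, rt: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        out = np.interp(rt, self._x, self._y)
        # linear extrapolation from the boundary segments
        if len(self._x) >= 2:
            lo = rt < self._x[0]
            hi = rt > self._x[-1]
            if lo.any():
                s = (self._y[1] - self._y[0]) / (self._x[1] - self._x[0])
                out[lo] = self._y[0] + s * (rt[lo] - self._x[0])
            if hi.any():
                s = (self._y[-1] - self._y[-2]) / (self._x[-1] - self._x[-2])
                out[hi] = self._y[-1] + s * (rt[hi] - self._x[-1])
        return out


class IdentityCurve:
    span = None
    n_anchors = 0

    def __call__(self, rt):
        return np.asarray(rt, dtype=float)


def fit_alignment(anchors: np.ndarray, span: float = DEFAULT_SPAN) -> LoessCurve:
    return LoessCurve(anchors, span=span)


@dataclass
class AlignmentModel:
    """Per-dataset fitted RT curves onto a common reference."""

    reference_id: str
    curves: dict = field(default_factory=dict)
    anchor_counts: dict = field(default_factory=dict)
    span: float = DEFAULT_SPAN

    def predict(self, dataset_id: str, rt: np.ndarray) -> np.ndarray:
        return self.curves[dataset_id](rt)

    def diagnostics(self) -> pd.DataFrame:
        rows = [{"dataset_id": ds,
                 "n_anchors": self.anchor_counts.get(ds, 0),
                 "span": getattr(c, "span", None),
                 "identity": isinstance(c, IdentityCurve)}
                for ds, c in sorted(self.curves.items())]
        return pd.DataFrame(rows)


def align_retention_times(frame: pd.DataFrame, span: float = DEFAULT_SPAN,
                          min_anchors: int = DEFAULT_MIN_ANCHORS):
    """Fit per-dataset LOESS curves and add an ``rt_aligned`` column.

    The reference dataset keeps its own retention times (identity curve).
    Datasets with fewer than ``min_anchors`` shared proteoforms fall back to
    the identity with a warning.
    """
    reference = choose_reference(frame)
    model = AlignmentModel(reference_id=reference, span=span)
    out = frame.copy()
    out["rt_aligned"] = np.nan
    for ds, sub in out.groupby("dataset_id"):
        if ds == reference:
            curve: object = IdentityCurve()
            model.anchor_counts[ds] = 0
        else:
            anchors = find_anchors(frame, ds, reference)
            model.anchor_counts[ds] = len(anchors)
            if len(anchors) < min_anchors:
                logger.warning("alignment %s: only %d anchors (<%d); "
                               "using identity", ds, len(anchors), min_anchors)
                curve = IdentityCurve()
            else:
                curve = LoessCurve(anchors, span=span)
        model.curves[ds] = curve
        out.loc[sub.index, "rt_aligned"] = curve(sub["rt_min"].to_numpy())
    return out, model


# ---------------------------------------------------------------------------
# Mass recalibration


@dataclass
class RecalModel:
    """Per-dataset median ppm corrections: mass / (1 + ppm * 1e-6)."""

    median_ppm: dict = field(default_factory=dict)
    global_mode: bool = False

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"dataset_id": ds, "median_ppm": ppm}
             for ds, ppm in sorted(self.median_ppm.items())])


def ppm_error(observed: np.ndarray, theoretical: np.ndarray) -> np.ndarray:
    observed = np.asarray(observed, dtype=float)
    theoretical = np.asarray(theoretical, dtype=float)
    return (observed - theoretical) / theoretical * 1e6


def recalibrate_masses(frame: pd.DataFrame, theoretical: pd.Series,
                       global_median: bool = False):
    """Recalibrate observed masses by the median ppm error.

    ``theoretical`` is aligned with ``frame`` and may be NaN for records
    without a confident identification; only non-NaN records contribute to
    the median, but the correction applies to every record of the dataset.
    Adds a ``mass_recal`` column; returns ``(frame, RecalModel)``.
    """
    out = frame.reset_index(drop=True).copy()
    theo = np.asarray(theoretical, dtype=float)
    errs = ppm_error(out["mass_da"].to_numpy(), theo)
    model = RecalModel(global_mode=global_median)
    if global_median:
        valid = np.isfinite(errs)
        med = float(np.median(errs[valid])) if valid.any() else 0.0
        for ds in out["dataset_id"].unique():
            model.median_ppm[ds] = med
        out["mass_recal"] = out["mass_da"] / (1 + med * 1e-6)
        return out, model
    out["mass_recal"] = np.nan
    for ds, sub in out.groupby("dataset_id"):
        e = errs[sub.index.to_numpy()]
        valid = np.isfinite(e)
        if valid.any():
            med = float(np.median(e[valid]))
        else:
            logger.warning("recalibration %s: no identified records; "
                           "correction 0", ds)
            med = 0.0
        model.median_ppm[ds] = med
        out.loc[sub.index, "mass_recal"] = (
            sub["mass_da"].to_numpy() / (1 + med * 1e-6))
    return out, model
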