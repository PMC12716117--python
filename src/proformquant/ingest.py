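"""Reading PSM tables, E-value ceiling, and target-decoy FDR filtering.

The canonical PSM dialect is a UTF-8 TSV with the columns in
:data:`CANONICAL_COLUMNS`; other dialects (e.g. TopPIC output) are mapped
onto it through a ``column_map`` of ``canonical -> source`` header names.
Mass-shift lists are encoded ``"<delta>@<first>-<last>"`` joined with ``";"``.

FDR filtering is the standard concatenated target-decoy estimate: at each
E-value rank the running FDR is #decoys / #targets at or above that
confidence; q-values are the cumulative minimum from the worst rank upward,
and targets with q <= the threshold are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PsmRecord

logger = logging.getLogger("proformquant")

CANONICAL_COLUMNS = [
    "dataset_id", "scan", "rt_min", "mass_da", "accession", "gene",
    "first_aa", "last_aa", "mod_shifts", "evalue", "is_decoy", "intensity",
    "cv_volts",
]

#: mapping for the TopPIC output dialect (canonical -> TopPIC header)
TOPPIC_COLUMN_MAP = {
    "dataset_id": "Data file name",
    "scan": "Scan(s)",
    "rt_min": "Retention time",
    "mass_da": "Adjusted precursor mass",
    "accession": "Protein accession",
    "gene": "Gene",
    "first_aa": "First residue",
    "last_aa": "Last residue",
    "mod_shifts": "MIScore",
    "evalue": "E-value",
    "intensity": "Feature intensity",
    "cv_volts": "Compensation voltage",
}

_MANDATORY = ["scan", "rt_min", "mass_da", "evalue"]


def encode_mod_shifts(mods) -> str:
    parts = []
    for m in mods or []:
        if isinstance(m, (tuple, list)):
            delta, loc = m[0], (m[1] if len(m) > 1 else "")
        else:
            delta, loc = m, ""
        parts.append(f"{float(delta):.4f}@{loc}" if loc else f"{float(delta):.4f}")
    return ";".join(parts)


def decode_mod_shifts(text) -> list:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    out = []
    for part in text.split(";"):
        if "@" in part:
            delta, loc = part.split("@", 1)
        else:
            delta, loc = part, ""
        out.append((float(delta), loc))
    return out


@dataclass
class PsmTable:
    """Records from one acquisition plus source metadata."""

    dataset_id: str
    frame: pd.DataFrame
    cv_channels: tuple = ()
    n_dropped: int = 0
    source: str = ""

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> list:
        return frame_to_records(self.frame)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "dataset_id": r.dataset_id, "scan": r.scan, "rt_min": r.rt_min,
            "mass_da": r.mass_da, "accession": r.accession, "gene": r.gene,
            "first_aa": r.first_aa, "last_aa": r.last_aa,
            "mod_shifts": encode_mod_shifts(r.mod_shifts_da),
            "evalue": r.evalue, "is_decoy": bool(r.is_decoy),
            "intensity": r.intensity, "cv_volts": str(r.cv_volts),
        })
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list:
    out = []
    for row in frame.itertuples(index=False):
        out.append(PsmRecord(
            dataset_id=str(row.dataset_id), scan=int(row.scan),
            rt_min=float(row.rt_min), mass_da=float(row.mass_da),
            accession=str(row.accession), gene=str(row.gene),
            first_aa=int(row.first_aa), last_aa=int(row.last_aa),
            mod_shifts_da=decode_mod_shifts(row.mod_shifts),
            evalue=float(row.evalue), is_decoy=bool(row.is_decoy),
            intensity=float(row.intensity), cv_volts=str(row.cv_volts),
        ))
    return out


def _parse_bool(series: pd.Series) -> pd.Series:
    truthy = {"1", "true", "t", "yes", "decoy", "d"}
    return series.astype(str).str.strip().str.lower().isin(truthy)


def read_psm_table(path, column_map: dict | None = None,
                   dataset_id: str | None = None) -> PsmTable:
    """Read one PSM TSV into a typed table.

    ``column_map`` maps canonical names to the file's header names; the
    canonical dialect needs no map.  Rows whose mandatory numeric fields
    fail to parse are dropped and counted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      comment="#")
    colmap = dict(column_map or {})
    frame = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src in raw.columns:
            frame[canon] = raw[src]
        elif canon in ("gene", "mod_shifts", "intensity", "cv_volts",
                       "is_decoy", "dataset_id"):
            frame[canon] = ""
        else:
            raise ValueError(f"missing mandatory column {canon!r} "
                             f"(looked for {src!r}) in {path}")
    for col in ("rt_min", "mass_da", "evalue", "intensity"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    for col in ("scan", "first_aa", "last_aa"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")

    if (frame["is_decoy"] == "").all():
        frame["is_decoy"] = frame["accession"].str.startswith("DECOY_")
    else:
        frame["is_decoy"] = _parse_bool(frame["is_decoy"])

    ok = frame[_MANDATORY].notna().all(axis=1) & (frame["mass_da"] > 0)
    ok &= frame["is_decoy"] | frame[["first_aa", "last_aa"]].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable mandatory fields",
                       path, n_dropped)
    frame = frame[ok].copy()
    for col in ("scan",):
        frame[col] = frame[col].astype(int)
    for col in ("first_aa", "last_aa"):
        frame[col] = frame[col].fillna(0).astype(int)

    if dataset_id is None:
        ids = [v for v in frame["dataset_id"].unique() if v]
        dataset_id = ids[0] if ids else str(path)
    frame["dataset_id"] = dataset_id
    channels = tuple(sorted(v for v in frame["cv_volts"].unique() if v != ""))
    return PsmTable(dataset_id=dataset_id, frame=frame.reset_index(drop=True),
                    cv_channels=channels, n_dropped=n_dropped,
                    source=str(path))


def write_psm_table(frame: pd.DataFrame, path) -> None:
    """Write records in the canonical dialect (round-trips with the reader)."""
    out = frame.copy()
    out["is_decoy"] = out["is_decoy"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False, columns=CANONICAL_COLUMNS)


# ---------------------------------------------------------------------------
# Filtering


def evalue_ceiling(frame: pd.DataFrame, max_e: float = 0.05) -> pd.DataFrame:
    """Retain records with E-value <= ``max_e`` (boundary inclusive)."""
    if max_e <= 0:
        raise ValueError("max_e must be > 0")
    return frame[frame["evalue"] <= max_e].reset_index(drop=True)


def compute_qvalues(evalue: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Target-decoy q-values in input order.

    Records are ranked by ascending E-value with targets before decoys at
    ties (the conservative convention).  Running FDR at rank i is
    ``#decoys(<=i) / max(1, #targets(<=i))``; q-values are the cumulative
    minimum of the running FDR taken from the worst rank upward.
    """
    evalue = np.asarray(evalue, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    order = np.lexsort((is_decoy, evalue))  # targets first at equal evalue
    dec_sorted = is_decoy[order]
    n_dec = np.cumsum(dec_sorted)
    n_tgt = np.cumsum(~dec_sorted)
    running = n_dec / np.maximum(1, n_tgt)
    q_sorted = np.minimum.accumulate(running[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def fdr_filter(frame: pd.DataFrame, target_fdr: float = 0.01,
               per_dataset: bool = False):
    """Filter PSMs to a target-decoy FDR; decoys are removed from the output.

    Returns ``(kept_targets, info)`` where ``info`` holds the E-value
    threshold actually applied and counts.  With ``per_dataset`` the
    procedure runs independently within each ``dataset_id``.
    """
    if not (0 < target_fdr <= 1):
        raise ValueError("target_fdr must be in (0, 1]")
    if per_dataset:
        parts, infos = [], {}
        for ds, sub in frame.groupby("dataset_id", sort=True):
            kept, info = fdr_filter(sub.reset_index(drop=True), target_fdr)
            parts.append(kept)
            infos[ds] = info
        kept = (pd.concat(parts, ignore_index=True) if parts
                else frame.iloc[0:0].copy())
        return kept, {"per_dataset": infos}

    n_targets = int((~frame["is_decoy"]).sum())
    if n_targets == 0:
        logger.warning("fdr_filter: no target records")
        return frame.iloc[0:0].copy(), {"threshold": np.nan, "n_kept": 0,
                                        "n_decoys": int(len(frame))}
    q = compute_qvalues(frame["evalue"].to_numpy(),
                        frame["is_decoy"].to_numpy())
    keep = (~frame["is_decoy"].to_numpy()) & (q <= target_fdr)
    kept = frame[keep].copy()
    kept["qvalue"] = q[keep]
    threshold = float(kept["evalue"].max()) if len(kept) else np.nan
    info = {"threshold": threshold, "n_kept": int(len(kept)),
            "n_decoys": int(frame["is_decoy"].sum()),
            "n_targets": n_targets}
    return kept.reset_index(drop=True), info
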