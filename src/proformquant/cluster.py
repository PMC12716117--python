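"""Mass/RT clustering, identification transfer, and CV intensity roll-up.

Observations from all acquisitions are grouped into proteoform clusters by
complete-linkage agglomeration under the scaled distance

    d = max( |dmass| / (mass * ppm_tol * 1e-6),  |dRT| / rt_tol_min )

with the tree cut at d = 1, so a cluster's diameter is bounded by the
tolerances.  Identifications are extended across runs within a cluster
(match-between-runs): every member inherits the cluster's consensus key.
Within one (sample, CV channel) multiple member features contribute their
maximum intensity (the same elution profile must not be double counted);
across CV channels contributions are summed, since FAIMS channels partition
the ion population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import ProteoformKey, SampleDesign, format_proteoform_name
from .ingest import decode_mod_shifts

logger = logging.getLogger("proformquant")

DEFAULT_PPM_TOL = 10.0
DEFAULT_RT_TOL_MIN = 2.0


def _pairwise_scaled(mass: np.ndarray, rt: np.ndarray, ppm_tol: float,
                     rt_tol: float) -> np.ndarray:
    m = mass[:, None]
    dm = np.abs(m - mass[None, :])
    denom = 0.5 * (m + mass[None, :]) * ppm_tol * 1e-6
    d_mass = dm / denom
    d_rt = np.abs(rt[:, None] - rt[None, :]) / rt_tol
    return np.maximum(d_mass, d_rt)


def cluster_observations(frame: pd.DataFrame, ppm_tol: float = DEFAULT_PPM_TOL,
                         rt_tol_min: float = DEFAULT_RT_TOL_MIN,
                         mass_col: str = "mass_recal",
                         rt_col: str = "rt_aligned") -> pd.DataFrame:
    """Assign every observation to exactly one cluster (``cluster_id``).

    Observations are first partitioned at mass gaps wider than the ppm
    tolerance (no complete-linkage cluster cut at d = 1 can bridge such a
    gap), then each block is agglomerated exactly.
    """
    if ppm_tol <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be > 0")
    out = frame.reset_index(drop=True).copy()
    n = len(out)
    labels = np.zeros(n, dtype=int)
    if n == 0:
        out["cluster_id"] = labels
        return out
    mass = out[mass_col].to_numpy(float)
    rt = out[rt_col].to_numpy(float)
    order = np.lexsort((rt, mass))
    sm = mass[order]
    rel_gap = np.diff(sm) / (0.5 * (sm[1:] + sm[:-1])) * 1e6
    block_starts = np.concatenate([[0], np.nonzero(rel_gap > ppm_tol)[0] + 1,
                                   [len(sm)]])
    next_id = 0
    for b in range(len(block_starts) - 1):
        idx = order[block_starts[b]:block_starts[b + 1]]
        if len(idx) == 1:
            labels[idx] = next_id
            next_id += 1
            continue
        d = _pairwise_scaled(mass[idx], rt[idx], ppm_tol, rt_tol_min)
        z = linkage(squareform(d, checks=False), method="complete")
        flat = fcluster(z, t=1.0, criterion="distance")
        labels[idx] = flat + next_id - 1
        next_id += flat.max()
    out["cluster_id"] = labels
    return out


# ---------------------------------------------------------------------------
# Consensus identification (match-between-runs transfer)


def _row_key(row) -> ProteoformKey | None:
    if row.is_decoy or (not row.gene and not row.accession):
        return None
    mods = tuple((round(d, 2), loc)
                 for d, loc in decode_mod_shifts(row.mod_shifts))
    return ProteoformKey(str(row.gene), str(row.accession),
                         int(row.first_aa), int(row.last_aa), mods)


def assign_consensus(members: pd.DataFrame):
    """Consensus proteoform key of a cluster, or None if unidentified.

    Most frequent identified key wins; ties go to the key with the best
    (lowest) E-value, then lexicographic label (flagged in the log).
    """
    stats: dict = {}
    for row in members.itertuples(index=False):
        key = _row_key(row)
        if key is None:
            continue
        cnt, best_e = stats.get(key, (0, np.inf))
        stats[key] = (cnt + 1, min(best_e, float(row.evalue)))
    if not stats:
        return None
    ranked = sorted(stats.items(),
                    key=lambda kv: (-kv[1][0], kv[1][1],
                                    format_proteoform_name(kv[0])))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        logger.warning("consensus tie broken lexicographically: %s vs %s",
                       format_proteoform_name(ranked[0][0]),
                       format_proteoform_name(ranked[1][0]))
    return ranked[0][0]


@dataclass
class ProteoformCluster:
    """A cross-run group of observations treated as one proteoform."""

    cluster_id: int
    consensus: ProteoformKey | None
    mass_da: float
    rt_min: float
    n_members: int
    member_index: np.ndarray = field(repr=False, default=None)

    @property
    def label(self) -> str | None:
        return None if self.consensus is None else format_proteoform_name(
            self.consensus)


def summarize_clusters(frame: pd.DataFrame,
                       mass_col: str = "mass_recal",
                       rt_col: str = "rt_aligned") -> list:
    """Build :class:`ProteoformCluster` summaries from a clustered frame."""
    out = []
    for cid, members in frame.groupby("cluster_id"):
        out.append(ProteoformCluster(
            cluster_id=int(cid),
            consensus=assign_consensus(members),
            mass_da=float(members[mass_col].median()),
            rt_min=float(members[rt_col].median()),
            n_members=int(len(members)),
            member_index=members.index.to_numpy(),
        ))
    return out


# ---------------------------------------------------------------------------
# Roll-up and quantification matrix


def rollup_cv(members: pd.DataFrame, sample_col: str = "dataset_id"):
    """Per-sample abundance and spectral count for one cluster.

    abundance(sample) = sum over CV channels of the maximum member feature
    intensity in that channel; spectral count = number of member PSMs.
    Samples with no member are absent from the result.
    """
    with_int = members[np.isfinite(members["intensity"].astype(float))]
    per_cv = (with_int.groupby([sample_col, "cv_volts"])["intensity"].max()
              if len(with_int) else pd.Series(dtype=float))
    abundance = per_cv.groupby(level=0).sum() if len(per_cv) else \
        pd.Series(dtype=float)
    counts = members.groupby(sample_col).size()
    return abundance, counts


@dataclass
class QuantMatrix:
    """Proteoform x sample log2 abundances with design metadata."""

    abundance: pd.DataFrame          # log2 intensity, NaN = missing
    spectral_counts: pd.DataFrame    # same shape, 0 = unobserved
    row_info: pd.DataFrame           # label, gene, first_aa, last_aa, ...
    design: SampleDesign

    @property
    def labels(self) -> list:
        return list(self.abundance.index)

    def presence(self) -> pd.DataFrame:
        return self.abundance.notna()


def build_quant_matrix(frame: pd.DataFrame, design: SampleDesign,
                       sample_col: str = "dataset_id",
                       mass_col: str = "mass_recal",
                       rt_col: str = "rt_aligned") -> QuantMatrix:
    """Quantification matrix over identified clusters.

    Clusters sharing a consensus key are merged (re-rolled-up over the union
    of members, flagged).  Unidentified clusters are excluded; rows are
    labelled ``GENE_first-last[*]``, disambiguated when distinct
    modification signatures share a printed label.
    """
    clusters = summarize_clusters(frame, mass_col=mass_col, rt_col=rt_col)
    by_key: dict = {}
    n_unidentified = 0
    for cl in clusters:
        if cl.consensus is None:
            n_unidentified += 1
            continue
        by_key.setdefault(cl.consensus, []).append(cl)
    sample_ids = design.sample_ids
    abund = {}
    counts = {}
    rows = []
    label_seen: dict = {}
    n_merged = sum(1 for g in by_key.values() if len(g) > 1)
    if n_merged:
        logger.info("re-rolled %d consensus keys split across clusters",
                    n_merged)
    for key in sorted(by_key, key=format_proteoform_name):
        group = by_key[key]
        if len(group) > 1:
            logger.debug("merged %d clusters sharing consensus %s",
                         len(group), format_proteoform_name(key))
        idx = np.concatenate([cl.member_index for cl in group])
        members = frame.loc[idx]
        a, c = rollup_cv(members, sample_col=sample_col)
        label = format_proteoform_name(key)
        if label in label_seen:
            label_seen[label] += 1
            label = f"{label}#{label_seen[label]}"
        else:
            label_seen[label] = 1
        abund[label] = a
        counts[label] = c
        rows.append({
            "label": label, "gene": key.gene, "accession": key.accession,
            "first_aa": key.first_aa, "last_aa": key.last_aa,
            "modified": key.modified,
            "mod_signature": ";".join(f"{d:+.2f}@{loc}" if loc else f"{d:+.2f}"
                                      for d, loc in key.mod_signature),
            "mass_da": float(members[mass_col].median()),
            "rt_min": float(members[rt_col].median()),
            "n_clusters_merged": len(group),
        })
    row_info = pd.DataFrame(rows).set_index("label") if rows else \
        pd.DataFrame(columns=["gene"]).rename_axis("label")
    labels = list(row_info.index)
    abundance = pd.DataFrame(np.nan, index=labels, columns=sample_ids)
    spectral = pd.DataFrame(0, index=labels, columns=sample_ids, dtype=int)
    for label in labels:
        a = abund[label].reindex(sample_ids)
        abundance.loc[label] = np.log2(a.where(a > 0))
        spectral.loc[label] = counts[label].reindex(sample_ids).fillna(0)
    if n_unidentified:
        logger.info("%d unidentified clusters excluded from quantification",
                    n_unidentified)
    return QuantMatrix(abundance=abundance, spectral_counts=spectral,
                       row_info=row_info, design=design)


def top_n_by_spectral_count(qm: QuantMatrix, gene: str, n: int) -> list:
    """Proteoforms of ``gene`` ranked by median spectral count, descending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = qm.row_info.index[qm.row_info["gene"] == gene]
    if len(labels) == 0:
        return []
    med = qm.spectral_counts.loc[labels].median(axis=1)
    ranked = med.sort_index().sort_values(ascending=False, kind="mergesort")
    return list(ranked.index[:n])
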