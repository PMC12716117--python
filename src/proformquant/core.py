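"""Shared domain types for proteoform-centric analysis.

A *proteoform* is one specific molecular form of a gene product: a precursor
interval (``first_aa``..``last_aa``, 1-based inclusive, signal peptide residue
= 1) plus a set of mass modifications.  Proteoforms are referred to by gene
symbol and residue interval, e.g. the insulin B chain is ``INS_25-54``; a
trailing ``*`` marks a modified form.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("proformquant")

CONDITIONS = ("control", "treated")

#: number of decimals used when canonicalizing modification delta masses
MOD_SIGNATURE_DECIMALS = 2


@dataclass(frozen=True)
class ProteoformKey:
    """Identity of a proteoform: gene, accession, termini, and modifications.

    ``mod_signature`` is a canonicalized, sorted tuple of
    ``(delta_da rounded to 2 decimals, localization string)`` pairs so that
    float jitter in reported shifts does not split identities.
    """

    gene: str
    accession: str
    first_aa: int
    last_aa: int
    mod_signature: tuple = ()

    def __post_init__(self):
        if not (1 <= self.first_aa <= self.last_aa):
            raise ValueError(
                f"invalid residue interval {self.first_aa}-{self.last_aa}"
            )
        canon = canonical_mod_signature(self.mod_signature)
        object.__setattr__(self, "mod_signature", canon)

    @property
    def modified(self) -> bool:
        return len(self.mod_signature) > 0

    @property
    def label(self) -> str:
        return format_proteoform_name(self)


def canonical_mod_signature(mods: Iterable) -> tuple:
    """Round delta masses to 2 decimals and sort; idempotent."""
    out = []
    for m in mods:
        if isinstance(m, (tuple, list)):
            delta, loc = m[0], (m[1] if len(m) > 1 else "")
        else:
            delta, loc = m, ""
        out.append((round(float(delta), MOD_SIGNATURE_DECIMALS), str(loc)))
    return tuple(sorted(out))


@dataclass
class PsmRecord:
    """One proteoform-spectrum match from a single acquisition."""

    dataset_id: str
    scan: int
    rt_min: float
    mass_da: float
    accession: str
    gene: str
    first_aa: int
    last_aa: int
    mod_shifts_da: list = field(default_factory=list)
    evalue: float = 1.0
    is_decoy: bool = False
    intensity: float = np.nan
    cv_volts: str = ""

    def __post_init__(self):
        if self.rt_min < 0:
            raise ValueError("rt_min must be >= 0")
        if self.mass_da <= 0:
            raise ValueError("mass_da must be > 0")
        if not self.is_decoy and not (1 <= self.first_aa <= self.last_aa):
            raise ValueError("require 1 <= first_aa <= last_aa")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def key(self) -> ProteoformKey:
        return ProteoformKey(
            self.gene, self.accession, self.first_aa, self.last_aa,
            canonical_mod_signature(self.mod_shifts_da),
        )


class SampleDesign:
    """Paired sample design: donors crossed with control/treated conditions.

    Wraps a data frame with columns ``sample_id``, ``donor_id``,
    ``condition``; each (donor, condition) pair occurs at most once.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "donor_id", "condition"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["donor_id"] = frame["donor_id"].astype(str)
        bad = set(frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        if frame.duplicated(["donor_id", "condition"]).any():
            raise ValueError("a donor appears more than once per condition")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list:
        return list(self.frame["sample_id"])

    @property
    def donors(self) -> list:
        return sorted(self.frame["donor_id"].unique())

    def samples_in(self, condition: str) -> list:
        f = self.frame
        return list(f.loc[f["condition"] == condition, "sample_id"])

    def complete_pairs(self) -> list:
        """Donors with a sample in both conditions -> [(donor, control_id, treated_id)]."""
        piv = self.frame.pivot(index="donor_id", columns="condition",
                               values="sample_id")
        out = []
        for donor, row in piv.iterrows():
            if all(c in piv.columns and isinstance(row.get(c), str)
                   for c in CONDITIONS):
                out.append((donor, row["control"], row["treated"]))
        return out

    def condition_of(self, sample_id: str) -> str:
        f = self.frame
        return f.loc[f["sample_id"] == str(sample_id), "condition"].iloc[0]


# ---------------------------------------------------------------------------
# Proteoform naming


_NAME_RE = re.compile(r"^(?P<gene>[^_]+)_(?P<first>\d+)-(?P<last>\d+)(?P<star>\*?)$")


def format_proteoform_name(key: ProteoformKey, modified: bool | None = None) -> str:
    """``GENE_first-last`` with a trailing ``*`` for modified proteoforms.

    Falls back to the accession when the gene symbol is missing.
    """
    gene = key.gene
    if not gene:
        logger.warning("proteoform %s-%s has no gene symbol; using accession %s",
                       key.first_aa, key.last_aa, key.accession)
        gene = key.accession
    if modified is None:
        modified = key.modified
    star = "*" if modified else ""
    return f"{gene}_{key.first_aa}-{key.last_aa}{star}"


def parse_proteoform_name(label: str) -> tuple:
    """Inverse of :func:`format_proteoform_name` -> (gene, first, last, modified)."""
    m = _NAME_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse proteoform label {label!r}")
    return (m["gene"], int(m["first"]), int(m["last"]), m["star"] == "*")


def format_shared_terminus_group(keys: Sequence[ProteoformKey]) -> str:
    """Collapse proteoforms sharing one terminus: ``INS_57-79/80/81``.

    All keys must share the gene and exactly one terminus; the varying
    terminus positions are listed ascending, separated by ``/``.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("empty group")
    genes = {k.gene for k in keys}
    if len(genes) != 1:
        raise ValueError("group spans multiple genes")
    gene = genes.pop()
    if len(keys) == 1:
        k = keys[0]
        return f"{gene}_{k.first_aa}-{k.last_aa}"
    firsts = sorted({k.first_aa for k in keys})
    lasts = sorted({k.last_aa for k in keys})
    if len(firsts) == 1 and len(lasts) > 1:
        return f"{gene}_{firsts[0]}-" + "/".join(str(x) for x in lasts)
    if len(lasts) == 1 and len(firsts) > 1:
        return f"{gene}_" + "/".join(str(x) for x in firsts) + f"-{lasts[0]}"
    raise ValueError("keys must share exactly one terminus")


# ---------------------------------------------------------------------------
# Data completeness


def completeness_summary(presence: pd.DataFrame, n_bins: int = 10):
    """Per-proteoform fraction of samples observed, plus decile bin counts.

    Parameters
    ----------
    presence : boolean DataFrame, proteoforms x samples.

    Returns
    -------
    fractions : Series in [0, 1] indexed like ``presence``.
    bin_counts : Series of counts over ``n_bins`` equal bins of (0, 1]
        (left-open except the first bin, which includes 0).
    """
    if presence.shape[0] == 0 or presence.shape[1] == 0:
        raise ValueError("presence table must be non-empty")
    fractions = presence.astype(bool).mean(axis=1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.ceil(fractions.to_numpy() * n_bins).astype(int) - 1, 0,
                  n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    labels = [f"({edges[i]:.0%}, {edges[i + 1]:.0%}]" for i in range(n_bins)]
    return fractions, pd.Series(counts, index=labels, name="n_proteoforms")
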