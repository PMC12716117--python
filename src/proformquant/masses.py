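"""Monoisotopic mass arithmetic and delta-mass annotation.

Atomic monoisotopic masses are fixed to 5 decimals so residue and
modification masses are bit-stable across platforms.  Residue masses are
derived from elemental formulas through :func:`mono_mass`, which keeps the
whole table internally consistent.  Cysteine carries a fixed
carbamidomethyl group (iodoacetamide alkylation) by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

# monoisotopic atomic masses, Da (5 decimals)
ATOMIC_MASS = {
    "C": 12.00000,
    "H": 1.00783,
    "N": 14.00307,
    "O": 15.99491,
    "S": 31.97207,
    "P": 30.97376,
    "Fe": 55.93494,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d+)")


def parse_formula(text: str) -> dict:
    """Parse ``"O1 H-2"`` into ``{"O": 1, "H": -2}``."""
    counts: dict = {}
    stripped = text.replace(" ", "")
    pos = 0
    for m in _FORMULA_TOKEN.finditer(stripped):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2))
        pos = m.end()
    if pos != len(stripped):
        raise ValueError(f"malformed formula {text!r}")
    return counts


def mono_mass(formula) -> float:
    """Monoisotopic mass change of a signed elemental composition (Da)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for element, count in formula.items():
        try:
            total += ATOMIC_MASS[element] * count
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


# residue (= amino acid - H2O) elemental formulas, 20 canonical residues
RESIDUE_FORMULA = {
    "G": "C2H3N1O1", "A": "C3H5N1O1", "S": "C3H5N1O2", "P": "C5H7N1O1",
    "V": "C5H9N1O1", "T": "C4H7N1O2", "C": "C3H5N1O1S1", "L": "C6H11N1O1",
    "I": "C6H11N1O1", "N": "C4H6N2O2", "D": "C4H5N1O3", "Q": "C5H8N2O2",
    "K": "C6H12N2O1", "E": "C5H7N1O3", "M": "C5H9N1O1S1", "H": "C6H7N3O1",
    "F": "C9H9N1O1", "R": "C6H12N4O1", "Y": "C9H9N1O2", "W": "C11H10N2O1",
}

RESIDUE_MASS = {aa: mono_mass(f) for aa, f in RESIDUE_FORMULA.items()}
WATER_MASS = mono_mass("H2O1")
#: carbamidomethyl adduct on Cys (iodoacetamide), fixed modification
CARBAMIDOMETHYL_MASS = mono_mass("C2H3N1O1")


def theoretical_mass(sequence: str, mod_deltas=(), *,
                     fixed_cys_carbamidomethyl: bool = True) -> float:
    """Neutral monoisotopic mass of a proteoform.

    Sum of residue masses + one water, plus a fixed carbamidomethyl per
    cysteine, plus any variable modification deltas (Da).
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1}"
            ) from None
        if aa == "C" and fixed_cys_carbamidomethyl:
            total += CARBAMIDOMETHYL_MASS
    for d in mod_deltas:
        total += float(d)
    return total


# ---------------------------------------------------------------------------
# Modification delta table


@dataclass(frozen=True)
class ModDelta:
    """A named modification delta mass.

    ``delta_da`` is derived from ``formula``; ``observed_da``, if set, is an
    empirically reported shift for tentative assignments and is preferred
    when matching observed mass shifts.
    """

    name: str
    delta_da: float
    formula: str
    observed_da: float | None = None
    sites: str = ""

    def __post_init__(self):
        theo = mono_mass(self.formula)
        if abs(theo - self.delta_da) > 1e-4:
            raise ValueError(
                f"{self.name}: delta_da {self.delta_da} differs from formula "
                f"mass {theo:.5f} by more than 1e-4 Da"
            )

    @property
    def match_da(self) -> float:
        return self.delta_da if self.observed_da is None else self.observed_da


def load_mod_table(path=None) -> list:
    """Load a modification table TSV (packaged default when ``path`` is None)."""
    if path is None:
        ref = resources.files("proformquant.data") / "modifications.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        observed = row.get("observed_da", "").strip()
        out.append(ModDelta(
            name=row["name"],
            delta_da=float(row["delta_da"]),
            formula=row["formula"],
            observed_da=float(observed) if observed else None,
            sites=row.get("sites", ""),
        ))
    return out


def annotate_shift(observed_shift_da: float, table, tol_da: float = 0.1):
    """Best-matching table entry for an observed mass shift, or None.

    Minimizes ``|observed - entry|`` subject to ``<= tol_da``; ties broken
    by smaller absolute error, then lexicographic name.
    """
    if tol_da < 0:
        raise ValueError("tol_da must be >= 0")
    best = None
    best_err = None
    for entry in table:
        err = abs(observed_shift_da - entry.match_da)
        if err > tol_da:
            continue
        if best is None or err < best_err - 1e-12 or (
                abs(err - best_err) <= 1e-12 and entry.name < best.name):
            best, best_err = entry, err
    return best
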