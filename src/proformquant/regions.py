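"""Prohormone processing-product region maps and containment annotation.

Prohormones (proinsulin, proglucagon, chromogranins, ...) are proteolytically
matured into named products occupying defined residue intervals of the
precursor.  A proteoform is annotated with the *smallest* named region that
fully contains its interval (the most specific product, e.g. 53-81 maps to
glucagon, not oxyntomodulin); proteoforms overlapping regions without being
contained in one are annotated ``"Other"``; genes absent from the map are
``"unmapped"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class Region:
    name: str
    first_aa: int
    last_aa: int

    def contains(self, first: int, last: int) -> bool:
        return self.first_aa <= first and last <= self.last_aa

    def overlaps(self, first: int, last: int) -> bool:
        return first <= self.last_aa and self.first_aa <= last

    @property
    def span(self) -> int:
        return self.last_aa - self.first_aa + 1


class RegionMap:
    """gene -> list of named closed residue intervals."""

    def __init__(self, entries=None):
        self._by_gene: dict = {}
        for gene, name, first, last in (entries or []):
            self.add(gene, name, first, last)

    def add(self, gene: str, name: str, first_aa: int, last_aa: int) -> None:
        if not (1 <= first_aa <= last_aa):
            raise ValueError(f"{gene}/{name}: inverted interval "
                             f"{first_aa}-{last_aa}")
        regions = self._by_gene.setdefault(gene, [])
        if any(r.name == name for r in regions):
            raise ValueError(f"duplicate region name {name!r} for {gene}")
        regions.append(Region(name, first_aa, last_aa))

    def genes(self) -> list:
        return sorted(self._by_gene)

    def regions_of(self, gene: str) -> list:
        return list(self._by_gene.get(gene, []))

    def get(self, gene: str, name: str) -> Region:
        for r in self._by_gene.get(gene, []):
            if r.name == name:
                return r
        raise KeyError(f"unknown region {name!r} for gene {gene!r}")

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_gene.values())


def annotate_region(key, region_map: RegionMap) -> str:
    """Region label for a proteoform key (``gene``/``first_aa``/``last_aa``).

    Smallest containing region wins; overlap without unique containment is
    ``"Other"``; a gene missing from the map is ``"unmapped"``.
    """
    gene, first, last = key.gene, key.first_aa, key.last_aa
    if gene not in region_map:
        return "unmapped"
    containing = [r for r in region_map.regions_of(gene)
                  if r.contains(first, last)]
    if containing:
        best = min(containing, key=lambda r: (r.span, r.name))
        return best.name
    return "Other"


def load_region_map(path=None) -> RegionMap:
    """Load a region TSV (gene, region, first_aa, last_aa); packaged default
    when ``path`` is None."""
    if path is None:
        ref = resources.files("proformquant.data") / "prohormone_regions.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rmap = RegionMap()
    header = None
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.rstrip("\n").split("\t")
        if header is None:
            header = fields
            expected = ["gene", "region", "first_aa", "last_aa"]
            if header[:4] != expected:
                raise ValueError(f"region map header must be {expected}")
            continue
        row = dict(zip(header, fields))
        try:
            rmap.add(row["gene"], row["region"],
                     int(row["first_aa"]), int(row["last_aa"]))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"region map line {lineno}: {exc}") from None
    return rmap
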