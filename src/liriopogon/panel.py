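"""Reference haplotype panel for the rbcL barcode plus the ITS diagnostic triplet.

The panel is shipped as a JSON fixture (``data/panel.json``) holding the locus
reference sequences, the informative SNP positions, one row of bases per named
haplotype (Type 1 .. Type 6), the genus-diagnostic position, and the three-SNP
ITS triplet that separates *O. planiscapus* from *O. bodinieri*.  Everything
the rest of the pipeline knows about the marker system comes from this file,
so :func:`load_panel` validates it aggressively and fails loudly.

Coordinates are 1-based indices into the packaged locus reference sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "PanelError",
    "SNPPosition",
    "Haplotype",
    "ITSTriplet",
    "HaplotypePanel",
    "PanelDiff",
    "load_panel",
    "load_default_panel",
    "diff_from_consensus",
]

IUPAC_CODES = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
STRICT_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a panel file violates a structural invariant."""


@dataclass(frozen=True)
class SNPPosition:
    """An informative alignment column in a locus reference."""

    locus: str
    position: int  # 1-based
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PanelError(f"{self.locus}:{self.position}: position must be >= 1")
        if not self.alleles <= STRICT_BASES:
            bad = sorted(self.alleles - STRICT_BASES)
            raise PanelError(
                f"{self.locus}:{self.position}: non-ACGT allele(s) {bad}"
            )
        if len(self.alleles) < 2:
            raise PanelError(
                f"{self.locus}:{self.position}: needs >=2 alleles, got {sorted(self.alleles)}"
            )


@dataclass(frozen=True)
class Haplotype:
    """A named combination of bases over the panel positions."""

    name: str
    bases: Mapping[int, str]  # position -> base
    taxa: tuple[str, ...]
    low_confidence: bool = False

    def row(self, positions: Iterable[SNPPosition]) -> str:
        return "".join(self.bases[p.position] for p in positions)


@dataclass(frozen=True)
class ITSTriplet:
    """Three ITS SNPs whose joint pattern separates two close species.

    ``patterns`` maps a pattern key (e.g. ``"planiscapus"``) to the expected
    base at each of the three positions; ``species`` maps the same keys to the
    full species name the pattern supports.
    """

    locus: str
    positions: tuple[int, int, int]
    patterns: Mapping[str, Mapping[int, str]]
    species: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.positions) != 3:
            raise PanelError("ITS triplet must have exactly three positions")
        keys = list(self.patterns)
        if len(keys) != 2:
            raise PanelError("ITS triplet needs exactly two allele patterns")
        a, b = (self.patterns[k] for k in keys)
        for pos in self.positions:
            if pos not in a or pos not in b:
                raise PanelError(f"ITS triplet pattern missing position {pos}")
            if a[pos] == b[pos]:
                raise PanelError(
                    f"ITS triplet patterns do not differ at position {pos}"
                )


@dataclass(frozen=True)
class PanelDiff:
    """One difference between a haplotype and the consensus haplotype."""

    position: int
    consensus_base: str
    haplotype_base: str
    unique: bool  # no other haplotype carries this derived base here


@dataclass(frozen=True)
class HaplotypePanel:
    references: Mapping[str, str]  # locus -> reference sequence
    regions: Mapping[str, Mapping[str, tuple[int, int]]]  # locus -> name -> (start, end)
    positions: tuple[SNPPosition, ...]
    haplotypes: tuple[Haplotype, ...]
    consensus: str
    genus_position: int
    genus_locus: str
    genus_alleles: Mapping[str, str]  # base -> genus
    its_triplet: ITSTriplet
    raw: dict = field(repr=False, default_factory=dict)

    # -- lookups -------------------------------------------------------------
    def haplotype(self, name: str) -> Haplotype:
        for hap in self.haplotypes:
            if hap.name == name:
                return hap
        raise KeyError(f"unknown haplotype {name!r}")

    @property
    def haplotype_names(self) -> tuple[str, ...]:
        return tuple(h.name for h in self.haplotypes)

    def positions_for_locus(self, locus: str) -> tuple[SNPPosition, ...]:
        return tuple(p for p in self.positions if p.locus == locus)

    def positions_in_region(self, locus: str, region: str) -> tuple[SNPPosition, ...]:
        start, end = self.regions[locus][region]
        return tuple(
            p for p in self.positions if p.locus == locus and start <= p.position <= end
        )

    def informative_positions(self) -> tuple[SNPPosition, ...]:
        """Positions at which at least two haplotype rows differ."""
        out = []
        for pos in self.positions:
            observed = {h.bases[pos.position] for h in self.haplotypes}
            if len(observed) >= 2:
                out.append(pos)
        return tuple(out)

    def taxa_for(self, name: str) -> tuple[str, ...]:
        return self.haplotype(name).taxa

    def haplotype_for_species(self, species: str) -> Haplotype:
        for hap in self.haplotypes:
            if species in hap.taxa:
                return hap
        raise KeyError(f"species {species!r} not present in panel taxa map")


def _validate(panel: HaplotypePanel) -> None:
    pos_ids = [p.position for p in panel.positions]
    if len(set(pos_ids)) != len(pos_ids):
        raise PanelError("duplicate panel positions")
    for pos in panel.positions:
        ref = panel.references.get(pos.locus)
        if ref is None:
            raise PanelError(f"position references unknown locus {pos.locus!r}")
        if pos.position > len(ref):
            raise PanelError(
                f"{pos.locus}:{pos.position} lies outside the reference (len {len(ref)})"
            )

    names = [h.name for h in panel.haplotypes]
    if len(set(names)) != len(names):
        raise PanelError("duplicate haplotype names")
    rows: dict[str, str] = {}
    for hap in panel.haplotypes:
        if not hap.taxa:
            raise PanelError(f"{hap.name}: empty taxon list")
        for pos in panel.positions:
            base = hap.bases.get(pos.position)
            if base is None:
                raise PanelError(f"{hap.name}: missing base at position {pos.position}")
            if base not in STRICT_BASES:
                raise PanelError(f"{hap.name}@{pos.position}: non-ACGT base {base!r}")
            if base not in pos.alleles:
                raise PanelError(
                    f"{hap.name}@{pos.position}: base {base} not in declared alleles"
                )
        row = hap.row(panel.positions)
        if row in rows:
            raise PanelError(
                f"haplotypes {rows[row]} and {hap.name} are identical across all positions"
            )
        rows[row] = hap.name

    if panel.consensus not in names:
        raise PanelError(f"consensus haplotype {panel.consensus!r} not in panel")

    # Genus rule: exactly one haplotype group per genus allele at the genus SNP.
    gpos = panel.genus_position
    if gpos not in {p.position for p in panel.positions_for_locus(panel.genus_locus)}:
        raise PanelError(f"genus position {gpos} is not a panel position")
    for hap in panel.haplotypes:
        base = hap.bases[gpos]
        if base not in panel.genus_alleles:
            raise PanelError(
                f"{hap.name}@{gpos}: base {base} has no genus assignment"
            )
        genus = panel.genus_alleles[base]
        for taxon in hap.taxa:
            if not taxon.split()[0] == genus:
                raise PanelError(
                    f"{hap.name}: taxon {taxon!r} conflicts with genus SNP ({genus})"
                )

    # Every declared position must be informative (>=2 rows differ there).
    informative = {p.position for p in panel.informative_positions()}
    non_informative = [p.position for p in panel.positions if p.position not in informative]
    if non_informative:
        raise PanelError(f"non-informative panel positions: {non_informative}")

    # Triplet reference bases must be in range.
    trip = panel.its_triplet
    ref = panel.references.get(trip.locus)
    if ref is None:
        raise PanelError(f"triplet references unknown locus {trip.locus!r}")
    for pos in trip.positions:
        if not 1 <= pos <= len(ref):
            raise PanelError(f"triplet position {pos} outside {trip.locus} reference")


def _panel_from_dict(doc: dict) -> HaplotypePanel:
    try:
        loci = doc["loci"]
        references = {name: spec["reference"].upper() for name, spec in loci.items()}
        regions = {
            name: {r: tuple(bounds) for r, bounds in spec.get("regions", {}).items()}
            for name, spec in loci.items()
        }
        positions = tuple(
            SNPPosition(
                locus=p["locus"],
                position=int(p["position"]),
                alleles=frozenset(p["alleles"]),
            )
            for p in doc["positions"]
        )
        haplotypes = tuple(
            Haplotype(
                name=h["name"],
                bases={int(k): v.upper() for k, v in h["bases"].items()},
                taxa=tuple(h["taxa"]),
                low_confidence=bool(h.get("low_confidence", False)),
            )
            for h in doc["haplotypes"]
        )
        gp = doc["genus_position"]
        trip = doc["its_triplet"]
        triplet = ITSTriplet(
            locus=trip.get("locus", "ITS"),
            positions=tuple(int(p) for p in trip["positions"]),
            patterns={
                key: {int(p): b.upper() for p, b in pat.items()}
                for key, pat in trip["patterns"].items()
            },
            species=dict(trip["species"]),
        )
    except KeyError as exc:  # pragma: no cover - malformed fixture
        raise PanelError(f"panel file missing field {exc}") from exc

    panel = HaplotypePanel(
        references=references,
        regions=regions,
        positions=positions,
        haplotypes=haplotypes,
        consensus=doc["consensus"],
        genus_position=int(gp["position"]),
        genus_locus=gp["locus"],
        genus_alleles={b.upper(): g for b, g in gp["genus_alleles"].items()},
        its_triplet=triplet,
        raw=doc,
    )
    _validate(panel)
    return panel


def load_panel(path) -> HaplotypePanel:
    """Load and validate a panel file; invariant violations are hard errors."""
    with open(path) as fh:
        doc = json.load(fh)
    return _panel_from_dict(doc)


def load_default_panel() -> HaplotypePanel:
    """Load the panel shipped with the package."""
    text = resources.files("liriopogon.data").joinpath("panel.json").read_text()
    return _panel_from_dict(json.loads(text))


def save_panel(panel: HaplotypePanel, path) -> None:
    """Serialize a panel back to its JSON form (round-trips with load_panel)."""
    doc = panel.raw or _panel_to_dict(panel)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _panel_to_dict(panel: HaplotypePanel) -> dict:
    return {
        "format_version": 1,
        "loci": {
            locus: {"reference": seq, "regions": {r: list(b) for r, b in panel.regions.get(locus, {}).items()}}
            for locus, seq in panel.references.items()
        },
        "positions": [
            {"locus": p.locus, "position": p.position, "alleles": sorted(p.alleles)}
            for p in panel.positions
        ],
        "haplotypes": [
            {
                "name": h.name,
                "bases": {str(k): v for k, v in sorted(h.bases.items())},
                "taxa": list(h.taxa),
                "low_confidence": h.low_confidence,
            }
            for h in panel.haplotypes
        ],
        "consensus": panel.consensus,
        "genus_position": {
            "locus": panel.genus_locus,
            "position": panel.genus_position,
            "genus_alleles": dict(panel.genus_alleles),
        },
        "its_triplet": {
            "locus": panel.its_triplet.locus,
            "positions": list(panel.its_triplet.positions),
            "patterns": {
                k: {str(p): b for p, b in pat.items()}
                for k, pat in panel.its_triplet.patterns.items()
            },
            "species": dict(panel.its_triplet.species),
        },
    }


def diff_from_consensus(panel: HaplotypePanel, name: str) -> list[PanelDiff]:
    """Differences of the named haplotype from the consensus haplotype.

    A difference is *unique* when no other haplotype in the panel carries the
    same derived base at that position.
    """
    hap = panel.haplotype(name)  # raises KeyError for unknown names
    cons = panel.haplotype(panel.consensus)
    diffs = []
    for pos in panel.positions:
        cbase, hbase = cons.bases[pos.position], hap.bases[pos.position]
        if hbase == cbase:
            continue
        unique = not any(
            other.name != name and other.bases[pos.position] == hbase
            for other in panel.haplotypes
        )
        diffs.append(PanelDiff(pos.position, cbase, hbase, unique))
    return diffs
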