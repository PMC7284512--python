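"""Combine rbcL haplotype, ITS clade and ITS triplet evidence into a final
per-accession identification, and tally outcomes over a collection.

The rule table encodes a two-tier scheme: the rbcL haplotype fixes the genus
and, where a haplotype is species-diagnostic, the species; haplotypes shared
between species are resolved by the ITS clade; within the bodinieri/
planiscapus group the three-SNP ITS triplet outranks tree placement when the
two disagree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .haplotyper import UNDETERMINED, HaplotypeCall
from .panel import HaplotypePanel
from .phylogeny import CladeAssignment

__all__ = [
    "Identification",
    "CollectionReport",
    "DEFAULT_SYNONYMS",
    "CLADE_SPECIES",
    "normalize_label",
    "identify",
    "status_of",
    "report",
]

# accepted-name synonymy applied before any label comparison
DEFAULT_SYNONYMS: dict[str, str] = {
    "Liriope exiliflora": "Liriope muscari",
    "Ophiopogon wallichianus": "Ophiopogon japonicus",
}

_ABBREV = {"L.": "Liriope", "O.": "Ophiopogon"}

# species supported by each ITS clade label on its own
CLADE_SPECIES: dict[str, str] = {
    "Liriope-muscari": "Liriope muscari",
    "Liriope-spicata": "Liriope spicata",
    "B2": "Ophiopogon japonicus (II)",
    "B3a": "Ophiopogon planiscapus",
    "B3b": "Ophiopogon bodinieri",
    "jaburan-branch": "Ophiopogon jaburan",
}

GENUS_ONLY_EPITHETS = {"sp.", "spp.", "sp", "spp", "species", ""}


def normalize_label(label: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Expand genus abbreviations and apply the accepted-synonym table.

    Unknown labels pass through unchanged (modulo abbreviation expansion and
    whitespace cleanup); cultivar epithets in quotes are preserved.
    """
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    words = label.strip().split()
    if words and words[0] in _ABBREV:
        words[0] = _ABBREV[words[0]]
    cleaned = " ".join(words)
    core = _species_core(cleaned)
    if core in table:
        rest = cleaned[len(core):].strip()
        return table[core] + (f" {rest}" if rest else "")
    return cleaned


def _species_core(name: str) -> str:
    """Genus + epithet, ignoring cultivar quotes and subgroup qualifiers."""
    words = [w for w in name.strip().split() if not w.startswith(("'", '"', "("))]
    return " ".join(words[:2])


def _genus_of(name: str) -> str:
    words = name.strip().split()
    return _ABBREV.get(words[0], words[0]) if words else ""


def _is_genus_only(name: str) -> bool:
    words = name.strip().split()
    return len(words) < 2 or words[1].lower() in GENUS_ONLY_EPITHETS


@dataclass(frozen=True)
class Identification:
    accession_id: str
    original_label: str
    normalized_label: str
    genus: str  # Ophiopogon | Liriope | undetermined
    species: str  # full name, species-group name, or "undetermined"
    status: str  # confirmed | species_misid | genus_misid | newly_identified | undetermined
    haplotype: HaplotypeCall | None = None
    clade: CladeAssignment | None = None
    triplet: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CollectionReport:
    identifications: tuple[Identification, ...]
    tallies: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.tallies
        if t["confirmed"] + t["newly_identified"] + t["misidentified"] + t["undetermined"] != t["total"]:
            raise ValueError("tally conservation violated")
        if t["genus_misid"] + t["species_misid"] != t["misidentified"]:
            raise ValueError("misidentification level tallies violated")

    def to_json(self) -> str:
        doc = {
            "tallies": dict(self.tallies),
            "accessions": [
                {
                    "accession_id": i.accession_id,
                    "original_label": i.original_label,
                    "normalized_label": i.normalized_label,
                    "final_genus": i.genus,
                    "final_species": i.species,
                    "status": i.status,
                    "rbcl_haplotype": i.haplotype.best if i.haplotype else None,
                    "rbcl_distance": i.haplotype.distance if i.haplotype else None,
                    "genus_snp": i.haplotype.genus if i.haplotype else None,
                    "its_clade": i.clade.label if i.clade else None,
                    "its_support": i.clade.support if i.clade else None,
                    "triplet": i.triplet,
                    "flags": list(i.flags),
                }
                for i in self.identifications
            ],
        }
        return json.dumps(doc, indent=1)

    def to_tsv(self) -> str:
        cols = [
            "accession_id", "original_label", "normalized_label", "rbcl_haplotype",
            "rbcl_distance", "genus_snp", "its_clade", "its_support", "triplet",
            "final_identity", "status", "flags",
        ]
        lines = ["\t".join(cols)]
        for i in self.identifications:
            row = [
                i.accession_id,
                i.original_label,
                i.normalized_label,
                (i.haplotype.best or "|".join(i.haplotype.ties) or "") if i.haplotype else "",
                str(i.haplotype.distance) if i.haplotype and i.haplotype.distance is not None else "",
                i.haplotype.genus if i.haplotype else "",
                i.clade.label if i.clade else "",
                f"{i.clade.support:.0f}" if i.clade and i.clade.support is not None else "",
                i.triplet,
                i.species if i.species != UNDETERMINED else i.genus,
                i.status,
                ";".join(i.flags),
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def identify(
    haplotype: HaplotypeCall | None,
    clade: CladeAssignment | None,
    triplet: str,
    panel: HaplotypePanel,
) -> tuple[str, str, tuple[str, ...]]:
    """Apply the two-tier rule table; returns (genus, species, flags).

    ``triplet`` is the pattern key ("planiscapus"/"bodinieri", optionally
    suffixed "(partial)"), or ""/"undetermined" when not evaluated.
    """
    flags: list[str] = []
    clade_label = clade.label if clade is not None else "unassigned"
    clade_species = CLADE_SPECIES.get(clade_label)
    trip_key = triplet.split("(")[0].strip() if triplet else ""
    trip_partial = "(partial)" in triplet
    trip_species = panel.its_triplet.species.get(trip_key)

    hap_name = None
    if haplotype is not None and haplotype.flag in ("exact", "near"):
        hap_name = haplotype.best
        if haplotype.flag == "near":
            flags.append("haplotype_near_match")
    elif haplotype is not None and haplotype.flag == "ambiguous":
        flags.append("haplotype_ambiguous:" + "|".join(haplotype.ties))

    genus = haplotype.genus if haplotype is not None else UNDETERMINED

    if hap_name is None:
        # single-locus (ITS-only) call
        if clade_species is None and trip_species is None:
            return (UNDETERMINED if genus == UNDETERMINED else genus, UNDETERMINED,
                    tuple(flags + (["undetermined"] if genus == UNDETERMINED else ["single_locus"])))
        flags.append("single_locus")
        if clade_label in ("B3a", "B3b") and trip_species is not None:
            species = trip_species
            if CLADE_SPECIES[clade_label] != trip_species:
                flags.append("triplet_overrides_clade")
        else:
            species = clade_species if clade_species is not None else trip_species
        return _genus_of(species), species, tuple(flags)

    taxa = panel.taxa_for(hap_name)
    hap_genus = _genus_of(taxa[0])
    if genus != UNDETERMINED and genus != hap_genus:
        flags.append("genus_snp_conflicts_haplotype")
    genus = hap_genus

    if hap_name == "Type 6":
        if clade_species is not None and _genus_of(clade_species) == "Liriope":
            species = clade_species
        else:
            species = "Liriope sp."
            flags.append("species_unresolved")
            if clade_species is not None:
                flags.append("locus_discordance")
        return genus, species, tuple(flags)

    if hap_name == "Type 1":
        if clade_label not in ("B2", "unassigned"):
            flags.append("locus_discordance")
        return genus, "Ophiopogon japonicus (I)", tuple(flags)

    if hap_name == "Type 5":
        if clade_label not in ("jaburan-branch", "unassigned"):
            flags.append("locus_discordance")
        return genus, "Ophiopogon jaburan", tuple(flags)

    if hap_name == "Type 3":
        if trip_key == "planiscapus":
            if trip_partial:
                flags.append("triplet_partial")
        else:
            flags.append("triplet_uncorroborated")
        if clade_label == "B3b":
            flags.append("triplet_overrides_clade")
        return genus, "Ophiopogon planiscapus", tuple(flags)

    if hap_name == "Type 2":
        if clade_label == "B2":
            return genus, "Ophiopogon japonicus (II)", tuple(flags)
        if trip_key == "bodinieri":
            if trip_partial:
                flags.append("triplet_partial")
            if clade_label == "B3a":
                flags.append("triplet_overrides_clade")
            return genus, "Ophiopogon bodinieri", tuple(flags)
        if trip_key == "planiscapus":
            flags.append("haplotype_triplet_conflict")
            return genus, "Ophiopogon planiscapus", tuple(flags)
        if clade_species is not None and _genus_of(clade_species) == "Ophiopogon":
            flags.append("triplet_undetermined")
            return genus, clade_species, tuple(flags)
        flags.append("species_unresolved")
        return genus, "Ophiopogon sp. (Type 2 group)", tuple(flags)

    # Type 4 and any other panel row: taxa straight from the panel
    hap = panel.haplotype(hap_name)
    if hap.low_confidence:
        flags.append("low_confidence_haplotype")
    species = taxa[0] if len(taxa) == 1 else " / ".join(taxa)
    return genus, species, tuple(flags)


def status_of(
    genus: str,
    species: str,
    normalized_label: str,
) -> str:
    """Compare the molecular identity with the (normalized) original label.

    Genus disagreement wins over everything; genus-only labels with a resolved
    species are newly identified; otherwise species agreement (ignoring
    cultivar epithets and subgroup qualifiers) means confirmed.
    """
    if genus == UNDETERMINED or species == UNDETERMINED:
        return "undetermined"
    label_genus = _genus_of(normalized_label)
    if label_genus and label_genus != genus:
        return "genus_misid"
    if _is_genus_only(normalized_label):
        if _is_genus_only(species):
            return "undetermined"
        return "newly_identified"
    if _species_core(species) == _species_core(normalized_label):
        return "confirmed"
    if _is_genus_only(species):
        return "undetermined"
    return "species_misid"


def report(identifications: Iterable[Identification]) -> CollectionReport:
    idents = tuple(identifications)
    if not idents:
        raise ValueError("cannot report on an empty collection")
    tallies = {
        "total": len(idents),
        "confirmed": sum(i.status == "confirmed" for i in idents),
        "newly_identified": sum(i.status == "newly_identified" for i in idents),
        "misidentified": sum(i.status in ("genus_misid", "species_misid") for i in idents),
        "genus_misid": sum(i.status == "genus_misid" for i in idents),
        "species_misid": sum(i.status == "species_misid" for i in idents),
        "undetermined": sum(i.status == "undetermined" for i in idents),
    }
    for genus in ("Liriope", "Ophiopogon"):
        members = [i for i in idents if _genus_of(i.normalized_label) == genus]
        tallies[f"{genus.lower()}_labelled"] = len(members)
        tallies[f"{genus.lower()}_confirmed"] = sum(
            i.status == "confirmed" for i in members
        )
    return CollectionReport(identifications=idents, tallies=tallies)
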