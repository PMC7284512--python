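"""Call genus and rbcL haplotype from a query's bases at the panel positions.

The genus call reads the single genus-diagnostic SNP (G -> Ophiopogon,
A -> Liriope at rbcL 431); the haplotype call is a nearest-row match by
Hamming distance over the unambiguous panel positions.  An IUPAC ambiguity
code whose base set contains the haplotype base counts as a match; a gap or
missing position counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import seqio
from .panel import HaplotypePanel, IUPAC_CODES
from .seqio import GAP, SeqRecord

__all__ = ["SNPProfile", "HaplotypeCall", "extract_profile", "call_genus", "call_haplotype"]

UNDETERMINED = "undetermined"
MISSING = "."  # panel position not covered by the query


@dataclass(frozen=True)
class SNPProfile:
    """A query's bases at the panel positions (in panel order)."""

    accession_id: str
    positions: tuple[int, ...]
    bases: tuple[str, ...]  # ACGT, IUPAC code, GAP ('-') or MISSING ('.')
    n_ambiguous: int  # positions that are not a plain ACGT base

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.bases):
            raise ValueError("profile positions and bases differ in length")

    def base_at(self, position: int) -> str:
        return self.bases[self.positions.index(position)]


@dataclass(frozen=True)
class HaplotypeCall:
    best: str | None
    distance: int | None
    ties: tuple[str, ...] = ()
    genus: str = UNDETERMINED
    flag: str = "fail"  # exact | near | ambiguous | fail
    deltas: tuple[int, ...] = field(default=())  # positions disagreeing with best

    def __post_init__(self) -> None:
        if self.distance == 0 and self.flag not in ("exact", "ambiguous"):
            raise ValueError("zero distance must be flagged exact")
        if len(self.ties) > 1 and self.flag != "ambiguous":
            raise ValueError("ties present but flag is not ambiguous")


def extract_profile(
    record: SeqRecord,
    panel: HaplotypePanel,
    locus: str = "rbcL",
    *,
    min_identity: float = 0.70,
) -> SNPProfile:
    """Align the query to the locus reference and read the panel positions.

    Panel positions outside the aligned span (partial amplicons) are marked
    missing rather than deleted.
    """
    reference = SeqRecord(id=f"{locus}_reference", seq=panel.references[locus])
    cmap = seqio.align_to_reference(record, reference, min_identity=min_identity)
    positions = panel.positions_for_locus(locus)

    covered = cmap.ref_to_query > 0
    first = int(covered.argmax()) + 1 if covered.any() else 0
    last = len(covered) - int(covered[::-1].argmax()) if covered.any() else -1

    bases = []
    for pos in positions:
        if not first <= pos.position <= last:
            bases.append(MISSING)
            continue
        bases.append(seqio.base_at(cmap, record, pos.position))
    n_ambiguous = sum(1 for b in bases if b not in "ACGT")
    return SNPProfile(
        accession_id=record.id,
        positions=tuple(p.position for p in positions),
        bases=tuple(bases),
        n_ambiguous=n_ambiguous,
    )


def call_genus(profile: SNPProfile, panel: HaplotypePanel) -> str:
    """Genus from the diagnostic SNP alone; anything unclear is undetermined."""
    try:
        base = profile.base_at(panel.genus_position)
    except ValueError:
        return UNDETERMINED
    return panel.genus_alleles.get(base, UNDETERMINED)


def _site_matches(observed: str, expected: str) -> bool:
    if observed in (GAP, MISSING):
        return False
    codes = IUPAC_CODES.get(observed)
    if codes is None:
        return False
    return expected in codes


def call_haplotype(
    profile: SNPProfile,
    panel: HaplotypePanel,
    max_distance: int = 1,
) -> HaplotypeCall:
    """Nearest panel haplotype by Hamming distance over the panel positions.

    Ambiguity codes compatible with the haplotype base count as matches; gaps
    and uncovered positions count as mismatches.  Calls farther than
    ``max_distance`` from every row are flagged ``fail``; equally-near rows
    produce an ``ambiguous`` call listing every tied haplotype.
    """
    genus = call_genus(profile, panel)
    usable = sum(1 for b in profile.bases if b not in (GAP, MISSING) and b in IUPAC_CODES)
    if usable == 0:
        return HaplotypeCall(best=None, distance=None, genus=genus, flag="fail")

    distances: dict[str, int] = {}
    mismatch_sites: dict[str, tuple[int, ...]] = {}
    for hap in panel.haplotypes:
        bad = tuple(
            pos
            for pos, base in zip(profile.positions, profile.bases)
            if not _site_matches(base, hap.bases[pos])
        )
        distances[hap.name] = len(bad)
        mismatch_sites[hap.name] = bad

    dmin = min(distances.values())
    ties = tuple(h.name for h in panel.haplotypes if distances[h.name] == dmin)
    best = ties[0]
    if dmin > max_distance:
        return HaplotypeCall(
            best=None, distance=dmin, ties=(), genus=genus, flag="fail"
        )
    if len(ties) > 1:
        flag = "ambiguous"
    elif dmin == 0:
        flag = "exact"
    else:
        flag = "near"
    return HaplotypeCall(
        best=best if len(ties) == 1 else None,
        distance=dmin,
        ties=ties if len(ties) > 1 else (),
        genus=genus,
        flag=flag,
        deltas=mismatch_sites[best],
    )
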