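"""Seeded synthetic two-locus collections for end-to-end testing.

Every accession is realized as an rbcL amplicon carrying one panel haplotype
and an ITS amplicon carrying one clade signature plus a diagnostic-triplet
pattern.  Backbones are the packaged locus references; each ITS clade gets a
private set of marker substitutions (~2.5% between any two clades) so that
neighbor joining separates clades with full support at zero noise.

A packaged truth manifest reconstructs a 73-accession two-genus collection,
with per-accession original labels and true identities; rows whose labels are
not individually attested are filled so the category totals come out exactly
and carry ``source=reconstructed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .decision import _genus_of, normalize_label, status_of
from .panel import HaplotypePanel
from .seqio import SeqRecord

__all__ = [
    "GeneratorConfig",
    "CladeModel",
    "make_reference_set",
    "generate_accession",
    "load_truth_manifest",
    "validate_truth_manifest",
    "reconstruct_collection",
]

CLADES = ("Liriope-muscari", "Liriope-spicata", "B2", "B3a", "B3b", "jaburan-branch")

# default (haplotype, clade, triplet) signature per true species
SPECIES_SIGNATURES: dict[str, tuple[str, str, str]] = {
    "Liriope muscari": ("Type 6", "Liriope-muscari", ""),
    "Liriope spicata": ("Type 6", "Liriope-spicata", ""),
    "Ophiopogon japonicus (I)": ("Type 1", "B2", ""),
    "Ophiopogon japonicus (II)": ("Type 2", "B2", ""),
    "Ophiopogon bodinieri": ("Type 2", "B3b", "bodinieri"),
    "Ophiopogon planiscapus": ("Type 3", "B3a", "planiscapus"),
    "Ophiopogon jaburan": ("Type 5", "jaburan-branch", ""),
    "Ophiopogon longifolius": ("Type 4", "jaburan-branch", ""),
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    substitution_rate: float = 0.0
    ambiguity_rate: float = 0.0
    indel_rate: float = 0.0
    protect_diagnostic_positions: bool = True

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "ambiguity_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2], got {rate}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class CladeModel:
    """Per-clade ITS backbone plus the positions that define it."""

    clade: str
    backbone: str
    marker_positions: tuple[int, ...]  # 1-based, private to this clade
    references: tuple[SeqRecord, ...] = field(default=())


def _mutate_at(seq: str, position: int, rng: np.random.Generator) -> str:
    alternatives = [b for b in "ACGT" if b != seq[position - 1]]
    return seq[: position - 1] + str(rng.choice(alternatives)) + seq[position:]


def make_reference_set(
    panel: HaplotypePanel,
    seed: int,
    *,
    markers_per_clade: int = 15,
    refs_per_clade: int = 2,
) -> tuple[dict[str, str], dict[str, CladeModel]]:
    """Deterministic per-haplotype rbcL sequences and per-clade ITS references.

    Returns ``(rbcl_by_haplotype, clade_models)``.  Each clade backbone is the
    packaged ITS reference with ``markers_per_clade`` private substitutions
    (disjoint across clades, avoiding the triplet positions) and the triplet
    pattern appropriate for the clade; reference replicas beyond the first add
    two private substitutions each so references are distinguishable.
    """
    rng = np.random.default_rng(seed)

    rbcl_ref = panel.references["rbcL"]
    rbcl: dict[str, str] = {}
    for hap in panel.haplotypes:
        seq = list(rbcl_ref)
        for pos, base in hap.bases.items():
            seq[pos - 1] = base
        rbcl[hap.name] = "".join(seq)

    its_ref = panel.references[panel.its_triplet.locus]
    triplet = panel.its_triplet
    forbidden = set(triplet.positions)
    pool = [p for p in range(1, len(its_ref) + 1) if p not in forbidden]
    need = len(CLADES) * (markers_per_clade + 2 * (refs_per_clade - 1))
    chosen = rng.choice(len(pool), size=need, replace=False)
    chosen_iter = iter(int(pool[i]) for i in chosen)

    clade_models: dict[str, CladeModel] = {}
    for clade in CLADES:
        markers = tuple(sorted(next(chosen_iter) for _ in range(markers_per_clade)))
        backbone = its_ref
        for pos in markers:
            backbone = _mutate_at(backbone, pos, rng)
        # triplet pattern: B3a carries the planiscapus alleles, all others bodinieri
        pattern_key = "planiscapus" if clade == "B3a" else "bodinieri"
        for pos, base in triplet.patterns[pattern_key].items():
            backbone = backbone[: pos - 1] + base + backbone[pos:]
        refs = [SeqRecord(id=f"ref_{clade}_1", seq=backbone,
                          description=f"ref_{clade}_1 clade={clade}")]
        extra_positions: list[int] = list(markers)
        for k in range(2, refs_per_clade + 1):
            variant = backbone
            for _ in range(2):
                pos = next(chosen_iter)
                extra_positions.append(pos)
                variant = _mutate_at(variant, pos, rng)
            refs.append(SeqRecord(id=f"ref_{clade}_{k}", seq=variant,
                                  description=f"ref_{clade}_{k} clade={clade}"))
        clade_models[clade] = CladeModel(
            clade=clade,
            backbone=backbone,
            marker_positions=tuple(sorted(extra_positions)),
            references=tuple(refs),
        )
    return rbcl, clade_models


def _apply_noise(
    seq: str,
    rng: np.random.Generator,
    config: GeneratorConfig,
    protected: set[int],
) -> str:
    chars = list(seq)
    n = len(chars)
    protect = protected if config.protect_diagnostic_positions else set()
    if config.substitution_rate > 0:
        hits = np.nonzero(rng.random(n) < config.substitution_rate)[0]
        for i in hits:
            if i + 1 in protect:
                continue
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    if config.ambiguity_rate > 0:
        hits = np.nonzero(rng.random(n) < config.ambiguity_rate)[0]
        for i in hits:
            if i + 1 in protect:
                continue
            chars[i] = "N"
    if config.indel_rate > 0:
        keep = rng.random(n) >= config.indel_rate
        chars = [c for c, k, i in zip(chars, keep, range(n)) if k or i + 1 in protect]
    return "".join(chars)


def generate_accession(
    accession_id: str,
    species: str,
    config: GeneratorConfig,
    panel: HaplotypePanel,
    rbcl_refs: dict[str, str] | None = None,
    clade_models: dict[str, CladeModel] | None = None,
    *,
    rbcl_type: str | None = None,
    its_clade: str | None = None,
    triplet: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SeqRecord, SeqRecord]:
    """Emit the (rbcL, ITS) record pair for one accession.

    The haplotype/clade/triplet signature defaults to the species' canonical
    one but can be overridden per accession (discordant-locus cases).
    """
    if species not in SPECIES_SIGNATURES:
        raise KeyError(f"unknown species {species!r}")
    sig_type, sig_clade, sig_triplet = SPECIES_SIGNATURES[species]
    rbcl_type = rbcl_type or sig_type
    its_clade = its_clade or sig_clade
    triplet = sig_triplet if triplet is None else triplet

    if rbcl_refs is None or clade_models is None:
        rbcl_refs, clade_models = make_reference_set(panel, config.seed)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rbcl_seq = rbcl_refs[rbcl_type]
    its_seq = clade_models[its_clade].backbone
    trip = panel.its_triplet
    if triplet:
        for pos, base in trip.patterns[triplet].items():
            its_seq = its_seq[: pos - 1] + base + its_seq[pos:]

    rbcl_protect = {p.position for p in panel.positions_for_locus("rbcL")}
    its_protect = set(trip.positions) | set(clade_models[its_clade].marker_positions)

    rbcl_seq = _apply_noise(rbcl_seq, rng, config, rbcl_protect)
    its_seq = _apply_noise(its_seq, rng, config, its_protect)
    return (
        SeqRecord(id=accession_id, seq=rbcl_seq, description=f"{accession_id} locus=rbcL"),
        SeqRecord(id=accession_id, seq=its_seq, description=f"{accession_id} locus=ITS"),
    )


# ---------------------------------------------------------------------------
# Packaged collection reconstruction
# ---------------------------------------------------------------------------

EXPECTED_TALLIES = {
    "total": 73,
    "confirmed": 36,
    "newly_identified": 4,
    "misidentified": 33,
    "genus_misid": 7,
    "species_misid": 26,
    "liriope_collection": 46,
    "ophiopogon_collection": 27,
    "liriope_confirmed": 27,
    "type3": 9,
}


def load_truth_manifest() -> pd.DataFrame:
    text = resources.files("liriopogon.data").joinpath("truth_manifest.tsv").read_text()
    return pd.read_csv(StringIO(text), sep="\t", dtype=str).fillna("")


def validate_truth_manifest(df: pd.DataFrame, panel: HaplotypePanel) -> dict[str, int]:
    """Check the fixture's implied tallies before generating any sequence.

    Status is derived from (original label, true species) exactly as the
    decision stage would; a mismatch with the expected collection-level
    totals is a hard error.
    """
    statuses = []
    for _, row in df.iterrows():
        label = normalize_label(row["original_label"])
        genus = _genus_of(row["true_species"])
        statuses.append(status_of(genus, row["true_species"], label))
        if row["rbcl_type"] not in panel.haplotype_names:
            raise ValueError(f"{row['accession_id']}: unknown haplotype {row['rbcl_type']}")
        if row["its_clade"] not in CLADES:
            raise ValueError(f"{row['accession_id']}: unknown clade {row['its_clade']}")
        hap_taxa = panel.taxa_for(row["rbcl_type"])
        if not any(
            _species_matches(row["true_species"], taxon) for taxon in hap_taxa
        ):
            raise ValueError(
                f"{row['accession_id']}: {row['true_species']} not consistent "
                f"with {row['rbcl_type']} taxa {hap_taxa}"
            )
    observed = {
        "total": len(df),
        "confirmed": statuses.count("confirmed"),
        "newly_identified": statuses.count("newly_identified"),
        "misidentified": statuses.count("genus_misid") + statuses.count("species_misid"),
        "genus_misid": statuses.count("genus_misid"),
        "species_misid": statuses.count("species_misid"),
        "liriope_collection": int((df["collection"] == "Liriope").sum()),
        "ophiopogon_collection": int((df["collection"] == "Ophiopogon").sum()),
        "liriope_confirmed": sum(
            s == "confirmed"
            for s, (_, row) in zip(statuses, df.iterrows())
            if row["collection"] == "Liriope"
        ),
        "type3": int((df["rbcl_type"] == "Type 3").sum()),
    }
    if observed != EXPECTED_TALLIES:
        diffs = {
            k: (observed[k], EXPECTED_TALLIES[k])
            for k in EXPECTED_TALLIES
            if observed[k] != EXPECTED_TALLIES[k]
        }
        raise ValueError(f"truth manifest inconsistent with expected totals: {diffs}")
    return observed


def _species_matches(a: str, b: str) -> bool:
    strip = lambda s: " ".join(w for w in s.split() if not w.startswith("("))
    return strip(a) == strip(b)


def reconstruct_collection(
    config: GeneratorConfig,
    panel: HaplotypePanel,
) -> tuple[list[SeqRecord], list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Build the packaged collection: (rbcL records, ITS records, ITS clade
    references, manifest DataFrame)."""
    df = load_truth_manifest()
    validate_truth_manifest(df, panel)
    rbcl_refs, clade_models = make_reference_set(panel, config.seed)
    rng = np.random.default_rng(config.seed)

    rbcl_records: list[SeqRecord] = []
    its_records: list[SeqRecord] = []
    for _, row in df.iterrows():
        rec_rbcl, rec_its = generate_accession(
            row["accession_id"],
            row["true_species"],
            config,
            panel,
            rbcl_refs,
            clade_models,
            rbcl_type=row["rbcl_type"],
            its_clade=row["its_clade"],
            triplet=row["triplet"] or None,
            rng=rng,
        )
        rbcl_records.append(rec_rbcl)
        its_records.append(rec_its)
    reference_records = [
        ref for model in clade_models.values() for ref in model.references
    ]
    return rbcl_records, its_records, reference_records, df
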