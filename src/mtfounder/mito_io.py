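"""Panel input and variant extraction.

Reads whole-mitogenome FASTA panels with their sample metadata, anchors
each sequence to the reference coordinate system and expresses it as a
:class:`~mtfounder.variants.VariantProfile`. Sequences of full reference
length (gaps allowed) are compared column-by-column; anything else is
globally aligned first with Biopython's pairwise aligner.

Ambiguity codes (N, R, Y, ...) become *missing* positions — never
variants — and profiles with more than 5% missing sites are flagged
``high_missing``. Insertions are keyed to the preceding reference
position with ``.1``, ``.2`` suffix numbering; deletions are recorded
per deleted reference position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import (AlignmentError, DuplicateSampleError,
                     MetadataMismatchError, MtFounderError)
from .reference import ReferenceGenome
from .variants import (DELETION, INSERTION, MT_LENGTH, SUBSTITUTION, Variant,
                       VariantProfile)

VALID_BASES = set("ACGT")
GAP = "-"
MISSING_FRACTION_FLAG = 0.05


@dataclass(frozen=True)
class PanelRecord:
    """A raw panel entry: sequence plus its metadata row."""

    sample_id: str
    sequence: str
    population: str
    region: str = ""


def read_fasta_panel(path, metadata_path) -> List[PanelRecord]:
    """Read a mitogenome FASTA and its sample metadata TSV.

    The TSV must have columns ``sample_id``, ``population``, ``region``;
    every FASTA record ID must appear in it. Sequence case is
    normalised to upper; ambiguity codes are preserved for
    :func:`call_variants` to interpret.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    if not path.exists():
        raise MtFounderError(f"FASTA file not found: {path}")
    if not metadata_path.exists():
        raise MtFounderError(f"metadata file not found: {metadata_path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "population", "region"}
    if not required.issubset(meta.columns):
        raise MetadataMismatchError(
            f"metadata must have columns {sorted(required)}, "
            f"got {list(meta.columns)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateSampleError(f"duplicate sample IDs in metadata: {dups}")
    meta_map = meta.set_index("sample_id")

    records: List[PanelRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateSampleError(f"duplicate FASTA record ID: {rec.id}")
        seen.add(rec.id)
        if rec.id not in meta_map.index:
            raise MetadataMismatchError(
                f"FASTA record {rec.id!r} missing from metadata")
        row = meta_map.loc[rec.id]
        records.append(PanelRecord(sample_id=rec.id,
                                   sequence=str(rec.seq).upper(),
                                   population=row["population"],
                                   region=row["region"]))
    return records


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _align_to_reference(sequence: str, reference: ReferenceGenome) -> Tuple[str, str]:
    """Return (reference_row, sequence_row) of a global alignment."""
    if abs(len(sequence) - MT_LENGTH) > 2000:
        raise AlignmentError(
            f"sequence length {len(sequence)} incompatible with the "
            f"{MT_LENGTH}-bp reference")
    aln = _aligner().align(reference.sequence, sequence)[0]
    ref_row, seq_row = str(aln[0]), str(aln[1])
    return ref_row, seq_row


def call_variants(sequence: str, reference: ReferenceGenome,
                  sample_id: str = "sample", population: str = "study",
                  region: str = "") -> VariantProfile:
    """Express one mitogenome as a :class:`VariantProfile` against the
    reference. Deterministic for fixed input."""
    sequence = sequence.upper()
    if len(sequence) == MT_LENGTH:
        ref_row, seq_row = reference.sequence, sequence
    else:
        ref_row, seq_row = _align_to_reference(sequence, reference)

    variants: List[Variant] = []
    missing: set = set()
    ref_pos = 0  # last consumed 1-based reference position
    ins_index = 0
    pending_deletion_run: List[int] = []

    for rbase, sbase in zip(ref_row, seq_row):
        if rbase != GAP:
            ref_pos += 1
            ins_index = 0
            if sbase == GAP:
                variants.append(Variant(ref_pos, rbase, None, DELETION))
            elif sbase not in VALID_BASES:
                missing.add(ref_pos)
            elif sbase != rbase:
                variants.append(Variant(ref_pos, rbase, sbase, SUBSTITUTION))
        else:
            # insertion relative to the reference, keyed to previous position
            if sbase == GAP:
                continue
            ins_index += 1
            anchor = ref_pos if ref_pos >= 1 else 1
            if sbase in VALID_BASES:
                variants.append(Variant(anchor, None, sbase, INSERTION,
                                        insertion_index=ins_index))
    if ref_pos != MT_LENGTH:
        raise AlignmentError(
            f"alignment consumed {ref_pos} reference positions, "
            f"expected {MT_LENGTH}")

    flags: Tuple[str, ...] = ()
    if len(missing) / MT_LENGTH > MISSING_FRACTION_FLAG:
        flags = ("high_missing",)
    return VariantProfile(sample_id=sample_id, variants=tuple(variants),
                          population=population, region=region,
                          missing_positions=frozenset(missing), flags=flags)


def call_panel(records: Sequence[PanelRecord],
               reference: ReferenceGenome) -> List[VariantProfile]:
    """Variant-call every record of a panel."""
    return [call_variants(r.sequence, reference, sample_id=r.sample_id,
                          population=r.population, region=r.region)
            for r in records]


def apply_variants(reference: ReferenceGenome,
                   profile: VariantProfile) -> str:
    """Reconstruct the full-length sequence a profile describes
    (substitutions and deletions applied; insertions appended after their
    anchor; missing positions rendered as ``N``)."""
    seq = list(reference.sequence)
    inserts: Dict[int, List[str]] = {}
    for v in profile.variants:
        if v.kind == SUBSTITUTION and v.alt_allele:
            seq[v.position - 1] = v.alt_allele
        elif v.kind == DELETION:
            seq[v.position - 1] = ""
        elif v.kind == INSERTION and v.alt_allele:
            inserts.setdefault(v.position, []).append(v.alt_allele)
    for pos in profile.missing_positions:
        if seq[pos - 1]:
            seq[pos - 1] = "N"
    for pos, bases in inserts.items():
        seq[pos - 1] = seq[pos - 1] + "".join(bases)
    return "".join(seq)
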