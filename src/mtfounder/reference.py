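"""Reference mitogenome, gene annotation and hotspot handling.

The package treats the 16,569-bp human mitochondrial reference
coordinate system as fixed: every variant, gene and hotspot is expressed
in 1-based inclusive positions on it. The molecule is circular — the
control region spans the origin (16024..16569 joined to 1..576) — but
alignment and coordinates treat it as linear anchored at position 1, the
field's standard convention.

A deterministic *synthetic* reference sequence ships with the package
(``data/synthetic_reference.fasta``) together with the real, public gene
coordinate table, so the test-suite and the synthetic-data generator
never need a download. For real analyses the user supplies the actual
rCRS FASTA via :func:`load_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .errors import MtFounderError
from .variants import MT_LENGTH

CODING_REGION = (577, 16_023)

PROTEIN = "protein"
RRNA = "rRNA"
CONTROL = "control"


@dataclass(frozen=True)
class GeneAnnotation:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    frame_offset: int
    kind: str    # protein | rRNA | control

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise ValueError(f"{self.name}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ReferenceGenome:
    """The reference sequence plus its gene annotation."""

    sequence: str
    genes: Tuple[GeneAnnotation, ...] = ()
    is_circular: bool = True
    name: str = "reference"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != MT_LENGTH:
            raise MtFounderError(
                f"reference length {len(seq)} != expected {MT_LENGTH}")
        for g in self.genes:
            if g.kind == PROTEIN and not (
                    CODING_REGION[0] <= g.start and g.end <= CODING_REGION[1]):
                raise MtFounderError(
                    f"protein gene {g.name} outside coding region {CODING_REGION}")

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequence[position - 1]

    def protein_genes(self) -> Tuple[GeneAnnotation, ...]:
        return tuple(g for g in self.genes if g.kind == PROTEIN)

    def genes_at(self, position: int) -> Tuple[GeneAnnotation, ...]:
        """All annotated features covering a position (overlapping genes
        such as ATP8/ATP6 both returned)."""
        return tuple(g for g in self.genes if g.contains(position))

    def region_of(self, position: int) -> str:
        """Classify a position: protein / rRNA / control / other."""
        kinds = {g.kind for g in self.genes_at(position)}
        if PROTEIN in kinds:
            return PROTEIN
        if RRNA in kinds:
            return RRNA
        if position >= 16_024 or position <= 576:
            return CONTROL
        return "other"


def _data_path(name: str):
    return resources.files("mtfounder.data").joinpath(name)


def load_gene_annotation(path=None) -> Tuple[GeneAnnotation, ...]:
    """Read a gene annotation TSV (gene, start, end, strand, frame, kind)."""
    src = Path(path) if path is not None else _data_path("gene_annotation.tsv")
    genes: List[GeneAnnotation] = []
    with src.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end, strand, frame, kind = line.split("\t")
            genes.append(GeneAnnotation(name, int(start), int(end),
                                        strand, int(frame), kind))
    return tuple(genes)


def load_reference(fasta_path=None, annotation_path=None) -> ReferenceGenome:
    """Load a reference mitogenome.

    With no arguments, returns the packaged synthetic reference (a
    deterministic stand-in sequence on the real coordinate system, with
    the real gene coordinates). Pass the rCRS FASTA for real data.
    """
    src = Path(fasta_path) if fasta_path is not None else _data_path(
        "synthetic_reference.fasta")
    with src.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return ReferenceGenome(sequence=str(record.seq),
                           genes=load_gene_annotation(annotation_path),
                           name=record.id)


# ---------------------------------------------------------------------------
# Hotspots

@dataclass(frozen=True)
class HotspotList:
    """Hypervariable positions excluded from founder definitions, dating
    and haplogroup scoring."""

    positions: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        bad = [p for p in self.positions if not 1 <= p <= MT_LENGTH]
        if bad:
            raise MtFounderError(f"hotspot positions out of range: {sorted(bad)}")

    def __contains__(self, position: int) -> bool:
        return position in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(sorted(self.positions))


def load_hotspots(path) -> HotspotList:
    """Read a hotspot list: one 1-based position per line, ``#`` comments
    allowed, duplicates collapsed."""
    positions = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                pos = int(line)
            except ValueError as exc:
                raise MtFounderError(f"{path}:{ln}: not an integer: {line!r}") from exc
            if not 1 <= pos <= MT_LENGTH:
                raise MtFounderError(f"{path}:{ln}: position {pos} out of range")
            positions.add(pos)
    return HotspotList(frozenset(positions))


def default_hotspots() -> HotspotList:
    """The packaged minimal default hotspot list (well-known mtDNA
    hypervariable sites). For real analyses supply the full published
    hypervariable-site list via :func:`load_hotspots`."""
    with resources.as_file(_data_path("hotspots_default.txt")) as p:
        return load_hotspots(p)
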