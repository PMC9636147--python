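"""mtDNA variant nomenclature: the :class:`Variant` value type, string
parsing/formatting, and per-sample :class:`VariantProfile` containers.

Variants are named against the 16,569-bp mitochondrial reference in the
field's standard style: ``A2833G`` (substitution, reference allele
optional on input: ``7419A``), ``8281d`` (deletion), ``8280.1C``
(insertion, suffix-numbered after the anchoring reference position) and a
leading ``@`` marking a back mutation (reversion), which may stand alone
as ``@16261`` when the alleles are implied by context.

Coordinates are 1-based inclusive throughout; the package never exposes
0-based positions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

from .errors import VariantParseError

MT_LENGTH = 16_569

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

_VARIANT_RE = re.compile(
    r"""^(?P<back>@)?
         (?P<ref>[ACGT])?
         (?P<pos>\d+)
         (?:
             \.(?P<insidx>\d+)(?P<insbase>[ACGT]+)   # insertion: 8280.1C
           | (?P<alt>[ACGT])                          # substitution alt
           | (?P<del>d)                               # deletion
         )?$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class Variant:
    """A single difference from the reference.

    ``ref_allele``/``alt_allele`` may be ``None`` only in the bare
    back-mutation notation (``@16261``) and for deletions (no alt).
    ``insertion_index`` is the ``.N`` suffix for insertions (0 otherwise).
    """

    position: int
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    kind: str = SUBSTITUTION
    insertion_index: int = 0
    is_back_mutation: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == SUBSTITUTION and self.ref_allele and self.alt_allele:
            if self.ref_allele == self.alt_allele:
                raise ValueError("ref and alt alleles are identical")

    @property
    def is_substitution(self) -> bool:
        return self.kind == SUBSTITUTION

    def as_back_mutation(self) -> "Variant":
        return replace(self, is_back_mutation=True)


def format_variant(v: Variant) -> str:
    """Render a :class:`Variant` in canonical mtDNA nomenclature."""
    prefix = "@" if v.is_back_mutation else ""
    if v.kind == INSERTION:
        return f"{prefix}{v.position}.{v.insertion_index}{v.alt_allele}"
    if v.kind == DELETION:
        return f"{prefix}{v.ref_allele or ''}{v.position}d"
    if v.alt_allele is None:  # bare back-mutation form
        return f"{prefix}{v.position}"
    return f"{prefix}{v.ref_allele or ''}{v.position}{v.alt_allele}"


def parse_variant(text: str) -> Variant:
    """Parse one variant string; inverse of :func:`format_variant`.

    Raises :class:`VariantParseError` with the offset of the first
    offending character.
    """
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        # locate the failure point for the error message
        offset = 0
        for i in range(len(text), -1, -1):
            if _VARIANT_RE.match(text[:i] + "1A") or i == 0:
                offset = i
                break
        raise VariantParseError(text, offset)
    back = bool(m.group("back"))
    pos = int(m.group("pos"))
    if pos < 1 or pos > MT_LENGTH:
        raise VariantParseError(text, m.start("pos"), "position out of range")
    if m.group("insidx") is not None:
        return Variant(pos, None, m.group("insbase"), INSERTION,
                       insertion_index=int(m.group("insidx")),
                       is_back_mutation=back)
    if m.group("del"):
        return Variant(pos, m.group("ref"), None, DELETION, is_back_mutation=back)
    alt = m.group("alt")
    if alt is None:
        if not back:
            raise VariantParseError(text, len(text),
                                    "bare position allowed only with '@'")
        return Variant(pos, None, None, SUBSTITUTION, is_back_mutation=True)
    ref = m.group("ref")
    if ref == alt:
        raise VariantParseError(text, len(text) - 1, "ref equals alt")
    return Variant(pos, ref, alt, SUBSTITUTION, is_back_mutation=back)


@dataclass(frozen=True)
class VariantProfile:
    """An individual's mitogenome as an ordered set of differences from
    the reference — the pipeline's universal currency.

    ``missing_positions`` holds sites that could not be called
    (ambiguity codes); they are excluded from every downstream count.
    """

    sample_id: str
    variants: Tuple[Variant, ...] = ()
    population: str = "study"
    region: str = ""
    missing_positions: FrozenSet[int] = frozenset()
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants,
                               key=lambda v: (v.position, v.kind, v.insertion_index)))
        object.__setattr__(self, "variants", ordered)
        seen = set()
        for v in ordered:
            key = (v.position, v.kind, v.insertion_index)
            if key in seen:
                raise ValueError(
                    f"{self.sample_id}: two variants at position {v.position} "
                    f"of kind {v.kind}")
            seen.add(key)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def substitutions(self) -> Tuple[Variant, ...]:
        return tuple(v for v in self.variants if v.kind == SUBSTITUTION)

    def substitution_state(self, exclude: Iterable[int] = ()) -> Dict[int, str]:
        """Map position -> derived allele for substitutions, minus ``exclude``."""
        ex = set(exclude)
        return {v.position: v.alt_allele for v in self.substitutions()
                if v.position not in ex and v.alt_allele is not None}

    def haplotype_key(self, exclude: Iterable[int] = ()) -> FrozenSet[Tuple[int, str]]:
        """Hashable fingerprint of the substitution haplotype."""
        return frozenset(self.substitution_state(exclude).items())

    def with_population(self, population: str, region: str = "") -> "VariantProfile":
        return replace(self, population=population, region=region)


def pairwise_differences(a: VariantProfile, b: VariantProfile,
                         exclude: Iterable[int] = ()) -> int:
    """Number of substitution sites at which two profiles differ.

    Positions missing in either profile, and positions in ``exclude``
    (typically mutational hotspots), are not counted.
    """
    skip = set(exclude) | set(a.missing_positions) | set(b.missing_positions)
    sa = a.substitution_state(skip)
    sb = b.substitution_state(skip)
    n = 0
    for pos in set(sa) | set(sb):
        if sa.get(pos) != sb.get(pos):
            n += 1
    return n


# ---------------------------------------------------------------------------
# JSON serialisation of profile panels

def profile_to_dict(p: VariantProfile) -> dict:
    return {
        "sample_id": p.sample_id,
        "population": p.population,
        "region": p.region,
        "variants": [format_variant(v) for v in p.variants],
        "missing_positions": sorted(p.missing_positions),
        "flags": list(p.flags),
    }


def profile_from_dict(d: dict) -> VariantProfile:
    return VariantProfile(
        sample_id=d["sample_id"],
        variants=tuple(parse_variant(s) for s in d.get("variants", [])),
        population=d.get("population", "study"),
        region=d.get("region", ""),
        missing_positions=frozenset(d.get("missing_positions", [])),
        flags=tuple(d.get("flags", [])),
    )


def write_profiles_json(profiles: Sequence[VariantProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump([profile_to_dict(p) for p in profiles], fh, indent=1)


def read_profiles_json(path) -> List[VariantProfile]:
    with open(path) as fh:
        return [profile_from_dict(d) for d in json.load(fh)]
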