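"""Heparan-sulfate oligosaccharide sequences and protein basic-cluster scanning.

Heparan sulfate (HS) is a linear polysaccharide of alternating hexuronic acid
(here iduronic acid, IdoA) and glucosamine (GlcN) units.  Glucosamine may be
N-acetylated (GlcNAc) or N-sulfated (GlcNS) and O-sulfated at the 6- (and
rarely 3-) position; iduronic acid may be 2-O-sulfated.  Sequences are written
in a compact shorthand, e.g. ``IdoA2S-GlcNS6S-IdoA2S-GlcNS``, optionally
annotated with a pyranose ring conformer in parentheses, e.g.
``IdoA2S(1C4)``.  By convention the leftmost token is the non-reducing end
(NRE); an orientation flag records the opposite convention where needed.

This module provides:

* a lossless parser/formatter for the shorthand notation,
* combinatorial enumeration of sequence libraries from per-position variant
  alphabets (the input to virtual screening),
* per-sequence physicochemical properties (sulfate count, net charge),
* a sliding-window scan of protein primary sequence for clusters of basic
  residues, the canonical first guess at a GAG binding site.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

__all__ = [
    "Base",
    "NSubstituent",
    "Conformer",
    "SaccharideUnit",
    "OligoSequence",
    "LibrarySpec",
    "BasicCluster",
    "SequenceError",
    "parse_unit",
    "parse_sequence",
    "format_sequence",
    "enumerate_library",
    "sequence_properties",
    "find_basic_clusters",
    "write_library",
    "read_library",
]


class SequenceError(ValueError):
    """Raised for malformed or invalid saccharide sequence notation."""


class Base(str, Enum):
    IDOA = "IdoA"
    GLCN = "GlcN"


class NSubstituent(str, Enum):
    NONE = "none"
    ACETYL = "Ac"
    SULFATE = "S"


class Conformer(str, Enum):
    C1C4 = "1C4"
    S2O = "2SO"
    C4C1 = "4C1"
    UNSPECIFIED = "unspecified"


# ring conformers are base-specific: IdoA samples 1C4/2SO, GlcN sits in 4C1
_ALLOWED_CONFORMERS = {
    Base.IDOA: {Conformer.C1C4, Conformer.S2O, Conformer.UNSPECIFIED},
    Base.GLCN: {Conformer.C4C1, Conformer.UNSPECIFIED},
}
_ALLOWED_OSULF = {Base.IDOA: {"2S"}, Base.GLCN: {"3S", "6S"}}


@dataclass(frozen=True, order=True)
class SaccharideUnit:
    """One monosaccharide unit with its substitution and conformer state."""

    base: Base
    n_substituent: NSubstituent = NSubstituent.NONE
    o_sulfation: frozenset[str] = frozenset()
    conformer: Conformer = Conformer.UNSPECIFIED

    def __post_init__(self) -> None:
        if self.base is Base.IDOA and self.n_substituent is not NSubstituent.NONE:
            raise SequenceError("IdoA carries no N-substituent")
        if self.base is Base.GLCN and self.n_substituent is NSubstituent.NONE:
            raise SequenceError("GlcN requires an N-substituent (Ac or S)")
        bad = set(self.o_sulfation) - _ALLOWED_OSULF[self.base]
        if bad:
            raise SequenceError(
                f"O-sulfation position(s) {sorted(bad)} invalid for {self.base.value}"
            )
        if self.conformer not in _ALLOWED_CONFORMERS[self.base]:
            raise SequenceError(
                f"conformer {self.conformer.value} invalid for {self.base.value}"
            )
        # normalise o_sulfation to frozenset even if a plain set/iterable was passed
        object.__setattr__(self, "o_sulfation", frozenset(self.o_sulfation))

    @property
    def n_sulfates(self) -> int:
        n = len(self.o_sulfation)
        if self.n_substituent is NSubstituent.SULFATE:
            n += 1
        return n

    def token(self, with_conformer: bool = True) -> str:
        """Canonical notation token for this unit."""
        if self.base is Base.IDOA:
            text = "IdoA" + ("2S" if "2S" in self.o_sulfation else "")
        else:
            text = "GlcN" + (
                "Ac" if self.n_substituent is NSubstituent.ACETYL else "S"
            )
            # positions in ascending numeric order: 3S before 6S
            for pos in sorted(self.o_sulfation):
                text += pos
        if with_conformer and self.conformer is not Conformer.UNSPECIFIED:
            text += f"({self.conformer.value})"
        return text

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


class Orientation(str, Enum):
    NRE_FIRST = "nre_first"
    RE_FIRST = "re_first"


@dataclass(frozen=True)
class OligoSequence:
    """An ordered oligosaccharide; leftmost unit is the non-reducing end by default."""

    units: tuple[SaccharideUnit, ...]
    orientation: Orientation = Orientation.NRE_FIRST
    label: str = ""

    def __post_init__(self) -> None:
        units = tuple(self.units)
        object.__setattr__(self, "units", units)
        if len(units) < 1:
            raise SequenceError("sequence must contain at least one unit")
        for a, b in zip(units, units[1:]):
            if a.base is b.base:
                raise SequenceError(
                    f"bases must alternate: consecutive {a.base.value} units"
                )

    def __len__(self) -> int:
        return len(self.units)

    @property
    def notation(self) -> str:
        return format_sequence(self)

    def with_label(self, label: str) -> "OligoSequence":
        return replace(self, label=label)


_UNIT_RE = re.compile(
    r"^(?P<base>IdoA|GlcN)"
    r"(?P<nsub>Ac|S)?"
    r"(?P<osulf>(?:[236]S)*)"
    r"(?:\((?P<conf>1C4|2SO|4C1)\))?$"
)


def parse_unit(token: str) -> SaccharideUnit:
    """Parse a single notation token such as ``GlcNS6S`` or ``IdoA2S(1C4)``."""
    m = _UNIT_RE.match(token.strip())
    if m is None:
        raise SequenceError(f"unrecognised saccharide token: {token!r}")
    base = Base(m.group("base"))
    nsub = m.group("nsub")
    osulf_text = m.group("osulf") or ""
    osulf = frozenset(osulf_text[i : i + 2] for i in range(0, len(osulf_text), 2))
    conf = Conformer(m.group("conf")) if m.group("conf") else Conformer.UNSPECIFIED
    if base is Base.IDOA:
        if nsub is not None:
            raise SequenceError(f"unrecognised saccharide token: {token!r}")
        n_substituent = NSubstituent.NONE
    else:
        if nsub is None:
            raise SequenceError(
                f"GlcN token {token!r} lacks an N-substituent (use GlcNAc or GlcNS)"
            )
        n_substituent = NSubstituent.ACETYL if nsub == "Ac" else NSubstituent.SULFATE
    try:
        return SaccharideUnit(base, n_substituent, osulf, conf)
    except SequenceError as exc:
        raise SequenceError(f"invalid token {token!r}: {exc}") from exc


def parse_sequence(
    text: str,
    orientation: Orientation = Orientation.NRE_FIRST,
    label: str = "",
) -> OligoSequence:
    """Parse a full ``-``-separated sequence string into an :class:`OligoSequence`.

    Raises :class:`SequenceError` naming the offending token for unknown
    tokens, and for sequences whose bases do not alternate.
    """
    tokens = [t for t in text.strip().split("-") if t != ""]
    if not tokens:
        raise SequenceError("empty sequence string")
    units = tuple(parse_unit(t) for t in tokens)
    return OligoSequence(units, orientation=orientation, label=label or text.strip())


def format_sequence(seq: OligoSequence, with_conformers: bool = True) -> str:
    """Canonical notation string; the exact inverse of :func:`parse_sequence`."""
    return "-".join(u.token(with_conformer=with_conformers) for u in seq.units)


# ---------------------------------------------------------------------------
# combinatorial library enumeration
# ---------------------------------------------------------------------------

#: The common variant alphabets used for toy tetrasaccharide libraries.
DEFAULT_IDOA_VARIANTS: tuple[SaccharideUnit, ...] = (
    parse_unit("IdoA"),
    parse_unit("IdoA2S"),
)
DEFAULT_GLCN_VARIANTS: tuple[SaccharideUnit, ...] = (
    parse_unit("GlcNAc"),
    parse_unit("GlcNAc6S"),
    parse_unit("GlcNS"),
    parse_unit("GlcNS6S"),
)


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for combinatorial enumeration of an alternating-oligomer library.

    ``length`` is the degree of polymerisation (dp); ``start_base`` fixes the
    base at the non-reducing end and the rest alternate.  Conformers listed on
    the variants are carried as metadata and multiply the library only if
    distinct conformers are explicitly listed as separate variants.
    """

    length: int = 4
    start_base: Base = Base.IDOA
    idoa_variants: tuple[SaccharideUnit, ...] = DEFAULT_IDOA_VARIANTS
    glcn_variants: tuple[SaccharideUnit, ...] = DEFAULT_GLCN_VARIANTS
    exclusions: tuple[Callable[[OligoSequence], bool], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SequenceError("library length must be >= 1")
        object.__setattr__(self, "idoa_variants", tuple(self.idoa_variants))
        object.__setattr__(self, "glcn_variants", tuple(self.glcn_variants))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))

    def variants_at(self, position: int) -> tuple[SaccharideUnit, ...]:
        bases = (Base.IDOA, Base.GLCN)
        offset = 0 if self.start_base is Base.IDOA else 1
        base = bases[(position + offset) % 2]
        return self.idoa_variants if base is Base.IDOA else self.glcn_variants


def enumerate_library(spec: LibrarySpec) -> list[OligoSequence]:
    """Enumerate every alternating sequence the spec admits.

    Returns deduplicated sequences in deterministic lexicographic order of
    their canonical notation; exclusion predicates are applied after
    enumeration.  With empty exclusions the count is the product of the
    per-position variant-list sizes.
    """
    per_position = [spec.variants_at(i) for i in range(spec.length)]
    for i, variants in enumerate(per_position):
        if not variants:
            raise SequenceError(f"empty variant list at position {i}")
    seen: dict[str, OligoSequence] = {}
    for combo in itertools.product(*per_position):
        seq = OligoSequence(combo)
        if any(pred(seq) for pred in spec.exclusions):
            continue
        seen.setdefault(format_sequence(seq), seq)
    out = []
    for i, key in enumerate(sorted(seen)):
        out.append(seen[key].with_label(key))
    return out


def sequence_properties(seq: OligoSequence) -> dict[str, int]:
    """Sulfate count, formal net charge and uronic-acid count for a sequence.

    Net charge counts one negative charge per sulfate (N- or O-) plus one per
    uronic-acid carboxylate, all fully ionised.
    """
    n_sulfates = sum(u.n_sulfates for u in seq.units)
    n_uronic = sum(1 for u in seq.units if u.base is Base.IDOA)
    return {
        "n_sulfates": n_sulfates,
        "net_charge": -(n_sulfates + n_uronic),
        "n_uronic": n_uronic,
    }


# ---------------------------------------------------------------------------
# library I/O (one sequence per line, or CSV with properties)
# ---------------------------------------------------------------------------

def write_library(sequences: Iterable[OligoSequence], path, fmt: str = "txt") -> None:
    """Write a library as plain text (one notation per line) or CSV."""
    sequences = list(sequences)
    if fmt == "txt":
        with open(path, "w") as fh:
            for seq in sequences:
                fh.write(format_sequence(seq) + "\n")
    elif fmt == "csv":
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "sequence", "n_sulfates", "net_charge"])
            for seq in sequences:
                props = sequence_properties(seq)
                writer.writerow(
                    [
                        seq.label or format_sequence(seq),
                        format_sequence(seq),
                        props["n_sulfates"],
                        props["net_charge"],
                    ]
                )
    else:
        raise ValueError(f"unknown library format: {fmt!r}")


def read_library(path) -> list[OligoSequence]:
    """Read a library written by :func:`write_library` (txt or CSV)."""
    with open(path) as fh:
        first = fh.readline()
        rest = fh.readlines()
    lines = [ln.strip() for ln in [first, *rest] if ln.strip()]
    if not lines:
        return []
    if lines[0].lower().startswith("label,"):
        out = []
        for ln in lines[1:]:
            parts = ln.split(",")
            out.append(parse_sequence(parts[1], label=parts[0]))
        return out
    return [parse_sequence(ln) for ln in lines]


# ---------------------------------------------------------------------------
# basic-cluster scanning of protein primary sequence
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class BasicCluster:
    """A maximal run of basic residues dense enough to suggest a GAG site."""

    start: int
    end: int
    residues: str
    count_basic: int


def find_basic_clusters(
    protein_seq: str,
    first_residue_number: int = 1,
    window: int = 5,
    min_basic: int = 3,
    include_histidine: bool = False,
) -> list[BasicCluster]:
    """Scan a one-letter protein sequence for clusters of basic residues.

    Slides a window of ``window`` residues; windows containing at least
    ``min_basic`` basic residues (K/R, optionally H) are merged when they
    overlap, and each merged region is trimmed to its first and last basic
    residue.  Residue numbering starts at ``first_residue_number``.
    """
    seq = protein_seq.strip().upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"invalid residue letter(s): {sorted(bad)}")
    if not (window >= min_basic >= 1):
        raise ValueError("require window >= min_basic >= 1")
    basic = set("KR") | (set("H") if include_histidine else set())
    is_basic = [c in basic for c in seq]

    hits: list[tuple[int, int]] = []  # [start, end) index spans of qualifying windows
    for i in range(0, max(len(seq) - window + 1, 0)):
        if sum(is_basic[i : i + window]) >= min_basic:
            if hits and i <= hits[-1][1]:
                hits[-1] = (hits[-1][0], i + window)
            else:
                hits.append((i, i + window))

    clusters = []
    for lo, hi in hits:
        span = range(lo, min(hi, len(seq)))
        basics = [i for i in span if is_basic[i]]
        first, last = basics[0], basics[-1]
        clusters.append(
            BasicCluster(
                start=first + first_residue_number,
                end=last + first_residue_number,
                residues=seq[first : last + 1],
                count_basic=sum(is_basic[first : last + 1]),
            )
        )
    return clusters
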