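"""Sequence parsing, residue composition, and modification schemes.

Sequences come in as FASTA (multi-record, wrapped lines) or raw pasted
text.  Parsing is tolerant of the things people actually paste: mixed
case, whitespace, line numbering from GenBank-style records, and DNA
template sequences (``T`` is mapped to ``U`` with a warning unless strict
mode is on).

A :class:`ModificationScheme` describes canonical-to-modified residue
substitutions, each with a fraction in [0, 1].  Applying a scheme to a
:class:`Composition` keeps real-valued counts internally so every
downstream photometric quantity is exactly linear in the substitution
fraction; integer rounding happens only when a discrete composition report
is requested.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO

from .errors import SequenceError, ValidationError
from .registry import normalize_code

__all__ = [
    "SubstitutionRule",
    "ModificationScheme",
    "Composition",
    "read_sequences",
    "composition",
    "apply_scheme",
    "parse_scheme",
]

CANONICAL_ALPHABET = frozenset("ACGU")
#: Single-letter extended codes accepted when ``extended=True``.
EXTENDED_ALPHABET = frozenset("ACGUY")
_STRIP = str.maketrans("", "", " \t\r\n0123456789")


@dataclass(frozen=True)
class SubstitutionRule:
    canonical: str
    modified: str
    fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical", normalize_code(self.canonical))
        object.__setattr__(self, "modified", normalize_code(self.modified))
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(
                f"substitution fraction must lie in [0, 1], got {self.fraction}"
            )
        if self.canonical == self.modified:
            raise ValidationError(
                f"substitution must change the residue code ({self.canonical!r})"
            )


@dataclass(frozen=True)
class ModificationScheme:
    """A set of canonical→modified substitutions with fractions."""

    substitutions: tuple[SubstitutionRule, ...] = ()

    def __post_init__(self) -> None:
        rules = tuple(
            r if isinstance(r, SubstitutionRule) else SubstitutionRule(*r)
            for r in self.substitutions
        )
        object.__setattr__(self, "substitutions", rules)
        seen = set()
        for r in rules:
            if r.canonical in seen:
                raise ValidationError(
                    f"at most one substitution rule per canonical code ({r.canonical!r})"
                )
            seen.add(r.canonical)

    def __bool__(self) -> bool:
        return bool(self.substitutions)

    def __str__(self) -> str:
        return ",".join(
            f"{r.canonical}:{r.modified}:{r.fraction:g}" for r in self.substitutions
        )


def parse_scheme(spec: str) -> ModificationScheme:
    """Parse ``CANON:MOD[:FRACTION]`` rules, comma-separated.

    Examples: ``"U:m1Y"`` (full substitution), ``"U:m1Y:0.5,C:m5C"``.
    """
    spec = spec.strip()
    if not spec:
        return ModificationScheme()
    rules = []
    for token in spec.split(","):
        parts = token.strip().split(":")
        if len(parts) not in (2, 3) or not all(parts):
            raise ValidationError(
                f"bad substitution {token!r}: expected CANON:MOD[:FRACTION], "
                "e.g. 'U:m1Y' or 'U:m1Y:0.5'"
            )
        fraction = 1.0
        if len(parts) == 3:
            try:
                fraction = float(parts[2])
            except ValueError:
                raise ValidationError(
                    f"bad substitution fraction {parts[2]!r} in {token!r}"
                ) from None
        rules.append(SubstitutionRule(parts[0], parts[1], fraction))
    return ModificationScheme(tuple(rules))


@dataclass(frozen=True)
class Composition:
    """Residue counts of a construct plus its cap identity.

    Counts may be real-valued after a fractional substitution; ``rounded()``
    produces the discrete (half-up) report.  The cap is recorded but never
    counted as a residue.
    """

    counts: dict[str, float] = field(default_factory=dict)
    cap: str = "none"

    def __post_init__(self) -> None:
        clean = {}
        for code, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for {code!r}: {n}")
            if n:
                clean[normalize_code(code)] = float(n)
        object.__setattr__(self, "counts", clean)
        object.__setattr__(self, "cap", normalize_code(self.cap))

    @property
    def length(self) -> float:
        return sum(self.counts.values())

    def rounded(self) -> dict[str, int]:
        """Discrete counts, half-up rounding."""
        import math

        return {code: math.floor(n + 0.5) for code, n in self.counts.items()}

    def __add__(self, other: "Composition") -> "Composition":
        merged = dict(self.counts)
        for code, n in other.counts.items():
            merged[code] = merged.get(code, 0.0) + n
        return Composition(merged, cap=self.cap)


def _looks_like_path(source: str) -> bool:
    return bool(source) and "\n" not in source and ">" not in source and Path(source).is_file()


def _clean(raw: str, *, strict_t: bool, extended: bool, record_id: str) -> str:
    seq = raw.translate(_STRIP).upper()
    if "T" in seq:
        if strict_t:
            pos = seq.index("T") + 1
            raise SequenceError(
                f"{record_id}: 'T' at position {pos} (strict mode rejects DNA input)"
            )
        warnings.warn(
            f"{record_id}: mapped {seq.count('T')} 'T' residue(s) to 'U' "
            "(DNA-style input)",
            stacklevel=3,
        )
        seq = seq.replace("T", "U")
    alphabet = EXTENDED_ALPHABET if extended else CANONICAL_ALPHABET
    bad = [(i + 1, ch) for i, ch in enumerate(seq) if ch not in alphabet]
    if bad:
        shown = ", ".join(f"{ch!r} at position {i}" for i, ch in bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise SequenceError(f"{record_id}: invalid characters: {shown}{more}")
    return seq


def read_sequences(
    source: Union[str, Path, IO[str]],
    *,
    strict_t: bool = False,
    extended: bool = False,
) -> list[tuple[str, str]]:
    """Read sequences from a FASTA file/text or a raw pasted sequence.

    ``source`` may be a path, an open text handle, FASTA-formatted text, or
    a bare sequence.  Returns ``[(id, sequence), ...]`` with sequences
    upper-cased and whitespace/digits stripped; raw input without a FASTA
    header becomes a single record named ``seq1``.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or (isinstance(source, str) and _looks_like_path(source)):
        text = Path(source).read_text()
    else:
        text = str(source)

    if not text.strip():
        raise ValidationError("empty input: no sequence records found")

    records: list[tuple[str, str]] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            records.append(
                (rec.id, _clean(str(rec.seq), strict_t=strict_t, extended=extended,
                                record_id=rec.id))
            )
        if not records:
            raise ValidationError("empty input: no sequence records found")
    else:
        records.append(
            ("seq1", _clean(text, strict_t=strict_t, extended=extended, record_id="seq1"))
        )
    return records


def composition(sequence: str, cap: str = "none") -> Composition:
    """Count residues of a validated sequence; the cap is recorded, not counted."""
    counts: dict[str, float] = {}
    for ch in sequence:
        counts[ch] = counts.get(ch, 0.0) + 1.0
    return Composition(counts, cap=cap)


def apply_scheme(comp: Composition, scheme: ModificationScheme) -> Composition:
    """Move ``fraction × n_canonical`` counts to each rule's modified code.

    Counts stay real-valued so the construct's molar absorption is exactly
    linear in every fraction; total length is conserved.
    """
    counts = dict(comp.counts)
    for rule in scheme.substitutions:
        n = counts.get(rule.canonical, 0.0)
        if n == 0.0:
            continue
        moved = rule.fraction * n
        counts[rule.canonical] = n - moved
        counts[rule.modified] = counts.get(rule.modified, 0.0) + moved
    return Composition(counts, cap=comp.cap)
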