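"""IMGT/HLA allele nomenclature: parsing, truncation, and field-level comparison.

HLA alleles are named by locus and up to four colon-delimited numeric
fields of increasing specificity (``A*02:01:01:02``). Fields 1-2 define
the protein; fields 3-4 encode synonymous exonic and intronic variation.
A single trailing letter (N, L, S, C, A, Q) marks atypical expression.

Digits are preserved verbatim: ``A*02:01`` and ``A*2:1`` are different
names here, matching how upstream genotypers and molecular typing report
them. G/P group names are rejected rather than silently truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "HlaAllele",
    "LocusGenotype",
    "AlleleParseError",
    "parse_allele",
    "truncate_allele",
    "alleles_match",
    "CLASSICAL_LOCI",
    "DRB_PARALOGS",
]

#: classical loci assessed by the genotypers under study
CLASSICAL_LOCI = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")
#: paralogous DRB genes present on 0-2 haplotypes per individual
DRB_PARALOGS = ("DRB3", "DRB4", "DRB5")

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?"
    r"(?P<locus>[A-Z][A-Z0-9]*)"
    r"\*"
    r"(?P<fields>[^A-Z]*?)"
    r"(?P<suffix>[A-Z])?$"
)


class AlleleParseError(ValueError):
    """Raised when an allele string does not follow the colon-delimited grammar."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A parsed HLA allele name.

    Attributes
    ----------
    locus : str
        Gene symbol without the ``HLA-`` prefix (``"A"``, ``"DRB1"``, ...).
    fields : tuple of str
        One to four numeric fields, digits kept verbatim (leading zeros
        preserved).
    suffix : str or None
        Optional expression suffix (one of N, L, S, C, A, Q).
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.fields:
            raise AlleleParseError("allele must carry at least one field")
        for f in self.fields:
            if not f.isdigit():
                raise AlleleParseError(f"non-digit field {f!r} in allele")
        if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleParseError(f"unknown expression suffix {self.suffix!r}")

    @property
    def depth(self) -> int:
        """Number of populated fields (1-4)."""
        return len(self.fields)

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.suffix or ''}"


def parse_allele(name: str) -> HlaAllele:
    """Parse an IMGT/HLA-style allele name.

    The optional ``HLA-`` prefix and lowercase input are normalized away.
    G/P group names (``01:01:01G``) are rejected: group resolution against
    an IMGT release is out of scope and silent truncation would misreport
    resolution.

    Raises
    ------
    AlleleParseError
        On a missing ``*``, a non-digit field, or an unknown suffix,
        naming the offending token.
    """
    if not isinstance(name, str):
        raise AlleleParseError(f"allele name must be a string, got {type(name).__name__}")
    cleaned = name.strip().upper()
    if "*" not in cleaned:
        raise AlleleParseError(f"{name!r}: missing '*' separator between locus and fields")
    m = _ALLELE_RE.match(cleaned)
    if m is None:
        raise AlleleParseError(f"{name!r}: does not match LOCUS*F1[:F2[:F3[:F4]]][suffix]")
    suffix = m.group("suffix")
    if suffix is not None:
        if suffix in ("G", "P"):
            raise AlleleParseError(
                f"{name!r}: {suffix}-group names are not supported; supply a plain allele name"
            )
        if suffix not in EXPRESSION_SUFFIXES:
            raise AlleleParseError(f"{name!r}: unknown expression suffix {suffix!r}")
    raw_fields = m.group("fields")
    if not raw_fields:
        raise AlleleParseError(f"{name!r}: no fields after '*'")
    fields = tuple(raw_fields.split(":"))
    for f in fields:
        if not f.isdigit():
            raise AlleleParseError(f"{name!r}: non-digit field {f!r}")
    if len(fields) > 4:
        raise AlleleParseError(f"{name!r}: more than four fields")
    return HlaAllele(locus=m.group("locus"), fields=fields, suffix=suffix)


def truncate_allele(allele: HlaAllele, field_level: int) -> HlaAllele:
    """Return the allele truncated to at most `field_level` fields.

    No padding is invented when the allele has fewer populated fields than
    requested. The expression suffix is kept only when nothing was cut
    (it annotates the full-resolution name, not a prefix of it).
    """
    if field_level < 1:
        raise ValueError("field_level must be >= 1")
    keep = min(field_level, allele.depth)
    suffix = allele.suffix if keep == allele.depth else None
    return HlaAllele(locus=allele.locus, fields=allele.fields[:keep], suffix=suffix)


def alleles_match(
    a: HlaAllele,
    b: HlaAllele,
    field_level: int,
    *,
    require_full_depth: bool = True,
) -> bool:
    """Compare two alleles at a fixed field resolution.

    A match at level ``f`` requires equal loci and equal field prefixes
    through field ``f``. Under the default strict rule an allele typed to
    fewer than ``f`` fields cannot match at level ``f``: a 2-field call is
    no evidence about field 3, and crediting it would inflate field-3
    accuracy for genotypers that never emit 3-field calls. Passing
    ``require_full_depth=False`` relaxes this to agreement over the fields
    both alleles populate (capped at ``field_level``).
    """
    if field_level < 1:
        raise ValueError("field_level must be >= 1")
    if a.locus != b.locus:
        return False
    if require_full_depth:
        if a.depth < field_level or b.depth < field_level:
            return False
        level = field_level
    else:
        level = min(field_level, a.depth, b.depth)
    return a.fields[:level] == b.fields[:level]


@dataclass(frozen=True)
class LocusGenotype:
    """The multiset of alleles called at one locus for one sample.

    Classical loci carry 0-2 alleles; each DRB3/4/5 paralog is treated as
    its own locus (0-2 alleles each before copy-number filtering, spurious
    extras possible in unfiltered upstream output). ``ranked`` marks that
    the allele order reflects the upstream genotyper's confidence ranking,
    a precondition of top-n copy-number filtering.
    """

    locus: str
    alleles: tuple[HlaAllele, ...] = field(default_factory=tuple)
    ranked: bool = False

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a.locus != self.locus:
                raise ValueError(
                    f"allele {a} does not belong to locus {self.locus}"
                )

    @property
    def is_empty(self) -> bool:
        return len(self.alleles) == 0

    def __len__(self) -> int:
        return len(self.alleles)

    def truncated(self, field_level: int) -> "LocusGenotype":
        """Genotype with every allele truncated to `field_level` fields."""
        return LocusGenotype(
            locus=self.locus,
            alleles=tuple(truncate_allele(a, field_level) for a in self.alleles),
            ranked=self.ranked,
        )

    def max_depth(self) -> int:
        """Deepest field resolution among the alleles (0 when empty)."""
        return max((a.depth for a in self.alleles), default=0)


def genotype(locus: str, *names: str, ranked: bool = False) -> LocusGenotype:
    """Convenience constructor from allele name strings."""
    return LocusGenotype(
        locus=locus,
        alleles=tuple(parse_allele(n) for n in names),
        ranked=ranked,
    )
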