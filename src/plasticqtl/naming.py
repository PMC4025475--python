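"""Chromosome labels and locus notation.

Yeast chromosomes are conventionally written as roman numerals (chrI..chrXVI);
internally we use arabic integers 1..16.  Loci are printed in the
``chrXIV(465,189)`` style: roman chromosome label and 1-based bp position with
thousands separators.
"""

from __future__ import annotations

import re

ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
    "XVII", "XVIII", "XIX", "XX",
]
_ROMAN_TO_INT = {r: i + 1 for i, r in enumerate(ROMAN)}

_LOCUS_RE = re.compile(r"^chr([0-9IVXLC]+)\(([\d,]+)\)$")


def chrom_to_int(label: object) -> int:
    """Normalize a chromosome label (roman or arabic, with/without 'chr') to an int.

    >>> chrom_to_int("chrXIV"), chrom_to_int("II"), chrom_to_int(3), chrom_to_int("7")
    (14, 2, 3, 7)
    """
    if isinstance(label, (int,)) and not isinstance(label, bool):
        return int(label)
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return int(s)
    su = s.upper()
    if su in _ROMAN_TO_INT:
        return _ROMAN_TO_INT[su]
    raise ValueError(f"unrecognized chromosome label: {label!r}")


def chrom_to_roman(chrom: int) -> str:
    """Arabic chromosome number to roman numeral label (1 -> 'I')."""
    if not 1 <= int(chrom) <= len(ROMAN):
        raise ValueError(f"chromosome number out of range: {chrom}")
    return ROMAN[int(chrom) - 1]


def format_locus(chrom: int, position_bp: int) -> str:
    """Format a locus as e.g. ``chrXIV(465,189)``."""
    return f"chr{chrom_to_roman(chrom)}({int(position_bp):,})"


def parse_locus(s: str) -> tuple[int, int]:
    """Parse ``chrXIV(465,189)`` (roman or arabic chromosome) to ``(14, 465189)``."""
    m = _LOCUS_RE.match(s.strip())
    if m is None:
        raise ValueError(f"unparseable locus string: {s!r}")
    return chrom_to_int(m.group(1)), int(m.group(2).replace(",", ""))
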