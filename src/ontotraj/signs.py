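"""Allometric sign patterns.

A sign pattern summarises, per variable, whether growth is positively
allometric (``+``), isometric (``=``) or negatively allometric (``−``),
with ``?`` for variables that could not be assessed.  Patterns are written
positionally in the canonical variable order so that a printed string such
as ``++−+=−−−−−+−++`` is directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

POSITIVE = "+"
ISOMETRIC = "="
NEGATIVE = "−"  # U+2212 MINUS SIGN, used on output
MISSING = "?"

# ASCII hyphen-minus is accepted interchangeably with U+2212 on input.
_INPUT_ALIASES = {
    "+": POSITIVE,
    "=": ISOMETRIC,
    "-": NEGATIVE,
    "−": NEGATIVE,
    "?": MISSING,
}

_SYMBOLS = (POSITIVE, ISOMETRIC, NEGATIVE, MISSING)


@dataclass(frozen=True)
class SignPattern:
    """Per-variable allometric signs plus derived totals."""

    signs: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [s for s in self.signs if s not in _SYMBOLS]
        if bad:
            raise ValueError(f"invalid sign symbol(s): {bad!r}")

    @property
    def n_positive(self) -> int:
        return sum(1 for s in self.signs if s == POSITIVE)

    @property
    def n_isometric(self) -> int:
        return sum(1 for s in self.signs if s == ISOMETRIC)

    @property
    def n_negative(self) -> int:
        return sum(1 for s in self.signs if s == NEGATIVE)

    @property
    def n_missing(self) -> int:
        return sum(1 for s in self.signs if s == MISSING)

    @property
    def totals(self) -> tuple[int, int, int]:
        """(nP, nI, nN), excluding missing positions."""
        return (self.n_positive, self.n_isometric, self.n_negative)

    @property
    def totals_string(self) -> str:
        p, i, n = self.totals
        return f"{p}P,{i}I,{n}N"

    def render(self) -> str:
        """Positional string with U+2212 for negative allometry."""
        return "".join(self.signs)

    def __len__(self) -> int:
        return len(self.signs)


def parse_sign_string(text: str) -> SignPattern:
    """Parse a positional sign string over the alphabet ``+ = − ?``.

    Both ASCII ``-`` and U+2212 are accepted for negative allometry.
    Whitespace is ignored.  Any other character raises ``ValueError``.
    """
    signs = []
    for ch in text:
        if ch.isspace():
            continue
        if ch not in _INPUT_ALIASES:
            raise ValueError(f"invalid character {ch!r} in sign string {text!r}")
        signs.append(_INPUT_ALIASES[ch])
    return SignPattern(tuple(signs))


def render_sign_string(pattern: SignPattern) -> str:
    return pattern.render()


def summarize_signs(pattern: SignPattern) -> tuple[int, int, int]:
    """(nP, nI, nN) counts; missing positions are excluded."""
    return pattern.totals
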