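"""Visual-acuity conversions and VA-based group assignment.

ETDRS letter scores relate to logMAR through the standard identity
``letters = 85 - 50 * logMAR``; one ETDRS line is 5 letters (0.1 logMAR).
Snellen fractions convert via ``logMAR = log10(denominator / numerator)``,
so 20/20 -> 85 letters, 20/25 -> 80 and 20/40 -> 70.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from ezquant.errors import DomainError, ParseError

_SNELLEN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")

#: letters per ETDRS line
LINE_LETTERS = 5


@dataclass(frozen=True)
class VAGroups:
    """Letter thresholds for the cross-sectional and longitudinal groupings.

    ``excellent_min_letters``/``worse_max_letters`` split eyes into
    excellent (>=80 letters, 20/25 or better) and worse (<=70 letters,
    20/40 or worse) acuity, leaving an intermediate band that subgroup
    analyses exclude. A loss of >= ``loss_2line_letters`` between visits is
    substantial worsening; a loss below ``line_letters`` (including any
    improvement) is stable.
    """

    excellent_min_letters: int = 80
    worse_max_letters: int = 70
    line_letters: int = LINE_LETTERS
    loss_2line_letters: int = 2 * LINE_LETTERS
    stable_max_loss_letters: int = LINE_LETTERS - 1

    def __post_init__(self) -> None:
        if self.worse_max_letters >= self.excellent_min_letters:
            raise DomainError("worse_max_letters must be below excellent_min_letters")
        if self.loss_2line_letters != 2 * self.line_letters:
            raise DomainError("loss_2line_letters must equal two lines")


def _round_half_away(x: float) -> int:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def snellen_to_letters(snellen: str) -> int:
    """Convert a Snellen fraction string to an ETDRS letter score.

    Parameters
    ----------
    snellen:
        A fraction such as ``"20/40"``. The denominator must be positive.

    Returns
    -------
    int
        ``round(85 - 50 * log10(D / N))``, rounded half away from zero.
    """
    m = _SNELLEN_RE.match(snellen)
    if not m:
        raise ParseError(f"malformed Snellen string {snellen!r}")
    num, den = float(m.group(1)), float(m.group(2))
    if num <= 0 or den <= 0:
        raise ParseError(f"Snellen fraction must be positive: {snellen!r}")
    logmar = math.log10(den / num)
    return _round_half_away(85.0 - 50.0 * logmar)


def letters_to_logmar(letters: float) -> float:
    """Inverse of the letter map before rounding: ``(85 - letters) / 50``."""
    if not 0 <= letters <= 100:
        raise DomainError(f"letters {letters} outside [0, 100]")
    return (85.0 - letters) / 50.0


def classify_va_group(letters: int, groups: VAGroups = VAGroups()) -> str:
    """Assign an eye to 'excellent', 'worse' or 'intermediate' acuity."""
    if letters >= groups.excellent_min_letters:
        return "excellent"
    if letters <= groups.worse_max_letters:
        return "worse"
    return "intermediate"


def classify_va_change(letters_y0: int, letters_y5: int,
                       groups: VAGroups = VAGroups()) -> str:
    """Classify the between-visit change in acuity.

    A loss of two lines or more (>=10 letters) is ``loss_ge_2_lines``;
    less than one line of worsening, improvement included, is
    ``stable_le_1_line``; losses of one to under two lines fall in an
    ``intermediate`` band excluded from the longitudinal comparison.
    """
    loss = letters_y0 - letters_y5
    if loss >= groups.loss_2line_letters:
        return "loss_ge_2_lines"
    if loss <= groups.stable_max_loss_letters:
        return "stable_le_1_line"
    return "intermediate"
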