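"""Validation rule codes, issue records and the parse error type.

Kept in a leaf module so that both the parser and the validator can use
them without importing each other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["RuleCode", "ValidationIssue", "GTrackParseError", "Severity"]


class RuleCode(str, enum.Enum):
    """Closed list of validation rules.

    R1–R15 are the conformance rules; SYNTAX and HEADER cover malformed
    lines and unknown/invalid header variables, which make a file
    unparseable before any rule can be checked.
    """

    R1 = "R1"    # column set must match the declared track type
    R2 = "R2"    # edges column requires the id column
    R3 = "R3"    # equal column count on every data line
    R4 = "R4"    # id uniqueness
    R5 = "R5"    # edge targets resolve to existing ids
    R6 = "R6"    # edge reciprocity when undirected
    R7 = "R7"    # sortedness when declared
    R8 = "R8"    # no overlaps when declared
    R9 = "R9"    # dense types have bounding regions and tile them exactly
    R10 = "R10"  # value/edge-weight cells parse per declared type
    R11 = "R11"  # fixed-size data line byte length
    R12 = "R12"  # elements inside their bounding region
    R13 = "R13"  # bounding regions non-overlapping
    R14 = "R14"  # strand cell in {+, -, .}
    R15 = "R15"  # (warning) length-1 segments under formal-model strictness
    SYNTAX = "SYNTAX"
    HEADER = "HEADER"

    def __str__(self) -> str:
        return self.value


class Severity(str, enum.Enum):
    ERROR = "error"
    WARNING = "warning"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ValidationIssue:
    """One located rule violation."""

    code: RuleCode
    severity: Severity
    message: str
    line_number: int | None = None

    def __str__(self) -> str:
        line = self.line_number if self.line_number is not None else "-"
        return f"{line}\t{self.code}\t{self.message}"

    @property
    def sort_key(self) -> tuple[int, str]:
        return (
            self.line_number if self.line_number is not None else 10**9,
            self.code.value,
        )


class GTrackParseError(ValueError):
    """A structural problem that prevents building a document."""

    def __init__(
        self,
        message: str,
        code: RuleCode = RuleCode.SYNTAX,
        line_number: int | None = None,
    ) -> None:
        super().__init__(message)
        self.code = code
        self.line_number = line_number
        self.message = message

    def as_issue(self) -> ValidationIssue:
        return ValidationIssue(
            code=self.code,
            severity=Severity.ERROR,
            message=self.message,
            line_number=self.line_number,
        )
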