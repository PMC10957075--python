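"""Antibody Liability Reference: liability motif definitions and matchers.

The reference is a small catalogue of amino-acid motifs associated with
chemical degradation risks in antibody variable domains (deamidation,
isomerization, fragmentation, hydrolysis, oxidation, N-linked glycosylation,
unpaired cysteines and integrin-binding motifs).  Each entry carries a
severity label (high / medium / low), a scope (CDRs only, or the whole
variable fragment) and either a sequence pattern or a positional-cysteine
rule.  The default reference ships as a versioned TSV data file so users can
extend it with in-house motifs.

Pattern dialect
---------------
Patterns are written over the 20 single-letter amino-acid codes and support
exactly three constructs:

* literal residues: ``DP``
* bracketed classes, optionally negated: ``N[GS]``, ``N[^P][ST]``
* top-level alternation: ``GPR|RGD|RYD|LDV|DGE|KGD|NGR``

No quantifiers, no nesting.  Every pattern therefore denotes a finite set of
fixed-length strings, which :func:`expand_pattern` enumerates; this keeps the
dialect auditable and permits exhaustive testing of the compiled matchers.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "SeverityLevel",
    "LiabilityMotif",
    "LiabilityReference",
    "ReferenceError",
    "compile_reference",
    "expand_pattern",
    "load_reference",
]


class ReferenceError(ValueError):
    """Raised for malformed liability-reference entries or files."""


class SeverityLevel(str, enum.Enum):
    """Closed three-level severity scale."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


_SCOPES = ("cdrs", "fv")
_RULE_KINDS = ("motif_scan", "conserved_cys_missing", "conserved_cys_extra")

# One token: a literal residue, or a (possibly negated) class.
_TOKEN_RE = re.compile(r"\[(\^?)([A-Z]+)\]|([A-Z])")


def _parse_branch(branch: str, pattern: str) -> list[frozenset[str]]:
    """Parse one alternation branch into a list of residue sets."""
    tokens: list[frozenset[str]] = []
    pos = 0
    while pos < len(branch):
        m = _TOKEN_RE.match(branch, pos)
        if m is None:
            raise ReferenceError(
                f"pattern {pattern!r}: cannot parse at {branch[pos:]!r}"
            )
        if m.group(3):
            letters = m.group(3)
            negated = False
        else:
            letters = m.group(2)
            negated = bool(m.group(1))
        for letter in letters:
            if letter not in AMINO_ACIDS:
                raise ReferenceError(
                    f"pattern {pattern!r}: {letter!r} is not a standard amino acid"
                )
        residues = frozenset(letters)
        if negated:
            residues = frozenset(AMINO_ACIDS) - residues
        tokens.append(residues)
        pos = m.end()
    if not tokens:
        raise ReferenceError(f"pattern {pattern!r}: empty branch")
    return tokens


@dataclass(frozen=True)
class LiabilityMotif:
    """One entry of the liability reference.

    Parameters
    ----------
    tag : str
        Short unique identifier (e.g. ``DeAmdH``, ``Ngly``).
    name : str
        Human-readable name.
    severity : SeverityLevel
    pattern : str
        Sequence pattern (empty for positional-cysteine rules).
    scope : {"cdrs", "fv"}
        Where a match is reported: only when touching a CDR, or anywhere in
        the variable fragment (IMGT 1-128).
    rule_kind : {"motif_scan", "conserved_cys_missing", "conserved_cys_extra"}
    """

    tag: str
    name: str
    severity: SeverityLevel
    pattern: str
    scope: str
    rule_kind: str = "motif_scan"
    # parsed branches: list of [residue-set per position]; cached at init
    _branches: tuple[tuple[frozenset[str], ...], ...] = field(
        default=(), repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.scope not in _SCOPES:
            raise ReferenceError(f"{self.tag}: unknown scope {self.scope!r}")
        if self.rule_kind not in _RULE_KINDS:
            raise ReferenceError(f"{self.tag}: unknown rule_kind {self.rule_kind!r}")
        if self.rule_kind == "motif_scan":
            if not self.pattern:
                raise ReferenceError(f"{self.tag}: motif_scan entry needs a pattern")
            branches = tuple(
                tuple(_parse_branch(b, self.pattern))
                for b in self.pattern.split("|")
            )
            object.__setattr__(self, "_branches", branches)
        elif self.pattern:
            raise ReferenceError(
                f"{self.tag}: positional-cysteine rules carry no pattern"
            )

    @property
    def is_scan(self) -> bool:
        return self.rule_kind == "motif_scan"

    def finditer(self, sequence: str) -> Iterator[tuple[int, str]]:
        """Yield ``(start_index, matched_string)`` for every (overlapping)
        occurrence of the pattern in *sequence*, in order of start index."""
        if not self.is_scan:
            raise ReferenceError(f"{self.tag}: not a motif_scan rule")
        n = len(sequence)
        for start in range(n):
            for branch in self._branches:
                k = len(branch)
                if start + k > n:
                    continue
                window = sequence[start : start + k]
                if all(ch in allowed for ch, allowed in zip(window, branch)):
                    yield start, window
                    break  # at most one report per start position


def expand_pattern(motif: LiabilityMotif) -> set[str]:
    """Enumerate every concrete string the motif pattern matches.

    Negated classes expand over the 19 permitted residues.  Raises
    :class:`ReferenceError` when called on a positional-cysteine rule.
    """
    if not motif.is_scan:
        raise ReferenceError(
            f"{motif.tag}: positional-cysteine rules have no finite expansion"
        )
    out: set[str] = set()
    for branch in motif._branches:
        strings = [""]
        for residues in branch:
            strings = [s + r for s in strings for r in sorted(residues)]
        out.update(strings)
    return out


@dataclass(frozen=True)
class LiabilityReference:
    """Ordered, tag-unique collection of liability motifs."""

    entries: tuple[LiabilityMotif, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        tags = [e.tag for e in self.entries]
        dupes = {t for t in tags if tags.count(t) > 1}
        if dupes:
            raise ReferenceError(f"duplicate tags in reference: {sorted(dupes)}")

    def __iter__(self) -> Iterator[LiabilityMotif]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, tag: str) -> LiabilityMotif:
        for e in self.entries:
            if e.tag == tag:
                return e
        raise KeyError(tag)

    @property
    def scan_entries(self) -> tuple[LiabilityMotif, ...]:
        return tuple(e for e in self.entries if e.is_scan)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# Antibody Liability Reference, v{self.version}\n")
            fh.write("# tag\tname\tseverity\tpattern\tscope\trule_kind\n")
            for e in self.entries:
                fh.write(
                    f"{e.tag}\t{e.name}\t{e.severity.value}\t{e.pattern}\t"
                    f"{e.scope}\t{e.rule_kind}\n"
                )


def _parse_reference_text(text: str, version: str = "1") -> LiabilityReference:
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            m = re.match(r"#\s*Antibody Liability Reference, v(\S+)", line)
            if m:
                version = m.group(1)
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ReferenceError(
                f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}"
            )
        tag, name, severity, pattern, scope, rule_kind = parts
        try:
            sev = SeverityLevel(severity)
        except ValueError:
            raise ReferenceError(
                f"line {lineno} ({tag}): unknown severity {severity!r}"
            ) from None
        entries.append(
            LiabilityMotif(
                tag=tag, name=name, severity=sev,
                pattern=pattern, scope=scope, rule_kind=rule_kind,
            )
        )
    return LiabilityReference(entries=tuple(entries), version=version)


def load_reference(path: str | Path) -> LiabilityReference:
    """Read a liability reference from a tab-separated text file."""
    text = Path(path).read_text(encoding="utf-8")
    return _parse_reference_text(text)


def compile_reference() -> LiabilityReference:
    """Return the default (built-in) Antibody Liability Reference.

    Thirteen categories: deamidation at three severities, fragmentation at
    two, and one severity each for isomerization, hydrolysis, Trp/Met
    oxidation, N-linked glycosylation sequon, integrin-binding motifs and the
    two conserved-cysteine rules (missing / extra Cys relative to IMGT 23
    and 104).
    """
    text = (
        resources.files("ablint.data")
        .joinpath("liability_reference.tsv")
        .read_text(encoding="utf-8")
    )
    return _parse_reference_text(text)
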