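"""IMGT-numbered chains, region delimitation, numbered-input parsing and QC.

Numbering itself is delegated to external tools (ANARCI-style CSV or
AIRR-Rearrangement TSV input); this module represents the result.  The IMGT
unique numbering assigns positions 1-128 to the variable domain, with the
conserved cysteines at 23 and 104 and the CDRs delimited as:

======  =========
region  positions
======  =========
FR1     1-26
CDR1    27-38
FR2     39-55
CDR2    56-65
FR3     66-104
CDR3    105-117
FR4     118-128
======  =========

Insertion codes (e.g. 111A) inherit the region of their base number, and
their order is taken from the numbered input as given — long-CDR3 insertion
conventions differ between tools, so we never re-sort.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .reference import AMINO_ACIDS

__all__ = [
    "ImgtPosition",
    "NumberedChain",
    "AntibodyUnit",
    "REGIONS",
    "CDR_REGIONS",
    "region_of",
    "attribute_region",
    "parse_numbered_input",
    "write_numbered_csv",
    "qc_filter",
    "QCResult",
]

# (region, first, last) — contiguous, non-overlapping, covering 1-128
REGIONS: tuple[tuple[str, int, int], ...] = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
    ("FR4", 118, 128),
)
CDR_REGIONS = frozenset({"CDR1", "CDR2", "CDR3"})

_CHAIN_TYPES = ("H", "K", "L")


@dataclass(frozen=True)
class ImgtPosition:
    """An IMGT position: base number 1-128 plus optional insertion letter."""

    number: int
    insertion: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.number <= 128:
            raise ValueError(f"IMGT position {self.number} outside 1-128")
        if self.insertion is not None and not re.fullmatch(
            r"[A-Z]", self.insertion
        ):
            raise ValueError(f"bad insertion code {self.insertion!r}")

    def __str__(self) -> str:
        return f"{self.number}{self.insertion or ''}"

    @classmethod
    def parse(cls, text: str) -> "ImgtPosition":
        m = re.fullmatch(r"(\d+)\s*([A-Za-z]?)", text.strip())
        if not m:
            raise ValueError(f"cannot parse IMGT position {text!r}")
        ins = m.group(2).upper() or None
        return cls(int(m.group(1)), ins)


def region_of(pos: ImgtPosition | int) -> str:
    """Region label for an IMGT position; insertions inherit their base."""
    number = pos.number if isinstance(pos, ImgtPosition) else int(pos)
    for name, lo, hi in REGIONS:
        if lo <= number <= hi:
            return name
    raise ValueError(f"IMGT position {number} outside 1-128")


def attribute_region(positions: Sequence[ImgtPosition]) -> str:
    """Classify a run of positions as ``cdr``, ``framework`` or ``boundary``.

    ``cdr`` if every position falls in a CDR, ``framework`` if none does,
    ``boundary`` if the run straddles a CDR/framework junction.
    """
    if not positions:
        raise ValueError("empty position list")
    in_cdr = [region_of(p) in CDR_REGIONS for p in positions]
    if all(in_cdr):
        return "cdr"
    if not any(in_cdr):
        return "framework"
    return "boundary"


@dataclass
class NumberedChain:
    """An IMGT-numbered variable-domain chain.

    ``residues`` is the ordered list of ``(ImgtPosition, residue)`` pairs in
    polypeptide order; positions must be strictly increasing under IMGT
    ordering except that insertion runs keep their input order.
    """

    id: str
    chain_type: str
    residues: list[tuple[ImgtPosition, str]]
    v_call: str | None = None
    j_call: str | None = None
    species_label: str | None = None

    def __post_init__(self) -> None:
        if self.chain_type not in _CHAIN_TYPES:
            raise ValueError(f"{self.id}: unknown chain type {self.chain_type!r}")
        for pos, aa in self.residues:
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.id}: non-standard residue {aa!r} at {pos}"
                )
        numbers = [p.number for p, _ in self.residues]
        if any(b < a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(f"{self.id}: IMGT base numbers not non-decreasing")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def positions(self) -> list[ImgtPosition]:
        return [p for p, _ in self.residues]

    def position_map(self) -> dict[ImgtPosition, str]:
        return {p: aa for p, aa in self.residues}

    def subgroup(self) -> str | None:
        """Germline subgroup from the V call (e.g. IGHV3-23*01 -> IGHV3)."""
        if not self.v_call:
            return None
        m = re.match(r"(IG[HKL]V\d+)", self.v_call)
        return m.group(1) if m else self.v_call.split("-")[0]

    def cdr_lengths(self) -> dict[str, int]:
        out = {"CDR1": 0, "CDR2": 0, "CDR3": 0}
        for p, _ in self.residues:
            r = region_of(p)
            if r in out:
                out[r] += 1
        return out


@dataclass
class AntibodyUnit:
    """One antibody molecule: a heavy and/or a light numbered chain."""

    heavy: NumberedChain | None = None
    light: NumberedChain | None = None
    structure_ref: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.heavy is None and self.light is None:
            raise ValueError("AntibodyUnit needs at least one chain")
        if self.heavy is not None and self.heavy.chain_type != "H":
            raise ValueError("heavy slot holds a non-H chain")
        if self.light is not None and self.light.chain_type not in ("K", "L"):
            raise ValueError("light slot holds a non-K/L chain")
        if not self.id:
            src = self.heavy or self.light
            self.id = src.id

    @property
    def is_paired(self) -> bool:
        return self.heavy is not None and self.light is not None

    @property
    def chains(self) -> list[NumberedChain]:
        return [c for c in (self.heavy, self.light) if c is not None]

    @property
    def sequence(self) -> str:
        return "".join(c.sequence for c in self.chains)


# ---------------------------------------------------------------------------
# Parsing numbered input


_GAPS = {".", "-", ""}


def _locus_to_chain_type(value: str) -> str:
    v = value.strip().upper()
    if v in _CHAIN_TYPES:
        return v
    mapping = {"IGH": "H", "IGK": "K", "IGL": "L"}
    if v in mapping:
        return mapping[v]
    raise ValueError(f"unknown chain type / locus {value!r}")


def parse_numbered_input(
    source: str | Path | io.TextIOBase,
    dialect: str,
) -> tuple[list[NumberedChain], list[tuple[str, str]]]:
    """Parse pre-numbered chain records.

    Parameters
    ----------
    source : path or open text handle
    dialect : {"anarci_csv", "airr_tsv"}
        ``anarci_csv``: comma-separated with columns ``Id``, ``chain_type``,
        optional ``v_call``/``j_call``/``species``, followed by one column per
        IMGT position (headers like ``3`` or ``111A``); ``-``/``.`` are gaps.
        ``airr_tsv``: AIRR Rearrangement TSV using the IMGT-gapped amino-acid
        alignment column ``sequence_alignment_aa`` (``.`` gaps, character *i*
        is IMGT position *i*+1) with ``sequence_id``, ``locus``, ``v_call``,
        ``j_call``.

    Returns
    -------
    (chains, rejections)
        Per-record failures (unknown chain type, residues outside the 20
        standard letters, positions outside 1-128) are collected as
        ``(record_id, reason)`` pairs, not raised.
    """
    if dialect not in ("anarci_csv", "airr_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    own = False
    if isinstance(source, (str, Path)):
        fh = open(source, "r", encoding="utf-8", newline="")
        own = True
    else:
        fh = source
    try:
        if dialect == "anarci_csv":
            return _parse_anarci_csv(fh)
        return _parse_airr_tsv(fh)
    finally:
        if own:
            fh.close()


def _parse_anarci_csv(fh) -> tuple[list[NumberedChain], list[tuple[str, str]]]:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise ValueError("empty numbered-input file")
    meta_cols = {"Id", "id", "chain_type", "v_call", "j_call", "species"}
    pos_cols: list[tuple[str, ImgtPosition]] = []
    for col in reader.fieldnames:
        if col in meta_cols:
            continue
        pos_cols.append((col, ImgtPosition.parse(col)))
    chains: list[NumberedChain] = []
    rejections: list[tuple[str, str]] = []
    for row in reader:
        rid = row.get("Id") or row.get("id") or "?"
        try:
            ctype = _locus_to_chain_type(row["chain_type"])
            residues: list[tuple[ImgtPosition, str]] = []
            for col, pos in pos_cols:
                aa = (row.get(col) or "").strip().upper()
                if aa in _GAPS:
                    continue
                if aa not in AMINO_ACIDS:
                    raise ValueError(f"non-standard residue {aa!r} at {pos}")
                residues.append((pos, aa))
            chains.append(
                NumberedChain(
                    id=rid,
                    chain_type=ctype,
                    residues=residues,
                    v_call=(row.get("v_call") or None),
                    j_call=(row.get("j_call") or None),
                    species_label=(row.get("species") or None),
                )
            )
        except (ValueError, KeyError) as exc:
            rejections.append((rid, str(exc)))
    return chains, rejections


def _parse_airr_tsv(fh) -> tuple[list[NumberedChain], list[tuple[str, str]]]:
    reader = csv.DictReader(fh, delimiter="\t")
    chains: list[NumberedChain] = []
    rejections: list[tuple[str, str]] = []
    for row in reader:
        rid = row.get("sequence_id") or "?"
        try:
            locus = row.get("locus") or row.get("chain") or ""
            ctype = _locus_to_chain_type(locus)
            aligned = (row.get("sequence_alignment_aa") or "").strip()
            if len(aligned) > 128:
                raise ValueError(
                    f"IMGT-gapped alignment longer than 128 ({len(aligned)})"
                )
            residues = []
            for i, aa in enumerate(aligned.upper()):
                if aa == ".":
                    continue
                if aa not in AMINO_ACIDS:
                    raise ValueError(
                        f"non-standard residue {aa!r} at {i + 1}"
                    )
                residues.append((ImgtPosition(i + 1), aa))
            chains.append(
                NumberedChain(
                    id=rid,
                    chain_type=ctype,
                    residues=residues,
                    v_call=(row.get("v_call") or None),
                    j_call=(row.get("j_call") or None),
                    species_label=(row.get("species") or None),
                )
            )
        except ValueError as exc:
            rejections.append((rid, str(exc)))
    return chains, rejections


def write_numbered_csv(chains: Iterable[NumberedChain], path: str | Path) -> None:
    """Serialize chains in the ANARCI-style CSV dialect (round-trippable)."""
    chains = list(chains)
    seen: list[str] = []
    for c in chains:
        for p in c.positions:
            key = str(p)
            if key not in seen:
                seen.append(key)
    # column order: by base number, insertions after their base in first-seen order
    def sort_key(label: str) -> tuple[int, int]:
        pos = ImgtPosition.parse(label)
        return (pos.number, 0 if pos.insertion is None else 1 + seen.index(label))

    columns = sorted(seen, key=sort_key)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Id", "chain_type", "v_call", "j_call", "species"] + columns)
        for c in chains:
            pm = {str(p): aa for p, aa in c.residues}
            writer.writerow(
                [c.id, c.chain_type, c.v_call or "", c.j_call or "",
                 c.species_label or ""]
                + [pm.get(col, "-") for col in columns]
            )


# ---------------------------------------------------------------------------
# QC filtering

_STANDARD = set(AMINO_ACIDS)


@dataclass
class QCResult:
    """Kept records plus a per-rejection ledger of ``(id, reason)``."""

    kept: list
    ledger: list[tuple[str, str]] = field(default_factory=list)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.ledger:
            out[reason] = out.get(reason, 0) + 1
        return out


def _record_parts(record):
    """Normalize a QC input record to (id, [sequence strings], [chains])."""
    if isinstance(record, AntibodyUnit):
        return record.id, [c.sequence for c in record.chains], record.chains
    if isinstance(record, NumberedChain):
        return record.id, [record.sequence], [record]
    if isinstance(record, tuple) and len(record) == 2:
        return record[0], [str(record[1])], []
    if hasattr(record, "id") and hasattr(record, "seq"):  # Bio.SeqRecord
        return record.id, [str(record.seq)], []
    raise TypeError(f"cannot QC a {type(record).__name__}")


def qc_filter(records: Iterable, paired: bool = False) -> QCResult:
    """Apply the standard pre-analysis filters, in order.

    Rules (first failing rule is the recorded reason):

    1. ``length`` — every chain sequence length in [40, 1000];
    2. ``exclamation`` — no ``'!'`` character;
    3. ``residue`` — only the 20 standard amino-acid letters;
    4. ``numbering`` — numbering and germline assignment succeeded
       (parsed chain with a ``v_call``); skipped for raw, un-numbered input;
    5. ``missing_cdr`` — all three CDRs non-empty in the numbered chain;
    6. ``chain_pairing`` — for paired input, exactly one H and one K/L chain;
    7. ``duplicate`` — exact variable-domain string (paired: concatenated
       H+L) already seen.

    Rejections are data, not exceptions; the result is idempotent (filtering
    the kept set again changes nothing).
    """
    kept: list = []
    ledger: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in records:
        rid, seqs, chains = _record_parts(record)
        reason = None
        for seq in seqs:
            if not 40 <= len(seq) <= 1000:
                reason = "length"
                break
            if "!" in seq:
                reason = "exclamation"
                break
            if any(ch not in _STANDARD for ch in seq):
                reason = "residue"
                break
        if reason is None and chains:
            for chain in chains:
                if chain.v_call is None:
                    reason = "numbering"
                    break
                if any(n == 0 for n in chain.cdr_lengths().values()):
                    reason = "missing_cdr"
                    break
        if reason is None and paired:
            if isinstance(record, AntibodyUnit):
                if not record.is_paired:
                    reason = "chain_pairing"
            elif chains:
                types = sorted(c.chain_type for c in chains)
                if not (len(types) == 2 and types[0] == "H" and types[1] in "KL"):
                    reason = "chain_pairing"
        if reason is None:
            key = "".join(seqs)
            if key in seen:
                reason = "duplicate"
            else:
                seen.add(key)
        if reason is None:
            kept.append(record)
        else:
            ledger.append((rid, reason))
    return QCResult(kept=kept, ledger=ledger)


def write_qc_ledger(result: QCResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "reason"])
        writer.writerows(result.ledger)
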