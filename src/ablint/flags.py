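"""Germline and therapeutic low-risk flags.

A detected liability motif is not necessarily a real degradation risk.  Two
sequence-only flags mark hits that are plausibly benign:

* **germline** — the motif exists at the identical IMGT position, with the
  identical residues, in a human germline V or J segment.  Only V and J are
  consulted (D-segment identification is unreliable), so most of CDR-H3 can
  never be germline-flagged.
* **therapeutic** — the (motif, IMGT start position) occurs in strictly more
  than 5% of chains of a marketed-therapeutic panel, i.e. molecules carrying
  it cleared the clinic and manufacturing.

"Same IMGT position" means exact (number, insertion) equality for every
residue of the motif, and exact residue identity — the flag asserts the
motif itself exists in germline, not a homolog.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .detect import LiabilityHit, check_conserved_cysteines, scan_chain
from .numbering import ImgtPosition, NumberedChain
from .reference import AMINO_ACIDS, LiabilityReference

__all__ = [
    "FlagConfig",
    "GermlineReference",
    "PositionalFrequencyTable",
    "flag_germline",
    "build_therapeutic_table",
    "flag_therapeutic",
]


@dataclass(frozen=True)
class FlagConfig:
    """Thresholds and policies for the three flags.

    therapeutic_threshold : fraction, strict ``>`` (default 0.05: "more than
        5% of marketed therapeutics").
    exposure_threshold : fraction of relative SASA, strict ``>`` (default
        0.075: exposed above 7.5%).
    germline_mode : "assigned" consults the chain's assigned top V and J;
        "any" consults every human segment pair.
    partial_policy : whether a partially buried motif counts as low-risk.
    """

    therapeutic_threshold: float = 0.05
    exposure_threshold: float = 0.075
    germline_mode: str = "assigned"
    partial_policy: str = "not_benign"

    def __post_init__(self) -> None:
        for name in ("therapeutic_threshold", "exposure_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.germline_mode not in ("assigned", "any"):
            raise ValueError(f"unknown germline_mode {self.germline_mode!r}")
        if self.partial_policy not in ("not_benign", "benign"):
            raise ValueError(f"unknown partial_policy {self.partial_policy!r}")


@dataclass
class GermlineReference:
    """IMGT-numbered human germline V and J segments, keyed by allele name."""

    v_segments: dict[str, NumberedChain] = field(default_factory=dict)
    j_segments: dict[str, NumberedChain] = field(default_factory=dict)

    def add(self, segment: NumberedChain, kind: str | None = None) -> None:
        if kind is None:
            kind = "J" if re.match(r"IG[HKL]J", segment.id) else "V"
        (self.v_segments if kind == "V" else self.j_segments)[segment.id] = segment

    def get_v(self, name: str) -> NumberedChain:
        return self._lookup(self.v_segments, name, "V")

    def get_j(self, name: str) -> NumberedChain:
        return self._lookup(self.j_segments, name, "J")

    @staticmethod
    def _lookup(table: dict[str, NumberedChain], name: str, kind: str) -> NumberedChain:
        if name in table:
            return table[name]
        # tolerate calls without allele suffix (IGHV3-1 vs IGHV3-1*01)
        for key, seg in table.items():
            if key.split("*")[0] == name.split("*")[0]:
                return seg
        raise KeyError(f"{kind} segment {name!r} not in germline reference")

    @classmethod
    def from_fasta(cls, path: str | Path, chain_type_of=None) -> "GermlineReference":
        """Load IMGT-gapped V/J segment FASTA ('.' gaps, char i = position i+1).

        Headers are allele names (e.g. ``IGHV3-1*01``); the locus letter in
        the name determines the chain type unless *chain_type_of* overrides.
        """
        ref = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id
            m = re.match(r"IG([HKL])([VJ])", name)
            if not m:
                raise ValueError(f"cannot infer segment kind from {name!r}")
            ctype = m.group(1) if chain_type_of is None else chain_type_of(name)
            kind = m.group(2)
            residues = []
            for i, aa in enumerate(str(rec.seq).upper()):
                if aa == ".":
                    continue
                if aa not in AMINO_ACIDS:
                    raise ValueError(f"{name}: non-standard residue {aa!r}")
                residues.append((ImgtPosition(i + 1), aa))
            ref.add(
                NumberedChain(id=name, chain_type=ctype, residues=residues,
                              v_call=name if kind == "V" else None),
                kind=kind,
            )
        return ref

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for table in (self.v_segments, self.j_segments):
                for name, seg in table.items():
                    pm = {p.number: aa for p, aa in seg.residues}
                    top = max(pm) if pm else 0
                    gapped = "".join(pm.get(i, ".") for i in range(1, top + 1))
                    fh.write(f">{name}\n{gapped}\n")


def _segment_pairs(hit_chain: NumberedChain, germ: GermlineReference, mode: str):
    """Candidate (V, J) segment pairs to consult for a germline match."""
    if mode == "assigned":
        if not hit_chain.v_call:
            raise ValueError(
                f"{hit_chain.id}: germline_mode=assigned requires a v_call"
            )
        v = germ.get_v(hit_chain.v_call)
        j = germ.get_j(hit_chain.j_call) if hit_chain.j_call else None
        yield v, j
    elif mode == "any":
        js = list(germ.j_segments.values()) or [None]
        for v in germ.v_segments.values():
            for j in js:
                yield v, j
    else:
        raise ValueError(f"unknown germline mode {mode!r}")


def flag_germline(
    hit: LiabilityHit,
    chain: NumberedChain,
    germ: GermlineReference,
    mode: str = "assigned",
) -> bool:
    """True iff every residue of the hit exists at the identical IMGT
    position with the identical amino acid in a consulted V/J segment pair.

    Positions covered by neither V nor J (most of CDR-H3) can never match.
    """
    if not hit.residues:
        raise ValueError("germline flag needs a motif hit with residues")
    for v, j in _segment_pairs(chain, germ, mode):
        covered = dict(v.residues)
        if j is not None:
            covered.update(dict(j.residues))
        if all(covered.get(pos) == aa for pos, aa in hit.residues):
            return True
    return False


@dataclass
class PositionalFrequencyTable:
    """(chain class, motif tag, IMGT start) -> frequency among a panel.

    Counts are per chain (a chain carrying a motif twice at two positions
    contributes one count to each position); light-chain loci K and L are
    pooled into one ``light`` class.  Exact rational counts are stored next
    to the float frequency.
    """

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)
    provenance: str = ""

    def frequency(self, chain_class: str, motif_tag: str, start: ImgtPosition | str
                  ) -> float:
        denom = self.denominators.get(chain_class)
        if not denom:
            return 0.0
        count = self.counts.get((chain_class, motif_tag, str(start)), 0)
        return count / denom

    def exact_frequency(self, chain_class, motif_tag, start) -> Fraction:
        denom = self.denominators.get(chain_class, 0)
        if not denom:
            return Fraction(0)
        return Fraction(
            self.counts.get((chain_class, motif_tag, str(start)), 0), denom
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(
                ["chain_class", "motif_tag", "imgt_start",
                 "count", "denominator", "frequency"]
            )
            for (cls_, tag, start), count in sorted(self.counts.items()):
                denom = self.denominators[cls_]
                w.writerow([cls_, tag, start, count, denom, f"{count / denom:.6f}"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionalFrequencyTable":
        table = cls()
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = (row["chain_class"], row["motif_tag"], row["imgt_start"])
                table.counts[key] = int(row["count"])
                table.denominators[row["chain_class"]] = int(row["denominator"])
        return table


def build_therapeutic_table(
    panel: Iterable[NumberedChain],
    ref: LiabilityReference,
    provenance: str = "",
    pool_light: bool = True,
) -> PositionalFrequencyTable:
    """Scan a marketed-therapeutic panel into a positional frequency table.

    Each (motif tag, IMGT start) is counted at most once per chain; the
    denominator is the number of panel chains of that class.  Extra-cysteine
    hits carry a position and are counted; missing-cysteine hits have none
    and are not.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty therapeutic panel")
    table = PositionalFrequencyTable(provenance=provenance)
    for chain in panel:
        cls_ = "H" if chain.chain_type == "H" else (
            "light" if pool_light else chain.chain_type
        )
        table.denominators[cls_] = table.denominators.get(cls_, 0) + 1
        keys = set()
        for hit in scan_chain(chain, ref) + check_conserved_cysteines(chain):
            if hit.start is None:
                continue
            keys.add((cls_, hit.motif_tag, str(hit.start)))
        for key in keys:
            table.counts[key] = table.counts.get(key, 0) + 1
    return table


def flag_therapeutic(
    hit: LiabilityHit,
    table: PositionalFrequencyTable,
    cfg: FlagConfig | None = None,
) -> bool:
    """True iff the panel frequency of (chain class, motif, start) is
    strictly greater than the threshold; absent entries have frequency 0."""
    if hit.start is None:
        raise ValueError("therapeutic flag needs a positioned hit")
    cfg = cfg or FlagConfig()
    freq = table.frequency(hit.chain_class, hit.motif_tag, hit.start)
    return freq > cfg.therapeutic_threshold
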