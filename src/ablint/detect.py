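"""Scan numbered chains against the liability reference.

Motif adjacency is defined on polypeptide chain order, not on IMGT numeric
adjacency: chemistry acts on consecutive residues, and IMGT numbering gaps
are notation only.  A CDR-scope motif is reported when at least one matched
residue lies in a CDR (the default "inclusive" policy, which captures
boundary liabilities straddling a framework/CDR junction); a strict mode
requiring all residues in a CDR is available.  Overlapping matches of
different reference entries are all reported independently — e.g. ``NGS``
yields both a high-severity deamidation hit (``NG``) and a glycosylation
sequon hit (``NGS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .numbering import (
    AntibodyUnit,
    CDR_REGIONS,
    ImgtPosition,
    NumberedChain,
    attribute_region,
    region_of,
)
from .reference import LiabilityReference, SeverityLevel

__all__ = [
    "FlagAnnotation",
    "LiabilityHit",
    "SequenceProfile",
    "ProfileConfig",
    "ConfigurationError",
    "scan_chain",
    "check_conserved_cysteines",
    "profile_antibody",
]

CONSERVED_CYS_POSITIONS = (ImgtPosition(23), ImgtPosition(104))


class ConfigurationError(ValueError):
    """A flag was requested without the inputs it needs."""


@dataclass
class FlagAnnotation:
    """Low-risk flag state of one hit.

    ``None`` means the flag was not applied; booleans / the surface class are
    set by the flag machinery.  ``surface`` is one of ``exposed``, ``buried``,
    ``partial``, ``unknown``.
    """

    germline: bool | None = None
    therapeutic: bool | None = None
    surface: str | None = None

    def benign_under(self, combo, partial_policy: str = "not_benign") -> bool:
        """True iff any flag in *combo* marks the hit low-risk."""
        if "germline" in combo and self.germline is True:
            return True
        if "therapeutic" in combo and self.therapeutic is True:
            return True
        if "surface" in combo:
            if self.surface == "buried":
                return True
            if self.surface == "partial" and partial_policy == "benign":
                return True
        return False


@dataclass
class LiabilityHit:
    """One detected liability occurrence on one chain.

    ``residues`` are consecutive in chain sequence order; empty for a
    missing-cysteine (mCys) hit, which has no position.
    """

    chain_id: str
    chain_type: str
    motif_tag: str
    severity: SeverityLevel
    residues: list[tuple[ImgtPosition, str]]
    attribution: str  # framework | cdr | boundary | fv
    flags: FlagAnnotation = field(default_factory=FlagAnnotation)

    @property
    def start(self) -> ImgtPosition | None:
        return self.residues[0][0] if self.residues else None

    @property
    def matched(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def chain_class(self) -> str:
        return "H" if self.chain_type == "H" else "light"


def scan_chain(
    chain: NumberedChain,
    ref: LiabilityReference,
    policy: str = "inclusive",
) -> list[LiabilityHit]:
    """Match every sequence-pattern reference entry against the chain.

    Parameters
    ----------
    policy : {"inclusive", "strict"}
        CDR-scope reporting rule: ``inclusive`` reports a match when >= 1
        matched residue is in a CDR; ``strict`` requires all of them.

    Conserved-cysteine rules are handled separately by
    :func:`check_conserved_cysteines`.
    """
    if policy not in ("inclusive", "strict"):
        raise ValueError(f"unknown scope policy {policy!r}")
    seq = chain.sequence
    residues = chain.residues
    hits: list[LiabilityHit] = []
    for motif in ref.scan_entries:
        for start, matched in motif.finditer(seq):
            span = residues[start : start + len(matched)]
            span_pos = [p for p, _ in span]
            if motif.scope == "cdrs":
                in_cdr = [region_of(p) in CDR_REGIONS for p in span_pos]
                keep = any(in_cdr) if policy == "inclusive" else all(in_cdr)
                if not keep:
                    continue
            hits.append(
                LiabilityHit(
                    chain_id=chain.id,
                    chain_type=chain.chain_type,
                    motif_tag=motif.tag,
                    severity=motif.severity,
                    residues=list(span),
                    attribution=attribute_region(span_pos),
                )
            )
    return hits


def check_conserved_cysteines(chain: NumberedChain) -> list[LiabilityHit]:
    """Positional-cysteine rules: missing Cys at IMGT 23/104 (``mCys``) and
    Cys anywhere else (``xCys``).  Both are high severity; attribution is
    the whole variable fragment."""
    pm = chain.position_map()
    hits: list[LiabilityHit] = []
    for pos in CONSERVED_CYS_POSITIONS:
        if pm.get(pos) != "C":
            hits.append(
                LiabilityHit(
                    chain_id=chain.id,
                    chain_type=chain.chain_type,
                    motif_tag="mCys",
                    severity=SeverityLevel.HIGH,
                    residues=[],
                    attribution="fv",
                )
            )
    for pos, aa in chain.residues:
        if aa == "C" and pos not in CONSERVED_CYS_POSITIONS:
            hits.append(
                LiabilityHit(
                    chain_id=chain.id,
                    chain_type=chain.chain_type,
                    motif_tag="xCys",
                    severity=SeverityLevel.HIGH,
                    residues=[(pos, aa)],
                    attribution="fv",
                )
            )
    return hits


@dataclass
class ProfileConfig:
    """What to run when profiling a unit.

    Flag inputs are supplied here; requesting a flag without its input is a
    configuration error.  The surface flag additionally requires a paired
    heavy/light unit — on a single chain, interface residues would be
    misclassified as exposed.
    """

    scope_policy: str = "inclusive"
    apply_germline: bool = False
    apply_therapeutic: bool = False
    apply_surface: bool = False
    germline_reference: object | None = None  # flags.GermlineReference
    germline_mode: str = "assigned"
    therapeutic_table: object | None = None  # flags.PositionalFrequencyTable
    flag_config: object | None = None  # flags.FlagConfig
    structure: object | None = None  # surface.StructureModel


@dataclass
class SequenceProfile:
    """All hits (with flag annotations) for one antibody unit."""

    unit_id: str
    hits: list[LiabilityHit]
    chain_types: list[str] = field(default_factory=list)
    species_label: str | None = None
    subgroup: str | None = None
    is_paired: bool = False

    @property
    def n_liabilities(self) -> int:
        return len(self.hits)

    def severity_counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in SeverityLevel}
        for h in self.hits:
            out[h.severity.value] += 1
        return out

    def remaining(self, combo, partial_policy: str = "not_benign") -> int:
        return sum(
            1 for h in self.hits if not h.flags.benign_under(combo, partial_policy)
        )


def profile_antibody(
    unit: AntibodyUnit,
    ref: LiabilityReference,
    config: ProfileConfig | None = None,
) -> SequenceProfile:
    """Scan every chain of the unit and apply the configured low-risk flags."""
    from . import flags as _flags  # deferred: flags imports detect types
    from . import surface as _surface

    config = config or ProfileConfig()
    if config.apply_germline and config.germline_reference is None:
        raise ConfigurationError("germline flag requested without a germline reference")
    if config.apply_therapeutic and config.therapeutic_table is None:
        raise ConfigurationError(
            "therapeutic flag requested without a positional frequency table"
        )
    if config.apply_surface:
        if not unit.is_paired:
            raise ConfigurationError(
                "surface flag requires a paired heavy/light unit"
            )
        if config.structure is None:
            raise ConfigurationError("surface flag requested without a structure")

    fcfg = config.flag_config or _flags.FlagConfig()
    hits: list[LiabilityHit] = []
    exposures = None
    if config.apply_surface:
        exposures = _surface.residue_exposures(config.structure, fcfg)

    for chain in unit.chains:
        role = "H" if chain.chain_type == "H" else "L"
        chain_hits = scan_chain(chain, ref, config.scope_policy)
        chain_hits += check_conserved_cysteines(chain)
        for hit in chain_hits:
            if config.apply_germline:
                hit.flags.germline = (
                    _flags.flag_germline(
                        hit, chain, config.germline_reference, config.germline_mode
                    )
                    if hit.residues
                    else False
                )
            if config.apply_therapeutic:
                hit.flags.therapeutic = (
                    _flags.flag_therapeutic(hit, config.therapeutic_table, fcfg)
                    if hit.residues
                    else False
                )
            if config.apply_surface:
                hit.flags.surface = _surface.flag_surface(hit, exposures, role)
        hits.extend(chain_hits)

    any_chain = unit.heavy or unit.light
    return SequenceProfile(
        unit_id=unit.id,
        hits=hits,
        chain_types=[c.chain_type for c in unit.chains],
        species_label=any_chain.species_label,
        subgroup=(unit.heavy or unit.light).subgroup(),
        is_paired=unit.is_paired,
    )
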