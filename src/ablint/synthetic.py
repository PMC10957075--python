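"""Deterministic synthetic fixtures: germline sets, planted-motif chains,
therapeutic panels with controlled positional frequencies, toy structures
with known burial, and benchmark records with a known effect direction.

Everything the main pipeline consumes can be generated here with no
downloads, and every planted item is recorded in a ledger so downstream
recovery can be checked *exactly*.  Two ingredients make the ledgers exact:

* background residues are drawn from a liability-inert alphabet (no C, W,
  M, N, D, P or T), from which no reference motif can be assembled;
* after planting, flanking positions are locally re-sampled until a scan
  of the finished chain reproduces the intended hit set and nothing else
  (a planted ``N`` next to a background ``S`` would otherwise create an
  accidental low-severity deamidation ``SN``).

The generator emulates sample-scale properties of real repertoires (IMGT
gaps, subgroup structure, germline-inherited motifs) but not clonal
structure or somatic hypermutation statistics.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .detect import scan_chain
from .flags import GermlineReference, PositionalFrequencyTable
from .numbering import AntibodyUnit, ImgtPosition, NumberedChain, REGIONS
from .reference import LiabilityReference, compile_reference, expand_pattern
from .surface import DEFAULT_RADIUS, ResidueRef, StructureModel

__all__ = [
    "SAFE_BACKGROUND",
    "PlantSpec",
    "SyntheticSpec",
    "PlantedHit",
    "make_toy_germline_set",
    "generate_sequences",
    "generate_therapeutic_panel",
    "generate_toy_structure",
    "generate_benchmark_records",
]

# Letters from which no liability motif of the default reference can be
# formed: excludes C, W, M (single-residue motifs), N and D (deamidation /
# isomerization / sequon / most integrin branches), P (GPR) and T (TS).
SAFE_BACKGROUND = "AEFGHIKLQRSVY"

_REGION_RANGE = {name: (lo, hi) for name, lo, hi in REGIONS}


def _rng(seed: int) -> random.Random:
    return random.Random(seed)


@dataclass(frozen=True)
class PlantedHit:
    """Ledger entry: one motif occurrence deliberately present in a chain."""

    chain_id: str
    motif_tag: str
    start: str  # IMGT start position as text
    matched: str
    source: str  # "planted" | "inherited"


def _scan_key(hits) -> list[tuple[str, str, str]]:
    return sorted((h.motif_tag, str(h.start), h.matched) for h in hits)


def _ledger_key(entries) -> list[tuple[str, str, str]]:
    return sorted((e.motif_tag, e.start, e.matched) for e in entries)


def _repair_chain(
    chain: NumberedChain,
    protected: set[ImgtPosition],
    expected: list[PlantedHit],
    ref: LiabilityReference,
    rng: random.Random,
    max_rounds: int = 200,
) -> NumberedChain:
    """Re-sample unprotected residues until the scan matches the ledger."""
    want = _ledger_key(expected)
    for _ in range(max_rounds):
        hits = scan_chain(chain, ref)
        got = _scan_key(hits)
        if got == want:
            return chain
        # every discrepancy is an extra hit (plants are written verbatim);
        # re-sample its non-protected residues
        want_counts = {}
        for k in want:
            want_counts[k] = want_counts.get(k, 0) + 1
        extras = []
        for h in hits:
            k = (h.motif_tag, str(h.start), h.matched)
            if want_counts.get(k, 0) > 0:
                want_counts[k] -= 1
            else:
                extras.append(h)
        if not extras:
            raise RuntimeError(
                f"{chain.id}: planted motif destroyed during repair"
            )
        index = {pos: i for i, (pos, _) in enumerate(chain.residues)}
        for h in extras:
            for pos, _ in h.residues:
                if pos in protected:
                    continue
                i = index[pos]
                chain.residues[i] = (pos, rng.choice(SAFE_BACKGROUND))
    raise RuntimeError(f"{chain.id}: could not repair background in {max_rounds} rounds")


# ---------------------------------------------------------------------------
# Germline set

# Per-subgroup intrinsic liabilities: (motif_tag, concrete string, start pos).
# All starts lie inside CDR1/CDR2 so the CDR-scope motifs report them, and
# within V coverage (1-106) so germline self-matching covers them.
_GERMLINE_PLANTS: dict[str, list[tuple[str, str, int]]] = {
    "IGHV1": [("DeAmdH", "NS", 36)],
    "IGHV3": [("DeAmdH", "NG", 56), ("Isom", "DS", 62)],
    "IGHV4": [("MetOx", "M", 30)],
    "IGKV1": [("DeAmdM", "NT", 30)],
    "IGLV1": [("FragM", "TS", 58)],
}

# V segments cover IMGT 1-106 with a couple of standard gaps; J segments
# cover the CDR3 tail and FR4 (115-128).
_V_GAPS = (10, 73)
_V_LAST = 106
_J_FIRST = 115


def _v_positions() -> list[ImgtPosition]:
    return [ImgtPosition(n) for n in range(1, _V_LAST + 1) if n not in _V_GAPS]


def _j_positions() -> list[ImgtPosition]:
    return [ImgtPosition(n) for n in range(_J_FIRST, 129)]


def make_toy_germline_set(
    seed: int = 0,
) -> tuple[GermlineReference, list[PlantedHit]]:
    """Build a small IMGT-numbered human-like germline set plus its ledger.

    Five V subgroups (three heavy, one kappa, one lambda) with two alleles
    each, and one J per locus.  Every V segment carries the conserved
    cysteines at IMGT 23 and 104; each subgroup carries the intrinsic
    liability motifs listed in the ledger and nothing else.
    """
    rng = _rng(seed)
    ref = compile_reference()
    germ = GermlineReference()
    ledger: list[PlantedHit] = []
    for subgroup, plants in _GERMLINE_PLANTS.items():
        ctype = subgroup[2]  # IG[HKL]V...
        for allele_no in (1, 2):
            name = f"{subgroup}-1*{allele_no:02d}"
            residues = [(p, rng.choice(SAFE_BACKGROUND)) for p in _v_positions()]
            seg = NumberedChain(id=name, chain_type=ctype, residues=residues,
                                v_call=name)
            pm = {p: i for i, (p, _) in enumerate(seg.residues)}
            protected: set[ImgtPosition] = set()
            for cys in (23, 104):
                pos = ImgtPosition(cys)
                seg.residues[pm[pos]] = (pos, "C")
                protected.add(pos)
            expected: list[PlantedHit] = []
            for tag, string, start in plants:
                for offset, aa in enumerate(string):
                    pos = ImgtPosition(start + offset)
                    seg.residues[pm[pos]] = (pos, aa)
                    protected.add(pos)
                expected.append(
                    PlantedHit(name, tag, str(ImgtPosition(start)), string,
                               "inherited")
                )
            seg = _repair_chain(seg, protected, expected, ref, rng)
            germ.add(seg, kind="V")
            ledger.extend(expected)
    for locus, ctype in (("IGH", "H"), ("IGK", "K"), ("IGL", "L")):
        name = f"{locus}J1*01"
        residues = [(p, rng.choice(SAFE_BACKGROUND)) for p in _j_positions()]
        seg = NumberedChain(id=name, chain_type=ctype, residues=residues)
        seg = _repair_chain(seg, set(), [], ref, rng)
        germ.add(seg, kind="J")
    return germ, ledger


# ---------------------------------------------------------------------------
# Planted-motif chains


@dataclass(frozen=True)
class PlantSpec:
    """Plant ``count`` occurrences of ``motif_tag`` per chain in ``region``.

    ``region`` is an IMGT region name (``CDR1`` ... ``FR4``) or ``boundary``
    (the motif straddles the CDR1/FR2 junction at IMGT 38-39).
    """

    motif_tag: str
    region: str = "CDR3"
    count: int = 1
    allow_boundary: bool = False


@dataclass
class SyntheticSpec:
    """Reproducible recipe for a synthetic chain/unit collection."""

    seed: int = 0
    n_units: int = 20
    paired: bool = True
    plants: tuple[PlantSpec, ...] = (
        PlantSpec("DeAmdH", "CDR3", 1),
        PlantSpec("Isom", "CDR1", 1),
    )
    cdr3_insertions: int = 0  # extra 111A/111B... positions per chain


def _assemble_chain(
    chain_id: str,
    germ: GermlineReference,
    v_name: str,
    j_name: str,
    rng: random.Random,
    n_insertions: int = 0,
) -> tuple[NumberedChain, set[ImgtPosition]]:
    """Chain = V residues + CDR3 filler + J residues.

    Returns the chain and the initially protected positions (the conserved
    cysteines).  Germline-copied background stays repairable: re-sampling a
    background residue does not disturb motif spans or the germline flag,
    which compares motif residues only.
    """
    v = germ.get_v(v_name)
    j = germ.get_j(j_name)
    residues: list[tuple[ImgtPosition, str]] = [tuple(r) for r in v.residues]
    filler = [ImgtPosition(n) for n in range(_V_LAST + 1, _J_FIRST)]
    mid = filler[: len(filler) // 2 + 1]
    for k in range(n_insertions):
        mid.append(ImgtPosition(111, chr(ord("A") + k)))
    tail = filler[len(filler) // 2 + 1 :]
    for pos in mid + tail:
        residues.append((pos, rng.choice(SAFE_BACKGROUND)))
    residues.extend(tuple(r) for r in j.residues)
    chain = NumberedChain(
        id=chain_id,
        chain_type=v.chain_type,
        residues=residues,
        v_call=v_name,
        j_call=j_name,
    )
    protected = {p for p, aa in chain.residues
                 if aa == "C" and p.number in (23, 104)}
    return chain, protected


def _plantable_starts(
    chain: NumberedChain, region: str, k: int
) -> list[int]:
    """Indices (into chain.residues) where a k-mer fits the requested region."""
    positions = chain.positions
    n = len(positions)
    out = []
    for i in range(n - k + 1):
        span = positions[i : i + k]
        numbers = [p.number for p in span]
        if region == "boundary":
            # straddle a CDR/framework junction (FR3-CDR3 is excluded: the
            # conserved Cys 104 must stay untouched)
            junctions = ([26, 27], [38, 39], [55, 56], [65, 66], [117, 118])
            if k == 2 and numbers in junctions:
                out.append(i)
            continue
        lo, hi = _REGION_RANGE[region]
        if all(lo <= m <= hi for m in numbers):
            out.append(i)
    return out


def _inherited_ledger(
    chain: NumberedChain, v_name: str, germ_ledger: list[PlantedHit]
) -> list[PlantedHit]:
    return [
        PlantedHit(chain.id, e.motif_tag, e.start, e.matched, "inherited")
        for e in germ_ledger
        if e.chain_id == v_name
    ]


def generate_sequences(
    spec: SyntheticSpec,
    germ: GermlineReference | None = None,
    germ_ledger: list[PlantedHit] | None = None,
    ref: LiabilityReference | None = None,
) -> tuple[list[AntibodyUnit], list[PlantedHit]]:
    """Generate antibody units with planted motifs and an exact hit ledger.

    Chains are derived from the toy germline set (so they carry v_call /
    j_call and the germline's intrinsic motifs, ledgered as ``inherited``);
    plan motifs are written at random admissible positions (ledgered as
    ``planted``) and the background is repaired until a scan finds exactly
    the ledger.  Same spec -> identical output.
    """
    rng = _rng(spec.seed)
    ref = ref or compile_reference()
    if germ is None:
        germ, germ_ledger = make_toy_germline_set(seed=spec.seed)
    assert germ_ledger is not None
    heavy_vs = sorted(n for n in germ.v_segments if n.startswith("IGHV"))
    light_vs = sorted(
        n for n in germ.v_segments if n.startswith(("IGKV", "IGLV"))
    )
    units: list[AntibodyUnit] = []
    ledger: list[PlantedHit] = []

    def build_chain(chain_id: str, v_pool: list[str]) -> NumberedChain:
        v_name = rng.choice(v_pool)
        locus = v_name[:3]
        j_name = f"{locus}J1*01"
        chain, protected = _assemble_chain(
            chain_id, germ, v_name, j_name, rng, spec.cdr3_insertions
        )
        expected = _inherited_ledger(chain, v_name, germ_ledger)
        # motif spans plus a 2-residue margin: plants must not abut another
        # motif, or an unrepairable composite motif could straddle them
        occupied: set[int] = set()
        index = {p: i for i, (p, _) in enumerate(chain.residues)}
        for e in expected:
            start_i = index[ImgtPosition.parse(e.start)]
            occupied.update(range(start_i, start_i + len(e.matched)))
            protected.update(
                chain.residues[k][0]
                for k in range(start_i, start_i + len(e.matched))
            )
        for plant in spec.plants:
            motif = ref[plant.motif_tag]
            choices = sorted(expand_pattern(motif))
            reported = motif.scope == "fv" or plant.region in (
                "CDR1", "CDR2", "CDR3", "boundary",
            )
            for _ in range(plant.count):
                string = rng.choice(choices)
                k = len(string)
                starts = [
                    i
                    for i in _plantable_starts(chain, plant.region, k)
                    if not any(j in occupied for j in range(i - 2, i + k + 2))
                ]
                if not starts:
                    raise ValueError(
                        f"cannot place {plant.motif_tag} ({string}) in "
                        f"{plant.region} of {chain_id}"
                    )
                i = rng.choice(starts)
                for off, aa in enumerate(string):
                    pos = chain.residues[i + off][0]
                    chain.residues[i + off] = (pos, aa)
                    protected.add(pos)
                occupied.update(range(i, i + k))
                if reported:
                    expected.append(
                        PlantedHit(
                            chain_id, plant.motif_tag,
                            str(chain.residues[i][0]), string, "planted",
                        )
                    )
        chain = _repair_chain(chain, protected, expected, ref, rng)
        ledger.extend(expected)
        return chain

    for u in range(spec.n_units):
        heavy = build_chain(f"unit{u:03d}_H", heavy_vs)
        if spec.paired:
            light = build_chain(f"unit{u:03d}_L", light_vs)
            units.append(AntibodyUnit(heavy=heavy, light=light, id=f"unit{u:03d}"))
        else:
            units.append(AntibodyUnit(heavy=heavy, id=f"unit{u:03d}"))
    return units, ledger


# ---------------------------------------------------------------------------
# Therapeutic panel


def generate_therapeutic_panel(
    plan: list[tuple[str, int, float]],
    n: int,
    seed: int = 0,
    chain_type: str = "H",
    ref: LiabilityReference | None = None,
) -> tuple[list[NumberedChain], PositionalFrequencyTable]:
    """Panel of *n* chains where each planned ``(motif_tag, imgt_start,
    target_frequency)`` appears in exactly ``k = round(f * n)`` chains.

    The target frequency must be representable as ``k / n`` (to 1e-9);
    otherwise a ValueError names the offending plan entry.  Returns the
    panel and the expected positional frequency table for comparison
    against :func:`ablint.flags.build_therapeutic_table`.
    """
    if n <= 0:
        raise ValueError("panel size must be positive")
    rng = _rng(seed)
    ref = ref or compile_reference()
    carriers: dict[tuple[str, int], set[int]] = {}
    for tag, start, freq in plan:
        k = round(freq * n)
        if abs(k / n - freq) > 1e-9:
            raise ValueError(
                f"frequency {freq} for ({tag}, {start}) is not representable "
                f"as k/{n}"
            )
        carriers[(tag, start)] = set(rng.sample(range(n), k))
    chains: list[NumberedChain] = []
    cls_ = "H" if chain_type == "H" else "light"
    expected = PositionalFrequencyTable(provenance=f"synthetic panel seed={seed}")
    expected.denominators[cls_] = n
    for (tag, start), members in carriers.items():
        if members:
            expected.counts[(cls_, tag, str(ImgtPosition(start)))] = len(members)
    for i in range(n):
        residues = [
            (ImgtPosition(m), rng.choice(SAFE_BACKGROUND)) for m in range(1, 129)
        ]
        chain = NumberedChain(
            id=f"panel{i:03d}", chain_type=chain_type, residues=residues,
            v_call="panel",
        )
        index = {p: j for j, (p, _) in enumerate(chain.residues)}
        protected: set[ImgtPosition] = set()
        for cys in (23, 104):
            pos = ImgtPosition(cys)
            chain.residues[index[pos]] = (pos, "C")
            protected.add(pos)
        plants: list[PlantedHit] = []
        for (tag, start), members in carriers.items():
            if i not in members:
                continue
            string = sorted(expand_pattern(ref[tag]))[0]
            for off, aa in enumerate(string):
                pos = ImgtPosition(start + off)
                chain.residues[index[pos]] = (pos, aa)
                protected.add(pos)
            plants.append(PlantedHit(chain.id, tag, str(ImgtPosition(start)),
                                     string, "planted"))
        chain = _repair_chain(chain, protected, plants, ref, rng)
        chains.append(chain)
    return chains, expected


# ---------------------------------------------------------------------------
# Toy structures


def generate_toy_structure(
    unit: AntibodyUnit,
    burial_plan: dict[tuple[str, str], str] | None = None,
    seed: int = 0,
    chain_separation: float = 10.0,
) -> tuple[StructureModel, dict[tuple[str, ImgtPosition], str]]:
    """C-alpha-level structure for a paired unit with planned burial.

    Each chain's CA atoms are laid on a gentle helix at 3.8 A spacing; the
    light chain runs parallel at ``chain_separation`` A.  Residues marked
    ``buried`` in the plan (keys ``(role, position_text)``) are wrapped in a
    dense occluding shell of dummy atoms at 3 A; everything else stays free
    and classifies as exposed.  Returns the structure and the expected
    per-residue exposure classes.
    """
    if not unit.is_paired:
        raise ValueError("toy structures require a paired unit")
    burial_plan = burial_plan or {}
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    radii: list[float] = []
    residues: list[ResidueRef] = []
    expected: dict[tuple[str, ImgtPosition], str] = {}
    shell = _shell_points()
    for role, chain, y0 in (("H", unit.heavy, 0.0), ("L", unit.light,
                                                     chain_separation)):
        for i, (pos, aa) in enumerate(chain.residues):
            # coarse CA-only curve; 5.5 A spacing keeps an occluding shell
            # around one residue from burying its chain neighbours
            t = i * 0.6
            center = np.array(
                [5.5 * i + 1.5 * np.cos(t), y0 + 1.5 * np.sin(t), 2.0 * np.sin(t / 3)]
            )
            coords.append(center)
            radii.append(DEFAULT_RADIUS)
            atom_i = len(coords) - 1
            residues.append(ResidueRef(role, pos, aa, [atom_i]))
            plan_class = burial_plan.get((role, str(pos)), "exposed")
            expected[(role, pos)] = plan_class
            if plan_class == "buried":
                for p in shell:
                    coords.append(center + p)
                    radii.append(DEFAULT_RADIUS)
    return StructureModel(np.array(coords), np.array(radii), residues), expected


def _shell_points(radius: float = 3.0, n: int = 146) -> np.ndarray:
    from .surface import sphere_points

    return radius * sphere_points(n)


# ---------------------------------------------------------------------------
# Benchmark records


def generate_benchmark_records(
    profiles,
    seed: int = 0,
    flagged_mean: float = 5.0,
    unflagged_mean: float = 30.0,
    condition: str = "deamidation_low_pH",
    combo: tuple[str, ...] = ("germline", "therapeutic", "surface"),
):
    """Benchmark records whose %modification depends on flag status.

    Flagged (benign) liabilities draw from a Beta distribution with the low
    mean, unflagged from one with the high mean (both concentration 10,
    scaled to percent), emulating the designed property that flagged motifs
    modify less.  Returns a list of
    :class:`~ablint.stats.BenchmarkRecord`.
    """
    from .stats import BenchmarkRecord

    rng = np.random.default_rng(seed)
    records = []
    for p in profiles:
        for h in p.hits:
            if h.start is None:
                continue
            benign = h.flags.benign_under(combo)
            mean = flagged_mean if benign else unflagged_mean
            a = mean / 100.0 * 10.0
            b = 10.0 - a
            value = float(rng.beta(a, b) * 100.0)
            records.append(
                BenchmarkRecord(
                    therapeutic_id=p.unit_id,
                    motif=h.matched,
                    imgt_position=str(h.start),
                    condition=condition,
                    value=value,
                )
            )
    return records
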