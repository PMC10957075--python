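"""Dataset-level survey summaries, flag-reduction accounting and benchmarks.

Given a collection of per-antibody liability profiles, this module computes
the survey quantities used to characterize a corpus (fraction of sequences
with any liability, liabilities per sequence, per-type and per-region
breakdowns) and the reduction obtained by each low-risk flag combination: a
liability is *removed* by a combination iff any applied flag marks it benign,
and a sequence *remains* iff it still carries at least one non-benign
liability.

It also implements the benchmark statistics used to validate the flags
against experimental modification data: Fisher's exact test on 2x2
oxidation-vs-flag tables, Welch two-sample t-tests on modification-rate
distributions, and pairwise chi-squared comparisons of per-sequence
liability-count histograms with Bonferroni correction.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .detect import SequenceProfile
from .numbering import region_of

__all__ = [
    "DEFAULT_COMBOS",
    "DatasetSummary",
    "ContingencyTable2x2",
    "BenchmarkRecord",
    "summarize_dataset",
    "region_distribution",
    "fisher_exact",
    "two_sample_t",
    "chi2_pairwise_bonferroni",
    "benchmark_flags",
]

# Flag combinations reported by default: none, each sequence flag, sequence
# flags together, and all three (surface applies to paired data only).
DEFAULT_COMBOS: tuple[tuple[str, ...], ...] = (
    (),
    ("germline",),
    ("therapeutic",),
    ("surface",),
    ("germline", "therapeutic"),
    ("germline", "therapeutic", "surface"),
)


def _combo_key(combo: Sequence[str]) -> str:
    return "+".join(sorted(combo)) if combo else "none"


@dataclass
class DatasetSummary:
    """Survey statistics for one profile collection."""

    n_units: int
    pct_with_liability: float
    total_liabilities: int
    mean_liabilities: float
    std_liabilities: float
    median_liabilities: float
    per_type: dict[str, int]
    per_severity: dict[str, int]
    per_region: dict[str, int]
    remaining_liabilities: dict[str, int]  # combo key -> count
    remaining_sequences: dict[str, int]  # combo key -> units with >=1 non-benign

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "pct_with_liability": round(self.pct_with_liability, 4),
            "total_liabilities": self.total_liabilities,
            "mean_liabilities": round(self.mean_liabilities, 4),
            "std_liabilities": round(self.std_liabilities, 4),
            "median_liabilities": self.median_liabilities,
            "per_type": dict(self.per_type),
            "per_severity": dict(self.per_severity),
            "per_region": dict(self.per_region),
            "remaining_liabilities": dict(self.remaining_liabilities),
            "remaining_sequences": dict(self.remaining_sequences),
        }


def summarize_dataset(
    profiles: Sequence[SequenceProfile],
    combos: Sequence[Sequence[str]] = DEFAULT_COMBOS,
    partial_policy: str = "not_benign",
    group_by: str | None = None,
):
    """Compute a :class:`DatasetSummary` (optionally per group).

    ``group_by`` may be ``species_label``, ``subgroup`` or ``chain_types``;
    when given, a dict of summaries keyed by group value is returned.
    A paired unit counts as one molecule throughout.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile list")
    if group_by is not None:
        groups: dict[str, list[SequenceProfile]] = {}
        for p in profiles:
            value = getattr(p, group_by)
            key = ",".join(value) if isinstance(value, list) else str(value)
            groups.setdefault(key, []).append(p)
        return {
            k: summarize_dataset(v, combos, partial_policy)
            for k, v in sorted(groups.items())
        }

    counts = np.array([p.n_liabilities for p in profiles])
    per_type: Counter = Counter()
    per_severity: Counter = Counter()
    per_region: Counter = Counter()
    for p in profiles:
        for h in p.hits:
            per_type[h.motif_tag] += 1
            per_severity[h.severity.value] += 1
            per_region[h.attribution] += 1
    remaining_liab: dict[str, int] = {}
    remaining_seq: dict[str, int] = {}
    for combo in combos:
        key = _combo_key(combo)
        rem = [p.remaining(combo, partial_policy) for p in profiles]
        remaining_liab[key] = int(sum(rem))
        remaining_seq[key] = int(sum(1 for r in rem if r > 0))
    return DatasetSummary(
        n_units=len(profiles),
        pct_with_liability=100.0 * float(np.mean(counts > 0)),
        total_liabilities=int(counts.sum()),
        mean_liabilities=float(counts.mean()),
        std_liabilities=float(counts.std(ddof=0)),
        median_liabilities=float(np.median(counts)),
        per_type=dict(per_type),
        per_severity=dict(per_severity),
        per_region=dict(per_region),
        remaining_liabilities=remaining_liab,
        remaining_sequences=remaining_seq,
    )


def region_distribution(profiles: Iterable[SequenceProfile]) -> dict[str, int]:
    """Liability counts per IMGT region, with boundary hits binned by the
    pair of regions they straddle (e.g. ``CDR1-FR2``)."""
    out: Counter = Counter()
    for p in profiles:
        for h in p.hits:
            if not h.residues:
                out["no_position"] += 1
                continue
            regions = []
            for pos, _ in h.residues:
                r = region_of(pos)
                if not regions or regions[-1] != r:
                    regions.append(r)
            out["-".join(regions)] += 1
    return dict(out)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: outcome present / absent; columns: with flag / without flag."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    @property
    def cells(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact(table: ContingencyTable2x2 | Sequence[Sequence[int]]
                 ) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one; the odds ratio
    is the sample ratio ``a*d / (b*c)`` with the usual infinity/zero
    conventions.  Returns ``(p_value, odds_ratio)``.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    p = float(sps.fisher_exact(table.cells, alternative="two-sided")[1])
    if table.b * table.c == 0:
        odds = float("inf") if table.a * table.d > 0 else float("nan")
    else:
        odds = table.a * table.d / (table.b * table.c)
    return p, odds


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Welch two-sided two-sample t-test p-value.

    Degenerate identical zero-variance samples give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def chi2_pairwise_bonferroni(
    count_vectors: dict[str, Sequence[int]],
    min_expected: float = 1.0,
) -> dict[tuple[str, str], float]:
    """Pairwise chi-squared tests on per-sequence liability-count histograms.

    ``count_vectors`` maps dataset name -> list of per-sequence liability
    counts.  Histogram bins whose expected count falls below ``min_expected``
    are pooled into the top bin (a warning notes the pooling).  Bonferroni:
    ``p_adj = min(1, p * m)`` with *m* the number of pairs.
    """
    names = sorted(count_vectors)
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    pairs = list(combinations(names, 2))
    m = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for x, y in pairs:
        cx = Counter(count_vectors[x])
        cy = Counter(count_vectors[y])
        top = max(list(cx) + list(cy))
        hx = np.array([cx.get(k, 0) for k in range(top + 1)], dtype=float)
        hy = np.array([cy.get(k, 0) for k in range(top + 1)], dtype=float)
        while len(hx) > 2:
            obs = np.vstack([hx, hy])
            expected = (
                obs.sum(axis=1, keepdims=True)
                * obs.sum(axis=0, keepdims=True)
                / obs.sum()
            )
            if expected.min() >= min_expected:
                break
            warnings.warn("pooling sparse histogram bins for chi-squared test")
            hx = np.concatenate([hx[:-2], [hx[-2] + hx[-1]]])
            hy = np.concatenate([hy[:-2], [hy[-2] + hy[-1]]])
        if np.array_equal(hx, hy):
            p = 1.0
        else:
            keep = (hx + hy) > 0
            p = float(sps.chi2_contingency(np.vstack([hx[keep], hy[keep]]))[1])
        out[(x, y)] = min(1.0, p * m)
    return out


@dataclass(frozen=True)
class BenchmarkRecord:
    """One experimentally measured modification event on a therapeutic.

    For percent-modification conditions ``value`` is in [0, 100]; for the
    oxidation condition it is 1.0 (oxidized) or 0.0.
    """

    therapeutic_id: str
    motif: str  # matched motif string, e.g. "NG"
    imgt_position: str  # start position, e.g. "56" or "111A"
    condition: str
    value: float
    in_flag_training: bool = False

    _PCT_CONDITIONS = (
        "deamidation_high_pH",
        "deamidation_low_pH",
        "isomerization_low_pH",
    )

    def __post_init__(self) -> None:
        if self.condition not in self._PCT_CONDITIONS + ("oxidation",):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition != "oxidation" and not 0 <= self.value <= 100:
            raise ValueError(f"%modification {self.value} outside [0, 100]")


def read_benchmark_records(path: str | Path) -> list[BenchmarkRecord]:
    records = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                BenchmarkRecord(
                    therapeutic_id=row["therapeutic"],
                    motif=row["motif"],
                    imgt_position=row["imgt_position"],
                    condition=row["condition"],
                    value=float(row["value"]),
                    in_flag_training=row.get("in_training", "0") in ("1", "true", "True"),
                )
            )
    return records


def _match_hit(profile: SequenceProfile, record: BenchmarkRecord):
    for h in profile.hits:
        if h.matched == record.motif and h.start is not None and \
                str(h.start) == record.imgt_position:
            return h
    return None


def benchmark_flags(
    records: Sequence[BenchmarkRecord],
    profiles: Sequence[SequenceProfile],
    combos: Sequence[Sequence[str]] = (("germline",), ("therapeutic",),
                                       ("surface",),
                                       ("germline", "therapeutic", "surface")),
    exclude_training: bool = True,
    partial_policy: str = "not_benign",
) -> dict:
    """Stratify experimental modification data by flag status.

    Records are joined to profiles on (therapeutic id, motif string, IMGT
    start position); unmatched records are listed, not fatal.  For
    percent-modification conditions the output holds the flagged/unflagged
    value distributions per combo; for the oxidation condition, 2x2 tables
    (oxidation x flag) restricted to therapeutics with annotated
    methionines, plus their Fisher's exact p-values.  A molecule counts as
    "with flag" iff at least one of its annotated methionines is benign
    under the combo.  ``exclude_training`` drops records from therapeutics
    used to build the therapeutic flag.
    """
    by_id = {p.unit_id: p for p in profiles}
    unmatched: list[BenchmarkRecord] = []
    pct: dict[str, dict[str, dict[str, list[float]]]] = {}
    # oxidation bookkeeping per therapeutic: (oxidized, [met hits])
    ox_mols: dict[str, tuple[bool, list]] = {}

    for rec in records:
        if exclude_training and rec.in_flag_training:
            continue
        profile = by_id.get(rec.therapeutic_id)
        hit = _match_hit(profile, rec) if profile is not None else None
        if hit is None:
            unmatched.append(rec)
            continue
        if rec.condition == "oxidation":
            oxidized, hits = ox_mols.setdefault(
                rec.therapeutic_id, (rec.value > 0, [])
            )
            hits.append(hit)
        else:
            for combo in combos:
                key = _combo_key(combo)
                bucket = pct.setdefault(rec.condition, {}).setdefault(
                    key, {"flagged": [], "unflagged": []}
                )
                side = (
                    "flagged"
                    if hit.flags.benign_under(combo, partial_policy)
                    else "unflagged"
                )
                bucket[side].append(rec.value)

    oxidation: dict[str, dict] = {}
    if ox_mols:
        for combo in combos:
            key = _combo_key(combo)
            a = b = c = d = 0
            for oxidized, hits in ox_mols.values():
                met = [h for h in hits if h.motif_tag == "MetOx"]
                if not met:
                    continue
                with_flag = any(
                    h.flags.benign_under(combo, partial_policy) for h in met
                )
                if oxidized and with_flag:
                    a += 1
                elif oxidized:
                    b += 1
                elif with_flag:
                    c += 1
                else:
                    d += 1
            if a + b + c + d == 0:
                warnings.warn(f"oxidation benchmark empty for combo {key}")
                continue
            table = ContingencyTable2x2(a, b, c, d)
            p, odds = fisher_exact(table)
            oxidation[key] = {"table": table.cells, "p": p, "odds_ratio": odds}

    if not pct and not oxidation:
        warnings.warn("benchmark comparison is empty (all records excluded?)")
    return {
        "percent_modification": pct,
        "oxidation": oxidation,
        "unmatched": unmatched,
    }
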