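"""Liability detection: scanning, cysteine rules, profiles, oracle checks."""

import random
from collections import Counter

import pytest

from ablint.detect import (
    ConfigurationError,
    ProfileConfig,
    check_conserved_cysteines,
    profile_antibody,
    scan_chain,
)
from ablint.numbering import CDR_REGIONS, ImgtPosition, NumberedChain, region_of
from ablint.reference import AMINO_ACIDS, LiabilityReference, expand_pattern


def make_chain(cid="c", ctype="H", seq_at=None, fill="A", positions=None):
    """Chain covering the given IMGT positions (default 1-128) with residue
    `fill`, overridden at `seq_at` ({number: residue})."""
    seq_at = seq_at or {}
    positions = positions or [ImgtPosition(n) for n in range(1, 129)]
    residues = [(p, seq_at.get(p.number, fill)) for p in positions]
    return NumberedChain(id=cid, chain_type=ctype, residues=residues,
                         v_call="IGHV1-1*01", j_call="IGHJ1*01")


def brute_force_scan(chain, ref: LiabilityReference, policy="inclusive"):
    """Independent oracle: slide every expanded k-mer over the residue
    string and apply the scope rule."""
    seq = chain.sequence
    positions = chain.positions
    found = []
    for motif in ref.scan_entries:
        expansion = expand_pattern(motif)
        for k in {len(s) for s in expansion}:
            for i in range(len(seq) - k + 1):
                if seq[i : i + k] not in expansion:
                    continue
                span = positions[i : i + k]
                if motif.scope == "cdrs":
                    in_cdr = [region_of(p) in CDR_REGIONS for p in span]
                    ok = any(in_cdr) if policy == "inclusive" else all(in_cdr)
                    if not ok:
                        continue
                found.append((motif.tag, str(span[0]), seq[i : i + k]))
    return Counter(found)


def hit_key(hits):
    return Counter((h.motif_tag, str(h.start), h.matched) for h in hits)


def random_chain(rng, cid):
    """Random-residue chain on a random subset of IMGT positions."""
    numbers = sorted(rng.sample(range(1, 129), rng.randint(60, 120)))
    positions = []
    for n in numbers:
        positions.append(ImgtPosition(n))
        if n == 111 and rng.random() < 0.3:
            for k in range(rng.randint(1, 3)):
                positions.append(ImgtPosition(111, chr(ord("A") + k)))
    residues = [(p, rng.choice(AMINO_ACIDS)) for p in positions]
    return NumberedChain(id=cid, chain_type=rng.choice("HKL"),
                         residues=residues, v_call="x", j_call="x")


class TestScanChain:
    def test_cdr1_deamidation_hit(self, default_ref):
        chain = make_chain(seq_at={36: "N", 37: "G"})
        hits = [h for h in scan_chain(chain, default_ref) if h.motif_tag == "DeAmdH"]
        assert len(hits) == 1
        (h,) = hits
        assert h.severity.value == "high"
        assert h.attribution == "cdr"
        assert str(h.start) == "36" and h.matched == "NG"

    def test_polyalanine_has_no_scan_hits(self, default_ref):
        assert scan_chain(make_chain(), default_ref) == []

    def test_framework_motif_not_reported_under_cdrs_scope(self, default_ref):
        chain = make_chain(seq_at={20: "N", 21: "G"})
        assert scan_chain(chain, default_ref) == []

    def test_boundary_hit_inclusive_vs_strict(self, default_ref):
        chain = make_chain(seq_at={38: "N", 39: "G"})
        inclusive = scan_chain(chain, default_ref, "inclusive")
        assert [h.attribution for h in inclusive] == ["boundary"]
        assert scan_chain(chain, default_ref, "strict") == []

    def test_fv_scope_reported_in_framework(self, default_ref):
        chain = make_chain(seq_at={20: "N", 21: "A", 22: "S"})
        tags = {h.motif_tag for h in scan_chain(chain, default_ref)}
        assert "Ngly" in tags  # NAS sequon in FR1

    def test_overlapping_motifs_all_reported(self, default_ref):
        # NGS in CDR2: DeAmdH on NG, Ngly on NGS, FragH none...
        chain = make_chain(seq_at={60: "N", 61: "G", 62: "S"})
        key = hit_key(scan_chain(chain, default_ref))
        assert key[("DeAmdH", "60", "NG")] == 1
        assert key[("Ngly", "60", "NGS")] == 1

    def test_adjacency_across_numbering_gap(self, default_ref):
        """Motif residues adjacent in the polypeptide match across an IMGT gap."""
        positions = [ImgtPosition(n) for n in range(1, 129) if n != 61]
        chain = make_chain(seq_at={60: "N", 62: "G"}, positions=positions)
        key = hit_key(scan_chain(chain, default_ref))
        assert key[("DeAmdH", "60", "NG")] == 1

    def test_hit_count_invariant_under_reference_reordering(self, default_ref):
        rng = random.Random(5)
        chain = random_chain(rng, "r")
        shuffled = LiabilityReference(
            entries=tuple(sorted(default_ref.entries, key=lambda e: e.tag,
                                 reverse=True)),
            version=default_ref.version,
        )
        assert hit_key(scan_chain(chain, default_ref)) == hit_key(
            scan_chain(chain, shuffled)
        )

    def test_hit_residues_reproduce_pattern(self, default_ref):
        rng = random.Random(6)
        for i in range(50):
            chain = random_chain(rng, f"r{i}")
            for h in scan_chain(chain, default_ref):
                assert h.matched in expand_pattern(default_ref[h.motif_tag])

    @pytest.mark.parametrize("policy", ["inclusive", "strict"])
    def test_oracle_equivalence_on_random_chains(self, default_ref, policy):
        rng = random.Random(42)
        for i in range(300):
            chain = random_chain(rng, f"r{i}")
            assert hit_key(scan_chain(chain, default_ref, policy)) == \
                brute_force_scan(chain, default_ref, policy)


class TestConservedCysteines:
    def test_canonical_cysteines_clean(self):
        chain = make_chain(seq_at={23: "C", 104: "C"})
        assert check_conserved_cysteines(chain) == []

    def test_missing_cys_at_104(self):
        chain = make_chain(seq_at={23: "C"})
        hits = check_conserved_cysteines(chain)
        assert [h.motif_tag for h in hits] == ["mCys"]
        assert hits[0].residues == [] and hits[0].start is None
        assert hits[0].attribution == "fv"

    def test_extra_cys(self):
        chain = make_chain(seq_at={23: "C", 104: "C", 35: "C"})
        hits = check_conserved_cysteines(chain)
        assert [(h.motif_tag, str(h.start)) for h in hits] == [("xCys", "35")]

    def test_cys_on_insertion_is_extra(self):
        positions = [ImgtPosition(n) for n in range(1, 129)]
        positions.insert(positions.index(ImgtPosition(112)), ImgtPosition(111, "A"))
        residues = [(p, "C" if p.number in (23, 104) and p.insertion is None
                     else ("C" if p == ImgtPosition(111, "A") else "A"))
                    for p in positions]
        chain = NumberedChain(id="i", chain_type="H", residues=residues, v_call="x")
        hits = check_conserved_cysteines(chain)
        assert [(h.motif_tag, str(h.start)) for h in hits] == [("xCys", "111A")]


class TestProfileAntibody:
    def test_planted_unit_recovers_ledger(self, default_ref, small_cohort):
        units, ledger = small_cohort
        for unit in units:
            profile = profile_antibody(unit, default_ref)
            want = Counter(
                (e.motif_tag, e.start, e.matched)
                for e in ledger
                if e.chain_id in {c.id for c in unit.chains}
            )
            assert hit_key(profile.hits) == want

    def test_surface_without_pairing_is_config_error(self, default_ref):
        from ablint.numbering import AntibodyUnit

        unit = AntibodyUnit(heavy=make_chain(seq_at={23: "C", 104: "C"}))
        with pytest.raises(ConfigurationError, match="paired"):
            profile_antibody(unit, default_ref,
                             ProfileConfig(apply_surface=True))

    def test_germline_without_reference_is_config_error(self, default_ref):
        from ablint.numbering import AntibodyUnit

        unit = AntibodyUnit(heavy=make_chain(seq_at={23: "C", 104: "C"}))
        with pytest.raises(ConfigurationError, match="germline"):
            profile_antibody(unit, default_ref, ProfileConfig(apply_germline=True))

    def test_clean_unit_empty_profile(self, default_ref):
        from ablint.numbering import AntibodyUnit

        unit = AntibodyUnit(heavy=make_chain(seq_at={23: "C", 104: "C"}))
        profile = profile_antibody(unit, default_ref)
        assert profile.hits == []
        assert profile.n_liabilities == 0
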