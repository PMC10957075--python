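# ablint

Chemical-liability motif profiling of antibody variable domains, with
germline, therapeutic and surface low-risk flags.

Antibody engineers routinely scan lead candidates for sequence liabilities —
short motifs prone to deamidation (NG, NS…), isomerization (DG, DS…),
fragmentation (DP, TS), Met/Trp oxidation, N-linked glycosylation sequons
(N-X-S/T, X ≠ P), unpaired cysteines and integrin-binding motifs.  Plain
motif scanning is over-predictive: nearly every variable domain carries
several hits.  `ablint` detects liabilities in IMGT-numbered heavy and
light chains against a codified liability reference (13 categories, three
severity levels) and then annotates each hit with three flags that mark it
as plausibly benign:

* **germline** — the motif occurs at the identical IMGT position, with the
  identical residues, in a human germline V or J segment;
* **therapeutic** — the (motif, IMGT position) occurs in > 5% of chains of
  a marketed-therapeutic panel;
* **surface** — all motif residues are buried (relative SASA ≤ 7.5%) in a
  paired-Fv structural model (Shrake–Rupley, deterministic point lattice).

On top of per-sequence profiles it computes dataset survey statistics
(percent of sequences with any liability, liabilities per molecule,
per-type/per-region breakdowns) and flag-reduction accounting (liabilities
and sequences remaining after each flag combination), plus the benchmark
statistics used to validate flags against experimental modification data
(Fisher's exact test, Welch t-test, pairwise chi-squared with Bonferroni).

A synthetic-fixture module generates IMGT-numbered germline sets, chains
with planted motifs and exact ledgers, therapeutic panels with controlled
positional frequencies, and toy structures with planned burial — so the
whole pipeline builds and tests without any downloads.

## Worked example

```python
from ablint import (
    compile_reference, profile_antibody, ProfileConfig,
    build_therapeutic_table, summarize_dataset,
)
from ablint.synthetic import (
    make_toy_germline_set, generate_sequences, generate_therapeutic_panel,
    generate_toy_structure, SyntheticSpec, PlantSpec,
)

ref = compile_reference()
germ, germ_ledger = make_toy_germline_set(seed=1)
units, ledger = generate_sequences(
    SyntheticSpec(seed=7, n_units=10,
                  plants=(PlantSpec("DeAmdH", "CDR3", 1),
                          PlantSpec("Isom", "CDR1", 1))),
    germ, germ_ledger,
)
panel, _ = generate_therapeutic_panel([("DeAmdH", 56, 0.50)], n=20, seed=2)
table = build_therapeutic_table(panel, ref)

structure, _ = generate_toy_structure(units[0], seed=3)
config = ProfileConfig(
    apply_germline=True, germline_reference=germ,
    apply_therapeutic=True, therapeutic_table=table,
    apply_surface=True, structure=structure,
)
profile = profile_antibody(units[0], ref, config)
for h in profile.hits:
    print(h.chain_id, h.motif_tag, h.start, h.matched, h.attribution, h.flags)
```

prints one line per detected liability:

```
unit000_H DeAmdH 56 NG cdr FlagAnnotation(germline=True, therapeutic=True, surface='exposed')
unit000_H DeAmdH 113 NG cdr FlagAnnotation(germline=False, therapeutic=False, surface='exposed')
unit000_H Isom 27 DG cdr FlagAnnotation(germline=False, therapeutic=False, surface='exposed')
unit000_H Isom 62 DS cdr FlagAnnotation(germline=True, therapeutic=False, surface='exposed')
unit000_L DeAmdH 108 NG cdr FlagAnnotation(germline=False, therapeutic=False, surface='exposed')
unit000_L Isom 34 DT cdr FlagAnnotation(germline=False, therapeutic=False, surface='exposed')
unit000_L DeAmdM 30 NT cdr FlagAnnotation(germline=True, therapeutic=False, surface='exposed')
```

The NG at IMGT 56 is inherited from the assigned IGHV3 germline (germline
flag) and sits at a position frequent in the marketed panel (therapeutic
flag); the NG planted in CDR3 at 113 matches no germline, no frequent
therapeutic position and is solvent exposed — it stays a candidate for
engineering.  Summarize a cohort with:

```python
profiles = [profile_antibody(u, ref, config_for(u)) for u in units]
summary = summarize_dataset(profiles)
print(summary.total_liabilities,
      summary.remaining_liabilities["germline+surface+therapeutic"])
```

`remaining_liabilities` maps each flag combination to the number of hits
no applied flag marks benign; `remaining_sequences` counts molecules that
still carry at least one such hit.

## Command line

```sh
ablint synth --seed 3 --out fixtures/          # synthetic fixture set
ablint build-table --panel fixtures/panel.csv --out table.tsv
ablint profile --input fixtures/chains.csv --paired \
    --germline fixtures/germline.fasta --therapeutic-table table.tsv \
    --structure fixtures/unit000_synthetic.pdb --out report/
ablint summarize --hits report/hits.csv --out summary.json
ablint benchmark --records records.tsv --hits report/hits.csv --out bench.json
```

Input dialects: ANARCI-style CSV (one column per IMGT position) and AIRR
Rearrangement TSV (IMGT-gapped `sequence_alignment_aa`).  Numbering itself
is delegated to external tools such as ANARCI.

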