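# bamtool

Anchor-based annotation of unknown MS/MS spectra. Given a query spectrum,
the pipeline:

1. **finds an anchor** — an annotated spectrum with high *modified cosine*
   similarity (fragment peaks matched directly or shifted by the precursor
   mass difference), organised as a molecular network;
2. **applies biotransformation rules** — rules are extracted from
   reactant–product structure pairs by aligning them with a bond-order-aware
   maximum common substructure, recording the reaction-center atom type, its
   bonded neighborhood, the structural edit, and the monoisotopic mass delta.
   Rules whose unit-rounded delta matches the observed precursor mass
   difference are applied to the anchor structure at every compatible site to
   enumerate candidate suspect structures;
3. **ranks the candidates** by the likelihood that the edited atom is a site
   of metabolism, with average-rank tie resolution (a block of *t* tied
   candidates over positions *p..p+t−1* all receive rank Σpositions / *t*).

Candidate correctness is judged on the first 14 InChIKey characters
(2D connectivity). A fixtures module generates fully ground-truthed synthetic
benchmarks (scaffold catalogue, single-step transformation families,
deterministic pseudo-fragmentation spectra), so everything runs offline.

## CLI

```bash
bam make-fixtures --n 50 --seed 7 --out fixtures/        # synthetic benchmark
bam network --in fixtures/spectra.mgf --threshold 0.8 --tol 0.02 --out edges.tsv
bam extract-rules --pairs fixtures/rule_pairs.tsv --out rules.json
bam annotate --pairs queries.tsv --rules rules.json --out candidates.tsv
bam evaluate --benchmark fixtures/spectra.mgf --rules rules.json --scorer default --out report.json
bam run --config config.json                             # full pipeline
```

`bam run` reads a JSON config (see `bamtool.config.PipelineConfig`):

```json
{
  "schema_version": 1,
  "fragment_tol": 0.02,
  "network_threshold": 0.8,
  "adduct": "[M+H]+",
  "scorer_name": "default",
  "seed": 7,
  "paths": {
    "spectra": "fixtures/spectra.mgf",
    "rule_pairs": "fixtures/rule_pairs.tsv",
    "out_dir": "out"
  }
}
```

and writes `candidates.tsv`, `report.json` and `run.log` to `out_dir`.
Runs are deterministic: the same config and inputs produce byte-identical
outputs. Exit codes: 0 ok, 1 input error, 2 internal error.

## Site scorers

Ranking consumes a pluggable `SiteScorer` (one likelihood in [0, 1] per
heavy atom). The built-in `default` scorer is a Laplace-smoothed frequency
heuristic over reaction-center atom types in the loaded rule table; a
learned graph model can be dropped in by satisfying the same contract.

## Layout

| module | responsibility |
| --- | --- |
| `bamtool.chem` | structures, InChIKey identity, monoisotopic mass, fingerprints |
| `bamtool.spectra` | `Spectrum` model; MGF/MSP readers, MGF writer |
| `bamtool.network` | modified cosine, network construction, anchor–suspect pairs |
| `bamtool.rules` | atom typing, MCS rule extraction, edits, mass-indexed rule table |
| `bamtool.generate` | rule application and candidate enumeration |
| `bamtool.ranking` | scorers, average-rank ties, recall / rank@k evaluation |
| `bamtool.fixtures` | synthetic scaffolds, reaction pairs, spectra, benchmarks |
| `bamtool.config` / `pipeline` / `cli` | configuration, orchestration, `bam` CLI |
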