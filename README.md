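# notocrm

Sequence-level modeling of Brachyury-driven notochord enhancers:

- **Degenerate motif model** — the 6-bp T-box core `TNNCAC` and the 12-bp
  extended consensus `RWWNTNRCACYT` (core at positions 5–10), with packaged
  catalogs of the 16 possible cores (required / represented-only /
  unobserved) and 24 aligned functional 12-bp sites.
- **Scanner** — both-strand core matching with oriented 12-bp context,
  flank-mismatch scoring against the extended consensus, and inter-site
  spacing (edge-to-edge, with helical-offset modulo 10.5 bp).
- **Random-occurrence null** — analytic expected core counts in i.i.d.
  background plus Poisson/binomial tail probabilities for enrichment.
- **CRM caller** — clustering of confident sites into candidate intervals,
  architecture classification (multiple / single / zero confident sites)
  and the deterministic onset-class mapping (early / middle /
  late-or-indirect).
- **In-silico mutagenesis** — CAC→TCT core ablation and predicted
  architecture/onset shift (one of two sites gone → delayed onset; all
  gone → inactive).
- **Assay quantification** — staining fractions and onset calls from staged
  embryo count tables, Fisher tests on proportions, qPCR standard curves
  (efficiency from slope) and ChIP percent-input / fold-change arithmetic.
- **Synthetic data** — seeded generators for backgrounds, planted CRM
  architectures with ground truth, staged staining tables and qPCR runs.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(combinatorial counts, the analytic null, catalog regressions, scanner
oracle equivalence, classifier recovery on scrubbed synthetic genomes,
mutation-shift logic, and parameter-recovery simulations).

## CLI

```sh
notocrm simulate --out-prefix sim --n-loci 30 --seed 1        # synthetic genome + truth
notocrm scan sim.fasta --out-prefix hits                      # BED6 + JSON site detail
notocrm enrich sim.fasta --out enrich.json                    # observed vs expected cores
notocrm call sim.fasta --out-prefix crm                       # candidate intervals
notocrm predict sim.fasta --out report.json                   # architecture + onset + null
notocrm mutate sim.fasta --out-prefix mut \
    --targets locus_000_early:298-304:+                       # ablate a core, diff classes
notocrm quantify-staining staining.tsv --out st.json
notocrm quantify-chip standards.tsv samples.tsv --out chip.json
```

Options can also come from a YAML config (`--config`); CLI flags override
file values, which override the documented defaults (clustering window
300 bp, max flank mismatches 4, required-only core whitelist, single-strand
null). Exit codes: 0 success, 1 usage/config error, 2 data error.

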