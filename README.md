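# postgwas

Post-GWAS functional annotation and target-gene prioritization, with a
built-in synthetic-data engine so the whole pipeline runs and is tested
end to end without any external downloads.

Given a set of trait-associated index SNPs, summary statistics, a phased
genotype panel, gene models, chromatin tracks, TF motifs and molecular
phenotypes, the pipeline:

1. **Assembles the susceptibility-SNP set** — LD expansion of index SNPs at
   r² ≥ 0.8 plus summary SNPs at P < 5×10⁻⁸, deduplicated by position and
   allele pair (`postgwas.variants`).
2. **Annotates each SNP** with one primary region (CDS > splicing > UTR >
   ncRNA > promoter > intronic > intergenic), strand-aware coding
   consequences, a four-predictor damaging consensus for missense SNPs,
   gained/lost microRNA seed matches in 3'UTRs, and per-tissue enhancer
   membership from chromatin 15-state tracks (`postgwas.annotate`).
3. **Calls TF-binding disruption** by allele-aware PWM scanning over both
   strands and all covering offsets, and tests per-TF enrichment of
   disruption in promoter/enhancer SNPs (`postgwas.tfbs`).
4. **Tests histone-mark enrichment** of the associated variant set with
   LD-tally-matched permutation nulls (`postgwas.enrich_hist`).
5. **Maps cis-QTLs** (methylation, expression, protein) and filters
   expression targets through SMR with the HEIDI heterogeneity test;
   a gene counts as an eQTL target only when significant in both
   (`postgwas.qtl_smr`).
6. **Integrates evidence**: the target genes from the four sources are
   validated by Stouffer meta-analysis of case/control differential
   expression, mouse nervous-system phenotypes and direct disease-pathway
   membership; genes with all three hits are prioritized, unexplained genes
   are bridged through one-hop protein interactions, and approved drugs are
   joined (`postgwas.integrate`).

`postgwas.pipeline.run(cfg)` wires all stages together on a synthetic study
generated by `postgwas.synthio` from a single `SimConfig`.

## Quick start

```python
from postgwas import pipeline
from postgwas.config import SimConfig

res = pipeline.run(SimConfig(seed=1))
print(res.report["prioritized_genes"])
print(res.table1)
```

The narrative scripts in `examples/` walk through each stage:

| script | stage |
| --- | --- |
| `01_generate_study.py` | synthetic study + VCF/GTF/FASTA/JASPAR/BED export |
| `02_susceptibility_set.py` | index SNPs, LD expansion, source merging |
| `03_annotate_and_tfbs.py` | regions, consequences, predictors, TFBS calls |
| `04_histone_enrichment.py` | AVS + matched permutation enrichment |
| `05_qtl_smr.py` | cis-QTL, SMR/HEIDI, conditional analysis |
| `06_full_pipeline.py` | end-to-end run and prioritization report |

## Testing and the acceptance report

```bash
python -m pytest tests        # unit, property and end-to-end tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script generates its own data, runs the full pipeline and
writes the main computed quantities (functional-set tallies, target and
prioritization counts, recovery sensitivity against the planted truth) as
JSON.

Methodological details and formulas are documented in
[docs/methods.md](docs/methods.md).
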