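# svdosage

Structural variants (SVs) — insertions, deletions and larger
rearrangements ≥ 50 bp — often sit in the regulatory neighborhood of
genes rather than inside them, where they act like dosage knobs:
an SV allele can *suppress* its neighboring gene (typically by carrying
highly methylated CpG-island sequence) or *promote* it (typically by
carrying transcription-factor binding sites). `svdosage` is a toolkit
for quantifying this bidirectional dosage regulation in a pan-genome
setting, written for researchers analyzing multi-genome panels and
genotyped populations of a crop species such as *Brassica oleracea*.

The pipeline covers:

- **Catalog** — merging per-genome SV calls into a nonredundant catalog,
  genomic-context annotation, SV density profiles around genes, TE
  overlap, private-SV statistics, pan-SV saturation fitting
  (P(n) = A − B·e^(−n/C)) and LTR insertion dating (T = K/2µ).
- **Families** — pan-genome classification of syntenic gene families
  (core / softcore / dispensable / private), morphotype-specific gene
  loss and homoeolog copy-retention analysis across the three
  mesohexaploidy subgenomes (LF, MF1, MF2).
- **Dosage** — linking each SV to its closest gene within 10 kb,
  orientation-free presence/absence genotyping (the longer allele is
  "presence"), and direction calls: with group mean TPMs x̄_P and x̄_A,
  an SV is *promoting* when x̄_P ≥ 1.5·x̄_A and *suppressing* when
  x̄_A ≥ 1.5·x̄_P; population mode additionally requires a two-sided
  Mann–Whitney U test at α = 0.05.
- **Regulatory signatures** — weighted methylation levels
  (Σ methylated / Σ total reads over CpG sites with depth ≥ 3),
  CpG-island detection (≥ 200 bp, GC ≥ 50%, obs/exp CpG ≥ 0.6),
  IUPAC-consensus TF-binding-site scanning, and permutation tests
  contrasting suppressing vs promoting SV sequences.
- **Association** — case–control SV-GWAS per morphotype with two-tailed
  Fisher exact tests on accession counts and Bonferroni correction,
  top-fraction signal selection, two-SV haplotype groups, LD (r²)
  against SNPs, and cis/trans labeling of expression associations
  (cis = within 20 kb, same chromosome).
- **Simulation** — a generator that emulates the full study (27-genome
  panel, 704-accession population, planted suppressing/promoting SVs
  with CpG-rich or motif-rich sequences, morphotype-associated
  frequencies, missing calls) so every stage can be validated against a
  known truth table.

## Worked example

```python
from svdosage.simulate import SimConfig, gen_pangenome
from svdosage.dosage import dosage_pipeline, asymmetry_binomial
from svdosage.assoc import case_control_fisher

bundle = gen_pangenome(SimConfig(n_genes=400, n_svs=200, seed=42))

# panel mode: 27 assembled genomes, one expression sample each
calls, skipped = dosage_pipeline(
    bundle.catalog, bundle.genes,
    bundle.panel_genotypes, bundle.expression_panel, mode="panel",
)
n_sup = sum(c.direction == "suppressing" for c in calls)
n_pro = sum(c.direction == "promoting" for c in calls)
print(f"{len(calls)} SV genes called: {n_sup} suppressing, {n_pro} promoting")
print(f"asymmetry binomial p = {asymmetry_binomial(n_sup, n_pro):.3g}")

# population mode: case-control GWAS for one morphotype
res = case_control_fisher(bundle.population_genotypes, "ornamental_kale")
top = res["p_raw"].idxmin()
print(f"top GWAS SV: {top}  p = {res.loc[top, 'p_raw']:.3g}  "
      f"(planted exclusive: {bool(bundle.truth.at[top, 'exclusive'])})")
```

Output:

```
196 SV genes called: 64 suppressing, 57 promoting
asymmetry binomial p = 0.586
top GWAS SV: sv0000  p = 6.22e-31  (planted exclusive: True)
```

196 of the 200 planted SVs pass the eligibility filters (≥ 4 genomes in
the minority genotype group, expression filter); the 64/57 direction
split recovers the generator's 35%/30% planted mix, and at this scale
the excess of suppressors is not significant (binomial p = 0.59). In
the population, the SV planted as exclusive to the 18 ornamental-kale
accessions is the strongest GWAS signal by many orders of magnitude.

The same stages are available from the shell:

```bash
svdosage simulate --seed 42 --out fixtures/
svdosage dosage --vcf fixtures/svs_panel.vcf --gff fixtures/genes.gff3 \
    --expr fixtures/expression_panel.tsv --mode panel --out results/
svdosage assoc --vcf fixtures/svs_population.vcf --meta fixtures/accessions.tsv \
    --case-morphotype ornamental_kale --out results/
svdosage report --dir results/ --out results/report.json
```

Every analysis threshold (linking radius, fold rule, expression and
group-size filters, permutation counts, …) lives in an
`AnalysisConfig` that can be loaded from YAML and passed to any stage;
see `docs/methods.md` for the full model description and the rationale
behind each default.

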