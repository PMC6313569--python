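# trioscan

Trio whole-genome variant prioritization toolkit: de novo mutation
detection, recessive-model filtering, depth-based CNV segmentation, and
WHO toxic-equivalency (TEQ) arithmetic — driven by a seeded synthetic trio
generator so every stage is testable without external data.

## What it does

* **`trioscan.simulate`** — generates Mendelian-consistent trio datasets
  (reference FASTA, gene-model table, trio VCF, binned depth, population
  catalogs) with planted de novo SNVs/indels, trans-configured compound
  heterozygotes and homozygous deletions, plus a truth table for recovery
  testing. Two study-scale presets ship with the package: `paper_trio`
  (93 de novo heterozygous variants, 3 exonic, among >10,000 inherited
  sites) and `paper_cnv` (150-kb and 10-kb child-homozygous /
  parent-hemizygous deletions on a 5-Mb contig).
* **`trioscan.io`** — strict readers/writers for VCF 4.2 (trio, decomposed
  biallelic records), FASTA, gene-model TSV, known-site lists, depth bins
  and congener tables. Point variants are 1-based; intervals are 0-based
  half-open; conversion happens only at I/O boundaries.
* **`trioscan.annotate`** — region classification (exonic / splicing /
  UTR / ncRNA / intronic / intergenic with documented precedence), coding
  effect via codon arithmetic with strand handling, CpG-context and
  transition/transversion flags.
* **`trioscan.denovo`** — dual single-parent comparison (candidate iff the
  proband's alt allele is absent from *both* parents), edge-read indel
  filtering (supports within 10 bp of a read end are discounted), and
  mutation-spectrum statistics (Ts/Tv, CpG proportion, per-generation
  rate over a configurable diploid genome length).
* **`trioscan.recessive`** — compound-heterozygote calling with
  parental-origin phasing (trans configuration required), homozygous
  recessive calls, coding-effect and population-frequency filters, and an
  optional local cohort panel exclusion.
* **`trioscan.cnv`** — an in-house circular binary segmentation (CBS)
  implementation: maximal two-sample t-statistic over all arc splits,
  seeded permutation test with sequential early stopping, trio copy-state
  calling (`hom_del` / `hemi` / `normal` / `gain`), and a deterministic
  inheritance rule.
* **`trioscan.teq`** — WHO-1998/2005 TEF schemes, non-detect policies
  (zero / half / full detection limit), per-congener contributions, family
  totals, and subset shares; the exposed father's serum congener panel is
  packaged as data.
* **`trioscan.pipeline`** — end-to-end orchestration producing a JSON
  report with a per-sample novelty/region accounting matrix, the de novo
  spectrum, candidate tables, CNV segments and the TEQ block.

## CLI

```sh
trioscan simulate --preset paper_trio --seed 42 --out sim/
trioscan denovo --vcf sim/trio.vcf --ref sim/reference.fa --genes sim/genes.tsv
trioscan recessive --vcf sim/trio.vcf --ref sim/reference.fa \
    --genes sim/genes.tsv --af-table sim/af.tsv --panel sim/panel.sites
trioscan cnv --depth sim/depth.tsv --alpha 0.01 --nperm 1000 --seed 1
trioscan teq --scheme who1998 --nd half --families pcdd,pcdf
trioscan run --config run.toml
```

`trioscan teq` without `--input` uses the packaged serum panel.
`trioscan run` reads a TOML file whose keys mirror
`trioscan.pipeline.RunConfig`.

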