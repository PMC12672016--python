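# dpgkit

Analysis toolkit for **divergently-paired genes (DPGs)** — head-to-head
gene pairs on opposite strands whose transcription start sites (TSSs) lie
within 1 kb, sharing a bidirectional promoter. Roughly a tenth of human
protein-coding genes sit in such pairs, and their shared regulatory space
makes them a natural laboratory for studying promoter sharing, coordinated
expression and sequence-length selection. The package is aimed at
comparative and regulatory genomicists who want the full pipeline —
pair calling, conservation coding, co-expression, signal metaprofiles,
indel pressure, lineage gap events — as tested, scriptable building
blocks.

## The core quantities

* **Inter-TSS distance** d = TSS₊ − TSS₋ for a (minus-strand, plus-strand)
  pair on one chromosome; a pair is divergent when |d| < 1000 bp. Negative
  d means the 5′ regions overlap. Spacing modes: *overlapping* (d < 0),
  *optimal* (0 ≤ d ≤ 500), *distant* (d > 500).
* **Conservation code** per pair per comparison species:
  2 — orthologs of both members form a divergent pair in that species;
  1 — both orthologs exist but the arrangement is lost; 0 — one gene lost;
  −1 — both lost. Pairs with code 2 everywhere are the vertebrate-conserved
  set; pairs with code 1 somewhere are orientation-specific.
* **Co-expression**: Spearman ρ on ln(TPM+1) across each tissue's samples
  (RIN > 6, tissues with > 20 samples). Co-expressed in a tissue iff
  ρ > 0.8 and p < 0.05; generally co-expressed iff ρ > 0.7 in > 70% of
  tissues; level high / medium / RLow from the max ρ (> 0.9 / 0.8–0.9 /
  < 0.8).
* **Metaprofile**: each pair's inter-TSS signal rescaled onto 1000
  positions by exact integral resampling (oriented minus→plus TSS, 500 bp
  unscaled flanks), averaged positionwise per co-expression level.
* **Indel pressure**: population indels with AF ≥ 0.005 and length change
  ≥ 2 bp assigned to the closed inter-TSS interval, binned by spacing into
  50-bp bins over (−1 kb, 1 kb); deletion/insertion ratio reported where
  insertions > 1.
* **Gap-block events** in three-way (focal/sister/outgroup) alignments:
  focal-gap runs are focal-lineage deletions when sister and outgroup keep
  the sequence, sister-lineage insertions when only the sister does.

Every stage has a synthetic-fixture generator (`dpgkit.simulate`) that
plants ground truth in the standard file formats (GFF3, TSV, bedGraph,
VCF, aligned FASTA), so the whole pipeline is testable end to end without
external data.

## Worked example

```python
from dpgkit import simulate as sim
from dpgkit.annotation import filter_protein_coding
from dpgkit.pairs import classify_all_spacing, identify_dpgs

spec = sim.FixtureSpec(seed=20_260_926, n_dpgs=500)
catalog, truth = sim.build_annotation(spec)
dpgset = classify_all_spacing(identify_dpgs(filter_protein_coding(catalog)))
print(len(dpgset), dpgset.to_frame().spacing_class.value_counts().to_dict())
```

prints

```
500 {'optimal': 302, 'overlapping': 155, 'distant': 43}
```

— all 500 planted pairs recovered, split across the three spacing modes in
roughly the planted 0.60/0.29/0.11 mixture. The numbered drivers under
`analysis/` run the full study on this cohort and narrate their findings;
for example `analysis/04_coexpression.py` reports

```
samples kept: 250 across 5 tissues
levels (max tissue rho): {'RLow': 208, 'high': 169, 'medium': 123}
co-expression excess: 292/500 pairs vs 0/500 random-correlation controls
(chi_squared, p=4.46e-91 ***)
```

meaning the sample filters kept the five full tissues (dropping the
planted low-RIN and undersized-tissue decoys), pair levels track their
planted correlation targets, and pairs simulated with real correlation are
overwhelmingly separated from uncorrelated controls by the n-dependent
proportion test. Tables land in `results/`.

A thin CLI mirrors the library:

```bash
dpgkit simulate --seed 4 --out-dir fixture/
dpgkit identify --annotation fixture/annotation.gff3 --out pairs.tsv
dpgkit indels --vcf fixture/indels.vcf --pairs fixture/annotation.gff3 --out bins.tsv
dpgkit report --table 41 60 1 100
```

## Layout

```
src/dpgkit/        library: annotation, pairs, conservation, coexpression,
                   signals, variation, alignment, stats, simulate,
                   config, pipeline, cli
analysis/          numbered study drivers (01_simulate_cohort ... 07_lineage_events)
tests/             unit, property and end-to-end acceptance tests
scripts/           acceptance.py
docs/methods.md    models, conventions, fixture design, limitations
```
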