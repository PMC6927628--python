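# hybriddetect

Detection and classification of interspecific hybrids (F1, backcross,
introgressed, pure) from dominant molecular-marker data and parental
sequence comparisons.

When two related species are brought into contact — typically in a
botanical collection where normally allopatric taxa grow side by side —
putative hybrids are usually flagged by intermediate morphology and then
confirmed genetically.  `hybriddetect` implements the standard molecular
tool chain for this situation:

* **Dominant fingerprint markers** (RAPD/AFLP-style band
  presence/absence matrices): band categorisation (monomorphic,
  polymorphic, unique, species-diagnostic), Dice similarity and
  distance, UPGMA/NJ dendrograms with locus-bootstrap support, PCoA, a
  diagnostic-marker **hybrid index**, and a Bayesian **admixture model
  for dominant markers** (recessive-null coding) with Evanno ΔK cluster
  selection.
* **Nuclear sequence alignments** of the parental groups: discovery of
  diagnostic SNPs and indels fixed between species, and per-clone
  scoring of hybrid sequences as parental mosaics.
* **Plastid PCR-RFLP**: in-silico restriction digestion with a
  ten-enzyme panel and haplotype grouping to trace the maternal parent
  of hybrids (chloroplasts are maternally inherited in most
  angiosperms).
* A fully seeded **synthetic-data generator** that emulates the whole
  study design (diagnostic loci, Hardy–Weinberg parental pools,
  Mendelian F1/BC1 crosses, hybrid-novel bands, planted sequence
  differences), so every stage is testable without any external data.

## The hybrid index

Given $m_A$ markers diagnostic for species A (fixed-present in A,
fixed-absent in B) and $m_B$ for species B, a specimen is scored for
$c$ = number of B-diagnostic bands present and $a$ = number of
A-diagnostic bands absent.  Two variants are computed:

$$h_\text{raw} = \frac{c + a}{m_A + m_B}, \qquad
  h_\text{norm} = \frac{1}{2}\left(\frac{c}{m_B} + \frac{a}{m_A}\right).$$

Both run from 0 (pure A) to 1 (pure B).  The normalized variant equals
exactly 0.5 for a fully additive F1; under 1:1 Mendelian segregation a
first backcross to A averages 0.25.  Class calls (pure / backcross /
F1-type, plus an "introgressed" flag for pure-range specimens carrying
foreign markers) are made from configurable index intervals.

The admixture model treats each dominant locus as a biallelic diploid
locus with a recessive null allele: a band is shown iff at least one of
the two gene copies carries the presence allele, so
$\Pr(\text{band}) = 1 - \bigl(\sum_k q_{ik}(1-p_{kl})\bigr)^2$ for
membership vector $q_i$ and cluster band-allele frequencies $p_k$.
Inference is a Gibbs sampler with genotype augmentation; the number of
clusters is chosen by Evanno's
$\Delta K = |\bar L(K{+}1) - 2\bar L(K) + \bar L(K{-}1)| / \mathrm{sd}\,L(K)$.

## Worked example

```python
from hybriddetect import (DiagnosticMarkerSet, classify_bands,
                          hybrid_index_table, simulate_marker_dataset)
from hybriddetect.synthetic_data import SimConfig

matrix, meta, truth = simulate_marker_dataset(
    SimConfig(seed=42, n_F1=5, n_BC1_A=3))
bands = classify_bands(matrix, meta)          # parental pools only
dset = DiagnosticMarkerSet.from_classification(bands)
for r in hybrid_index_table(matrix, meta, dset):
    print(r.specimen_id, r.c_present, r.a_absent,
          round(r.index_normalized, 2), r.class_call)
```

prints (run `python examples/simulate_and_classify.py` for the full
narrative):

```
F01 44  0 0.5  F1_type
F02 44  0 0.5  F1_type
F03 44  0 0.5  F1_type
F04 44  0 0.5  F1_type
F05 44  0 0.5  F1_type
BA01 20  0 0.23 backcross_A
BA02 20  0 0.23 backcross_A
BA03 23  0 0.26 backcross_A
```

Every F1 carries all 44 B-diagnostic and all 51 A-diagnostic bands
(index exactly 0.5); the backcrosses to A keep every A band but only
about half of the B bands, landing near 0.25.

The `examples/` directory has one short script per capability
(index arithmetic, simulation + classification, trees/PCoA, admixture +
ΔK, sequence diagnostics + RFLP).  A thin CLI mirrors the library:

```bash
hybriddetect simulate --seed 42 --out demo/
hybriddetect hybrid-index --matrix demo/matrix.csv --meta demo/meta.csv
hybriddetect tree --matrix demo/matrix.csv --meta demo/meta.csv \
    --method nj --bootstrap 1000 --seed 42
hybriddetect run --config pipeline.yaml
```

## Layout

```
src/hybriddetect/
  io_matrix.py        marker-matrix model, I/O, band classification
  distance.py         Dice, trees, bootstrap, PCoA, exports
  hybrid_index.py     diagnostic scoring, index variants, class calls
  admixture.py        dominant-marker Gibbs sampler, ΔK, label alignment
  seq_diagnostics.py  diagnostic SNPs/indels, clone scoring, PCR-RFLP
  synthetic_data.py   marker / alignment / plastid simulators
  pipeline.py, cli.py orchestration and the command-line layer
docs/methods.md       model details, defaults, numerical choices
examples/             one narrative script per capability
```
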