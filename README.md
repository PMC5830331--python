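# bemut

Somatic exome mutation-landscape comparison for Barrett's esophagus
(BE) cohorts: does chronic NSAID use restrain somatic genomic
evolution? Given per-patient somatic mutation catalogs from purified
BE epithelium and a matched user/non-user design, `bemut` compares the
two groups across five axes:

1. **Trinucleotide spectra and mutation load** — the 96
   pyrimidine-referenced channels (6 substitutions x 16 flanking
   contexts), an exact sign test on per-channel median differences, and
   Kruskal-Wallis / multivariable (NSAID + smoking + *TP53*) tests on
   total load;
2. **VAF clonality** — in pure diploid tissue VAF ≈ purity·c/2 for a
   clone of prevalence c, so counts of mutations above a VAF threshold
   (after removing copy-altered and cnLOH territory) measure expanded
   clones; a threshold scan compares groups across a grid;
3. **Mutational signatures** — de novo extraction by
   stability-selected KL-NMF over bootstrap-perturbed spectra, and
   per-sample refitting against a reference 96xK matrix by forward-
   selection NNLS (0.06 weight floor, 50-SNV minimum), with
   log(count+1) regressions of per-signature loads on covariates;
4. **Pathway burden and diversity** — functional mutations (the five
   likely-functional annotation classes) assigned to gene-set pathways
   via 1-kb gene proximity, per-pathway Kruskal-Wallis at FDR 0.2, and
   a gene-count-normalized Shannon index
   SI = −Σ pᵢ ln pᵢ, pᵢ ∝ countᵢ/genesᵢ;
5. **Somatic chromosome alterations (SCA)** — an exome log-ratio/BAF
   segment caller and a six-class taxonomy (HD, loss, cnLOH, balanced
   gain, allele-specific gain, focal amplification) with arm-normalized
   loads, a genome-doubling flag, and a Fisher test on focal-amp
   prevalence.

Because cohorts like this are controlled-access, the package includes a
synthetic cohort generator (`bemut.simulate`) whose defaults emulate a
41-vs-41 matched cross-sectional study with known ground truth — group
mutation loads, signature mixtures, clonal VAF structure, a 50%
user-specific reduction of functional mutations in nine of 35 cancer
pathways, and group-specific SCA rates. The test suite validates every
stage by recovering what the generator injected. See
`docs/methods.md` for the model details and design choices.

## Worked example

```bash
bemut all --seed 1 --outdir be_run
```

simulates the default cohort and writes the full report bundle
(catalog, spectrum, test tables, signature model, VAF scans, pathway
and diversity tables, SCA tables, `summary.json`). With seed 1 the run
prints into `summary.json`, among others:

```
total_snvs                        23396
mean_snvs_user / nonuser          205.05 / 365.59
median mut/Mb user / nonuser      2.10 / 3.11
sign test (96 channels)           43 lower in users, 0 higher, p = 2.3e-13
Kruskal-Wallis total load p       0.011
NSAID coefficient p (adjusted)    0.049
de novo signatures                k = 2, cosine 0.97 to the S17-like reference
pathways flagged at FDR 0.2       30 of 35 (nine injected ones all flagged)
mean reduction across flagged     52.6 %
focal amplifications              0/41 users vs 5/41 non-users, Fisher p = 0.055
genome doubling                   0 users, 6 non-users
```

Users were simulated with fewer mutations overall, so besides the nine
pathways carrying the injected 50% functional-mutation reduction, many
pathways separate through the global load difference — the nine
injected pathways show the largest reductions (63–76% in this run).
The same stages are available individually (`bemut spectrum`,
`bemut clonality`, ...) and from Python:

```python
from bemut import simulate, spectrum, signatures, refsigs

truth = simulate.default_truth(seed=1)
catalog, meta, segments, truth_log = simulate.generate_cohort(truth)
sm = spectrum.build_spectrum(catalog, meta)
model = signatures.extract_signatures_nmf(sm, k_range=[1, 2, 3], seed=1)
print(model.k, model.stability.round(3))   # 2 [0.992 0.968]
```

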