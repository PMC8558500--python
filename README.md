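# admixscan

Local-ancestry architecture of composite cattle breeds: a neutral
crossbreeding simulator, window divergence scans, generation-proxy
contrasts, and QTL-window enrichment statistics.

## The problem

American composite beef breeds — Brangus and Santa Gertrudis (⅜ Brahman
× ⅝ taurine) and Beefmaster (½ Brahman) — were founded at designed
*Bos t. indicus* × *Bos t. taurus* proportions and have since been
shaped by selection. Local-ancestry inference (RFMix-style most-likely
window assignments) makes it possible to ask, window by window, where a
breed's genome has drifted away from its pedigree expectation, and
whether advanced-generation animals differ from early-generation ones.
`admixscan` implements that analysis as a tested, reusable pipeline for
population geneticists and breed scientists. Because composite-breed
genotypes are private to breed associations, the package includes a
first-class synthetic-data simulator so every stage runs end to end on
cohorts with known ground truth.

## The statistics at its core

For window *i* with cohort Brahman proportion *pᵢ* and breed
expectation θ (0.375 or 0.5):

    Zᵢ = (pᵢ − θ) / SD(θᵢ)

where SD(θᵢ), the dispersion of window proportions under neutrality,
cannot be estimated from the sample and is instead **calibrated by
forward simulation** of the breed's crossing scheme: Poisson
recombination at 0.01 crossovers/Mb on the 29 bovine autosomes
(λ₁ = 1.58532931 for the 158.5 Mb chromosome 1), N = 1,000 per
generation, 8 generations of random mating, 10 replicates. Two-sided
p-values are computed in the log domain (windows reach |Z| > 33, far
past where the naive normal tail underflows) and significance is
controlled by Benjamini–Hochberg FDR at q = 0.001.

Early- vs advanced-generation groups are defined by the **generation
proxy** — the total count of ancestry tracts per diploid genome, which
recombination increases every generation (58 for purebreds and F1s, on
average 87 for BC1 and 116 for F2 at one crossover per chromosome per
meiosis) — and compared per window with the pooled two-proportion
Z-test. QTL-window enrichment uses exact Poisson/binomial tail
probabilities for the QTL content of 1 Mb windows.

See `docs/methods.md` for the model, the three readings of "random
mating" and why the calibration defaults to the drift-free one, and all
numerical choices.

## Worked example

Simulate a ⅜-expectation cohort of 200 animals with viability selection
favouring Brahman ancestry at chromosome 5, 60 Mb (s = 0.4), emit
RFMix-style 25-SNP window calls, and scan against breed expectation:

```python
import dataclasses, numpy as np
import admixscan as a
from admixscan.scan import ScanConfig, scan
from admixscan.windows import window_proportions

gmap   = a.default_bovine_map()
rng    = np.random.default_rng(42)
sel    = a.SelectionSpec.single("5", 60_000_000, "Brahman", 0.4)
scheme = dataclasses.replace(a.BRANGUS_SG, n=200, generations_random_mating=8)
cohort = a.run_scheme(scheme, gmap, rng, selection=sel)

calls  = a.emit_window_calls(cohort, a.MarkerGrid.uniform(gmap, 15_000), window_snps=25)
result = scan(window_proportions(calls), ScanConfig(theta=0.375, sd=0.0106), "Brahman")
print(result.summary())
```

```
Divergence scan vs theta=0.375 sd=0.0106 (FDR q=0.001)
  windows: 6654  significant: 3721 (55.9%)
  nominal -log10 p threshold: 3.3941
  top windows:
    5:60007500-60382500  p_i=0.8150 -log10p=375.87 [indicine]
    5:60382500-60757500  p_i=0.8100 -log10p=367.41 [indicine]
    5:59632500-60007500  p_i=0.8050 -log10p=359.04 [indicine]
    5:59257500-59632500  p_i=0.7950 -log10p=342.61 [indicine]
    5:60757500-61132500  p_i=0.7775 -log10p=314.77 [indicine]
```

The five most significant windows all sit on top of the selected locus
and are labelled indicine-enriched — the injected signal, recovered.
(The selected sweep drags the whole genome's statistics with it in a
200-animal cohort, hence the large significant fraction; a neutral
cohort scanned with its own calibration rejects almost nothing.) The
same objects feed the generation contrast (`admixscan.contrast`) and
the tract-count metrics (`admixscan.windows.haplotype_metrics`; this
cohort averages 295.5 tracts per genome after 8 generations, up from 58
in its F1 ancestors).

The same pipeline is scriptable from the shell:

```bash
admixscan simulate  --scheme brangus_sg --n 200 --seed 42 --out-dir demo/
admixscan calibrate --scheme brangus_sg --replicates 10 --seed 1 --out calib.json
admixscan scan      --msp demo/cohort.msp.tsv --calibration calib.json \
                    --theta 0.375 --out-prefix demo/scan
admixscan enrich    --total 3511   # Poisson/binomial window probabilities
```

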