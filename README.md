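# oculoconcord

Concordance analysis of DNA methylation between peripheral blood and
matched ocular tissues.

## The problem

Epigenome-wide association studies of eye disease almost always measure
DNA methylation in blood, because retina, RPE/choroid and optic nerve
cannot be sampled in living people. Whether blood is a usable surrogate
depends on two separable questions: how much of methylation variation is
driven by tissue of origin versus by the individual, and at which CpG
sites inter-individual variation in blood *tracks* inter-individual
variation in eye tissue of the same person. `oculoconcord` implements the
full analysis chain for matched multi-tissue HM450K-style beta-value
matrices (probes × samples, β ∈ [0, 1]):

1. **Probe QC** — remove probes failing background detection
   (p > 0.01 in any sample), cross-reactive probes and SNP-overlapping
   probes; sex-chromosome probes retained by default (single-sex cohorts).
2. **Methylation classes** — per tissue, mean β per probe classed as
   hypomethylated (β ≤ 0.2), intermediate, or hypermethylated (β ≥ 0.8),
   with disjoint UpSet-style cross-tissue intersection counts.
3. **Global concordance** — all pairwise sample Spearman correlations,
   per-tissue-pair medians/ranges, and average-linkage clustering on
   d = 1 − ρ emitted as Newick.
4. **Surrogate covariation** — the core procedure. Restrict to
   *blood-variable* probes (inter-donor β range between the 10th and 90th
   percentiles > 5%); per probe, Spearman-correlate the donor-ordered
   blood vector with the matched eye-tissue vector; flag |ρ| > 0.5,
   p < 0.05 (t approximation with df = n − 2, exact-permutation option
   for small n); compare the matched correlation distribution against a
   pooled null built by permuting donor labels (identity excluded);
   intersect flagged sets across eye tissues; and find the most similarly
   methylated probes by donor-paired t-tests with BH correction plus an
   equivalence bound.
5. **Variation structure** — PCA on M-values (M = log2(β/(1 − β))),
   screening of each component against sample traits (ANOVA / regression,
   donor-level traits tested at donor level), identification of
   components associated with the individual and nothing else, probe
   selection by correlation with component scores (|r| > 0.5), and
   tissue-specific probe detection with an empirical-Bayes moderated
   F-statistic (per-probe variances shrunk toward a common prior).
6. **Genomic-context enrichment** — Fisher-exact enrichment of any probe
   subset against a background over genomic feature classes (TSS200 …
   intergenic) and CpG-island relations (island/shore/shelf/open sea).

No public matched blood–eye dataset ships with the package; instead a
first-class **synthetic-data generator** draws study-shaped datasets
(default 8 donors × blood/retina/RPE-choroid/optic-nerve) with known
ground truth: bimodal baselines, tissue effects following a configurable
tissue-distance matrix (blood most distinct; RPE/choroid–optic nerve most
similar), mQTL-like donor-shared effects, and logit-scale noise. Every
stage is tested against that ground truth and against brute-force
statistical oracles.

## Worked example

```python
import numpy as np
import oculoconcord as oc
from oculoconcord.simulate import SimConfig, simulate_dataset
from oculoconcord.core import AnalysisConfig

sim = simulate_dataset(SimConfig(n_probes=4000, seed=11))
cfg = AnalysisConfig(rng_seed=5)

beta, report = oc.filter_probes(sim.beta, sim.annotation, sim.detection_p, cfg)
print(report.n_retained, "of", report.n_input, "probes retained")

scm = oc.sample_pairwise_spearman(beta)
print("median sample ρ:", round(np.median(scm.values[np.triu_indices(32, 1)]), 3))

variable = oc.blood_variable_probes(beta, sim.sheet, cfg)
res = {t: oc.matched_probe_correlation(beta, sim.sheet, variable, t, cfg)
       for t in ("retina", "rpe_choroid", "optic_nerve")}
common = oc.common_correlated_probes(res)
ind = set(sim.truth.probes_of_class("individual"))
print(len(variable), "blood-variable probes;", len(common),
      "correlated with blood in all three eye tissues;",
      len(common & ind), "are true donor-effect probes")
```

prints

```
3599 of 4000 probes retained
median sample ρ: 0.939
1293 blood-variable probes; 145 correlated with blood in all three eye tissues; 145 are true donor-effect probes
```

So of ~1,300 probes variable in blood, only ~150 co-vary with every
ocular tissue within donors — and all of those carry a simulated
donor-shared (genetic-like) effect, mirroring the interpretation that
cross-tissue covariation is largely genetically driven.

The same analysis runs from the shell:

```bash
oculoconcord all --config examples/default.yaml
```

where the YAML config holds a `simulate` section (or `inputs` paths to
your own beta matrix / sample sheet / annotation TSVs), an `analysis`
section with every threshold, and an output directory. Outputs are TSVs
whose header comments record the config hash and seed; reruns with the
same config are byte-identical.

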