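# sgfc — benchmarking functional connectivity by structure and geometry

Most pairwise functional connections (FC) in the brain link regions
with **no** direct white-matter (structural, SC) connection. These
polysynaptic connections are numerous and highly organized, but their
raw correlation values conflate genuine coupling with two well-known
confounds: spatial proximity (FC decays with Euclidean distance) and
the presence of a direct anatomical link. `sgfc` implements
**structure- and geometry-informed functional connectivity**: each
structurally unconnected FC weight is re-expressed as a z-score
relative to structurally connected FC weights spanning a comparable
distance,

```
sgFC_ij = ( FC_ij − μ_b(d_ij) ) / σ_b(d_ij)        for SC_ij = 0,
```

where μ_b and σ_b are the mean and sample standard deviation of the
monosynaptic FC weights inside the equal-width distance bin containing
d_ij. The bin count is chosen with the Freedman–Diaconis rule on the
monosynaptic edge lengths and the map is smoothed by averaging over a
±25% spectrum of bin counts. Large positive sgFC flags connections
that are *unexpectedly strong given their length and the absence of a
direct link* — in empirical cortex these concentrate in the default
mode network and at the transmodal apex of the unimodal–transmodal
gradient.

The package is aimed at connectomics researchers who have (or want to
simulate) a region-parcellated SC/FC pair, and provides the full
surrounding workflow:

- `sgfc.synth` — synthetic spatially embedded connectomes with planted
  ground truth (anomalous long-range polysynaptic edges, a smooth
  hierarchy, bilateral intrinsic-network blocks), so every stage is
  testable without MRI data;
- `sgfc.consensus` — density- and length-preserving, hemisphere-
  stratified group-consensus structural connectomes;
- `sgfc.core` — the sgFC transform itself plus the structure-only
  (distance-blind) baseline;
- `sgfc.summaries` — within/between intrinsic-network decomposition,
  positive node strengths, exponential strength-vs-strength fits and
  hierarchy-residual correlations;
- `sgfc.gradient` — diffusion map embedding of FC (α = 1, Gaussian
  affinity σ = 1) for gradient estimation;
- `sgfc.nulls` — spatial-autocorrelation-preserving spin permutations
  and network enrichment tests;
- `sgfc.pipeline` / the `sgfc` CLI — end-to-end orchestration with
  TSV artifacts and a hashed manifest.

## Worked example

```python
import numpy as np
from sgfc import (
    SynthParams, generate_regions, generate_sc, generate_fc,
    euclidean_distances, smooth_sgfc, positive_strength, fit_exponential,
    spin_permutations, network_enrichment,
)

params = SynthParams(seed=42)                 # 200 regions, ~2% SC density
regions = generate_regions(params.n_regions, seed=42)
sc = generate_sc(regions, params)
fc, planted = generate_fc(regions, sc, params)
d = euclidean_distances(regions)

sgfc = smooth_sgfc(fc, sc, d)
print("bin-count spectrum:", sgfc.provenance["spectrum"])

iu = np.triu_indices(regions.n, k=1)
z = sgfc.z[iu]; defined = np.isfinite(z)
order = np.argsort(z[defined])[::-1][:60]
top = {(int(i), int(j)) for i, j in zip(iu[0][defined][order], iu[1][defined][order])}
print(f"planted edges recovered in top 60: {sum(e in top for e in planted)}/{len(planted)}")

mask = sgfc.defined
fit = fit_exponential(positive_strength(fc.weights, mask),
                      positive_strength(sgfc.z, mask))
print(f"strength fit: a={fit.a:.2f}, b={fit.b:.3f}, R^2={fit.r_squared:.2f}")

spins = spin_permutations(regions, n_perms=1000, seed=42)
enrich = network_enrichment(fit.residuals, regions.network_label, spins)
row = enrich.set_index("network").loc["default"]
print(f"default-network enrichment: t={row['t']:.1f}, "
      f"p_perm={row['p_perm']:.4f}, significant={row['significant_bonferroni']}")
```

Output:

```
bin-count spectrum: [6, 7, 8, 9, 10]
planted edges recovered in top 60: 30/30
strength fit: a=12.94, b=0.027, R^2=0.45
default-network enrichment: t=10.0, p_perm=0.0010, significant=True
```

All 30 anomalous long-range edges planted into the functional matrix
(boosted by 3 local standard deviations among ~19,500 candidate
polysynaptic pairs) rank in the sgFC top 60; the node-strength
relationship between FC and sgFC is exponential with most of the
variance explained; and the synthetic default-mode analogue — the node
band at the top of the planted hierarchy — carries significantly more
sgFC strength than 1,000 spatial-autocorrelation-preserving spin
permutations predict (p is at the permutation floor 1/1001).

The same workflow runs from the shell on TSV inputs:

```bash
sgfc synth --n-regions 200 --n-subjects 20 --out-dir data/
sgfc sgfc --fc data/fc.tsv --sc data/sc.tsv --regions data/regions.tsv --out-dir out/
sgfc run --config run.yaml       # full pipeline from a YAML config
```

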