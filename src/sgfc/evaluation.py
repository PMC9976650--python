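"""Recovery and calibration experiments on synthetic ground truth.

Each function sets up a synthetic instance at the package's default
study conditions, runs the relevant part of the pipeline, and scores
it against the planted ground truth.  These are the measurements the
package's quantitative claims rest on; the test suite and the
reproduction script both call them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from ._rand import derive_rng, derive_seed
from .consensus import ConsensusConfig, build_consensus, frequency_consensus
from .core import (
    SgfcConfig,
    bin_stats,
    euclidean_distances,
    fd_bin_count,
    smooth_sgfc,
)
from .gradient import GradientConfig, embed_fc
from .nulls import network_enrichment, spin_permutations
from .summaries import fit_exponential, positive_strength
from .synth import SynthParams, generate_cohort, generate_fc, generate_regions, generate_sc

__all__ = [
    "make_instance",
    "self_consistency_deviation",
    "planted_recovery_fraction",
    "enrichment_recovery",
    "gradient_recovery_r",
    "consensus_check",
    "stability_pair",
    "spin_pvalue_sample",
]


def make_instance(seed: int, **overrides):
    """Regions, SC, FC and planted edges at the default conditions."""
    params = SynthParams(seed=seed, **overrides)
    regions = generate_regions(params.n_regions, seed)
    sc = generate_sc(regions, params)
    fc, planted = generate_fc(regions, sc, params)
    return regions, sc, fc, planted, params


def self_consistency_deviation(seed: int, n_regions: int = 100) -> tuple[float, float]:
    """Max |per-bin mean| and |per-bin sd - 1| of the z-transform
    applied back to the connected edges themselves."""
    regions, sc, fc, _, _ = make_instance(seed, n_regions=n_regions)
    d = euclidean_distances(regions)
    iu = np.triu_indices(regions.n, k=1)
    conn = sc.binary_mask[iu]
    scheme = bin_stats(fc, sc, d, fd_bin_count(d[iu][conn]))
    idx = scheme.bin_index(d[iu][conn])
    w = fc.weights[iu][conn]
    worst_mu, worst_sd = 0.0, 0.0
    for b in np.where(scheme.valid)[0]:
        z = (w[idx == b] - scheme.mu[b]) / scheme.sigma[b]
        worst_mu = max(worst_mu, abs(float(z.mean())))
        worst_sd = max(worst_sd, abs(float(z.std(ddof=1)) - 1.0))
    return worst_mu, worst_sd


def planted_recovery_fraction(seed: int, top_k: int = 60) -> float:
    """Fraction of planted edges ranking in the sgFC top ``top_k``."""
    regions, sc, fc, planted, _ = make_instance(seed)
    d = euclidean_distances(regions)
    sg = smooth_sgfc(fc, sc, d, SgfcConfig())
    iu = np.triu_indices(regions.n, k=1)
    z = sg.z[iu]
    defined = np.isfinite(z)
    order = np.argsort(z[defined])[::-1][:top_k]
    ii = iu[0][defined][order]
    jj = iu[1][defined][order]
    top = {(int(i), int(j)) for i, j in zip(ii, jj)}
    hits = sum(1 for e in planted if e in top)
    return hits / len(planted)


def _strength_residuals(regions, sc, fc):
    d = euclidean_distances(regions)
    sg = smooth_sgfc(fc, sc, d, SgfcConfig())
    mask = sg.defined
    fit = fit_exponential(
        positive_strength(fc.weights, mask), positive_strength(sg.z, mask)
    )
    return fit.residuals


def enrichment_recovery(seed: int, n_perms: int = 1000) -> dict:
    """Does the planted-node network carry the largest strength residual
    and pass the spin-based Bonferroni test?"""
    regions, sc, fc, planted, params = make_instance(seed)
    residuals = _strength_residuals(regions, sc, fc)
    labels = regions.network_label
    n_pl = max(2, int(round(regions.n * params.planted_node_fraction)))
    planted_nodes = np.argsort(regions.gradient_truth, kind="stable")[-n_pl:]
    vals, counts = np.unique(labels[planted_nodes], return_counts=True)
    planted_network = vals[np.argmax(counts)]

    means = {
        lab: float(residuals[labels == lab].mean()) for lab in sorted(set(labels), key=str)
    }
    top_network = max(means, key=means.get)
    spins = spin_permutations(regions, n_perms, derive_seed(seed, "eval-spins"))
    enr = network_enrichment(residuals, labels, spins)
    row = enr[enr["network"] == planted_network].iloc[0]
    return {
        "planted_network": str(planted_network),
        "top_network": str(top_network),
        "top_is_planted": top_network == planted_network,
        "t": float(row["t"]),
        "p_perm": float(row["p_perm"]),
        "significant_bonferroni": bool(row["significant_bonferroni"]),
    }


def gradient_recovery_r(seed: int, config: GradientConfig = GradientConfig()) -> float:
    """|Pearson r| between diffusion component 1 and the planted gradient."""
    regions, _, fc, _, _ = make_instance(seed)
    result = embed_fc(fc, config)
    return float(abs(stats.pearsonr(result.components[:, 0], regions.gradient_truth)[0]))


def consensus_check(seed: int, n_subjects: int = 20, perturbation: float = 0.1) -> dict:
    """Density and length-distribution guarantees of the consensus.

    Returns the consensus/mean-subject edge-count deviation, the bin
    count, and the KS distances (consensus and frequency-only baseline
    at matched density) against the pooled subject edge lengths.
    """
    params = SynthParams(seed=seed)
    regions = generate_regions(params.n_regions, seed)
    cohort = generate_cohort(regions, params, n_subjects, perturbation=perturbation)
    d = euclidean_distances(regions)
    cons = build_consensus(cohort, d, regions.hemisphere, ConsensusConfig())
    mean_edges = float(np.mean([sc.n_edges for sc in cohort]))
    n_bins = len(getattr(cons, "bin_report", [])) or 1

    pooled_lengths = np.concatenate(
        [d[sc.edge_list()[:, 0], sc.edge_list()[:, 1]] for sc in cohort]
    )
    e = cons.edge_list()
    cons_lengths = d[e[:, 0], e[:, 1]]
    freq = frequency_consensus(cohort, cons.n_edges)
    ef = freq.edge_list()
    freq_lengths = d[ef[:, 0], ef[:, 1]]
    ks_cons = float(stats.ks_2samp(cons_lengths, pooled_lengths).statistic)
    ks_freq = float(stats.ks_2samp(freq_lengths, pooled_lengths).statistic)
    from .consensus import auto_bin_count

    return {
        "consensus_edges": cons.n_edges,
        "mean_subject_edges": mean_edges,
        "count_deviation": abs(cons.n_edges - mean_edges),
        "n_length_bins": auto_bin_count(cohort),
        "ks_consensus": ks_cons,
        "ks_frequency_only": ks_freq,
    }


def stability_pair(
    seed: int, n_subjects: int = 20, perturbation: float = 0.1
) -> dict:
    """Fig-5-style split stability: one ground truth, two independently
    perturbed cohorts, correlate the resulting sgFC maps."""
    params = SynthParams(seed=seed)
    regions = generate_regions(params.n_regions, seed)
    group_sc = generate_sc(regions, params)
    fc, _ = generate_fc(regions, group_sc, params)
    d = euclidean_distances(regions)
    out = []
    for half in (0, 1):
        p_half = dataclasses.replace(params, seed=derive_seed(seed, "half", half))
        cohort = generate_cohort(
            regions, p_half, n_subjects, perturbation=perturbation, group_sc=group_sc
        )
        cons = build_consensus(cohort, d, regions.hemisphere, ConsensusConfig())
        sg = smooth_sgfc(fc, cons, d, SgfcConfig())
        out.append(sg.z)
    za, zb = out
    iu = np.triu_indices(regions.n, k=1)
    both = np.isfinite(za[iu]) & np.isfinite(zb[iu])
    weight_r = float(np.corrcoef(za[iu][both], zb[iu][both])[0, 1])
    strength_r = float(
        np.corrcoef(positive_strength(za), positive_strength(zb))[0, 1]
    )
    return {"weight_r": weight_r, "strength_r": strength_r}


def spin_pvalue_sample(
    seed: int,
    n_maps: int = 200,
    n_perms: int = 500,
    n_regions: int = 100,
) -> np.ndarray:
    """Permutation p-values for white-noise maps (label-independent
    null); one p per replicate map, taken from the largest network."""
    regions = generate_regions(n_regions, seed)
    spins = spin_permutations(regions, n_perms, derive_seed(seed, "unif-spins"))
    labels = regions.network_label
    vals, counts = np.unique(labels, return_counts=True)
    target = vals[np.argmax(counts)]
    rng = derive_rng(seed, "null-maps")
    ps = np.empty(n_maps)
    for m in range(n_maps):
        values = rng.normal(size=regions.n)
        enr = network_enrichment(values, labels, spins)
        ps[m] = float(enr[enr["network"] == target]["p_perm"].iloc[0])
    return ps
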