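"""Synthetic spatially embedded connectomes.

Generates region geometries, structural connectomes, functional
connectomes and multi-subject cohorts that reproduce the statistical
regularities the sgFC method relies on: exponential distance decay of
structural connection probability and of functional weight, sparse
structural density (~2% at a few hundred to a thousand nodes),
systematically stronger functional weights on structurally connected
pairs, a planted smooth unimodal–transmodal-like gradient, and a set
of planted anomalously strong long-range unconnected edges
concentrated in the top-gradient node subset.  The planted edges and
gradient are the ground truth that recovery tests score against.

Geometry: regions live on two hemispherical shells displaced along x
by twice the shell radius, so inter-hemispheric pairs dominate the
long-distance tail, as in real brains.  Functional weights are
constructed directly in matrix space (not via latent time series),
trading positive-semidefiniteness for exact control of the planted
effects; an optional nearest-correlation projection is available but
off by default because the sgFC transform consumes weights, not
covariance structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rand import derive_rng
from .core import euclidean_distances
from .matrices import FunctionalConnectome, StructuralConnectome
from .regions import RegionSet

__all__ = [
    "SynthParams",
    "NETWORK_NAMES",
    "generate_regions",
    "generate_sc",
    "generate_fc",
    "generate_cohort",
    "project_nearest_correlation",
]

log = logging.getLogger(__name__)

# Synthetic analogues of the seven canonical intrinsic networks, ordered
# along the planted unimodal -> transmodal hierarchy.
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

SHELL_RADIUS_MM = 50.0  # hemisphere shell radius; centers displaced by 2x this


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for the synthetic generator.

    Lengths in mm; couplings dimensionless (FC weight units).

    ``planted_edge_boost`` is in units of the local (distance-matched)
    standard deviation of connected FC weights.
    ``connected_noise_inflation`` multiplies the pair noise on
    structurally connected pairs, modeling the large weight
    heterogeneity of monosynaptic coupling visible in empirical
    weight-vs-distance clouds; it keeps the pair noise of unconnected
    edges well below the local connected sd.  ``gradient_similarity``
    and ``gradient_similarity_scale`` define the planted hierarchy: a
    similarity kernel exp(-|g_i - g_j| / scale) that makes regions
    with nearby gradient positions coactivate — the 1-D manifold the
    diffusion embedding recovers.  ``network_coupling`` (with its
    floor and power shaping) adds a polysynaptic within-network
    coactivation excess that grows sharply toward the top of the
    hierarchy, the transmodal phenomenon the enrichment analyses
    detect.  ``sc_long_range_fraction`` mixes a distance-uniform
    component into the connection probability so connected (reference)
    edges exist at every distance, as in tractography data.
    """

    n_regions: int = 200
    sc_density_target: float = 0.02
    sc_decay_length: float = 30.0
    fc_decay_length: float = 60.0
    fc_amplitude: float = 0.25
    fc_connected_boost: float = 0.5
    planted_edge_count: int = 30
    planted_edge_boost: float = 3.0
    planted_node_fraction: float = 1.0 / 7.0
    noise_sd: float = 0.06
    connected_noise_inflation: float = 3.0
    gradient_similarity: float = 0.5
    gradient_similarity_scale: float = 0.35
    network_coupling: float = 0.5
    network_coupling_floor: float = 0.0
    network_coupling_power: float = 8.0
    sc_long_range_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 8:
            raise ValueError("n_regions must be >= 8")
        if self.fc_amplitude <= 0:
            raise ValueError("fc_amplitude must be strictly positive")
        for name in ("sc_decay_length", "fc_decay_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("sc_density_target", "planted_node_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.planted_edge_count < 0:
            raise ValueError("planted_edge_count must be nonnegative")
        if self.connected_noise_inflation < 1:
            raise ValueError("connected_noise_inflation must be >= 1")
        if not 0.0 <= self.sc_long_range_fraction < 1.0:
            raise ValueError("sc_long_range_fraction must be in [0, 1)")


def generate_regions(n: int, seed: int, n_networks: int = len(NETWORK_NAMES)) -> RegionSet:
    """Sample a synthetic bilateral region geometry.

    Regions are split evenly between hemispheres (left takes the extra
    one when n is odd) and placed on two hemispherical shells of radius
    ``SHELL_RADIUS_MM`` whose centers are displaced along x by twice
    the radius, with each shell opening away from the midline; all
    inter-hemispheric distances therefore exceed all intra-hemispheric
    ones.  ``sphere_coord`` is the within-hemisphere unit direction,
    ``gradient_truth`` is the distance from the midline plane (|x|)
    min-max rescaled to [0, 1] — a smooth, bilaterally mirrored
    hierarchy whose apex regions lie at the lateral poles, so apex-to-
    apex pairs span the longest inter-hemispheric distances.  Network
    labels are consecutive gradient bands — spatially contiguous
    bilateral patches, named after the canonical intrinsic networks in
    hierarchy order.
    """
    if n < 8:
        raise ValueError("need at least 8 regions")
    rng = derive_rng(seed, "regions")
    n_left = n // 2 + n % 2
    n_right = n - n_left
    R = SHELL_RADIUS_MM

    def shell(m: int, side: int) -> tuple[np.ndarray, np.ndarray]:
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u[:, 0] = side * np.abs(u[:, 0])  # open away from the midline
        center = np.array([side * R, 0.0, 0.0])
        return center + R * u, u

    cen_l, sph_l = shell(n_left, -1)
    cen_r, sph_r = shell(n_right, +1)
    centroids = np.vstack([cen_l, cen_r])
    sphere = np.vstack([sph_l, sph_r])
    hemisphere = np.array(["left"] * n_left + ["right"] * n_right, dtype=object)

    lat = np.abs(centroids[:, 0])
    gradient = (lat - lat.min()) / (lat.max() - lat.min())

    labels = np.empty(n, dtype=object)
    order = np.argsort(gradient, kind="stable")
    names = NETWORK_NAMES[:n_networks] if n_networks <= len(NETWORK_NAMES) else tuple(
        f"net{i}" for i in range(n_networks)
    )
    for band, idx in enumerate(np.array_split(order, len(names))):
        labels[idx] = names[band]

    return RegionSet(
        region_id=np.arange(n),
        centroids=centroids,
        hemisphere=hemisphere,
        network_label=labels,
        sphere_coord=sphere,
        gradient_truth=gradient,
    )


def generate_sc(regions: RegionSet, params: SynthParams) -> StructuralConnectome:
    """Distance-decaying random structural connectome.

    Edge (i, j) appears with probability proportional to a mixture of
    exp(-d_ij / sc_decay_length) and (with weight
    ``sc_long_range_fraction``) a distance-uniform component that keeps
    a thin tail of long-range edges — the callosal-like projections
    real tractography finds at every distance, which the method's
    distance-matched reference distribution depends on.  Probabilities
    are rescaled so the expected binary density equals
    ``sc_density_target``; values that would exceed 1 are clamped with
    a logged warning.  Edge weights are positive and decay with
    distance with lognormal scatter, mimicking streamline-count-like
    weights.
    """
    rng = derive_rng(params.seed, "sc")
    d = euclidean_distances(regions)
    n = regions.n
    iu = np.triu_indices(n, k=1)
    decay = np.exp(-d[iu] / params.sc_decay_length)
    f = params.sc_long_range_fraction
    shape = (1.0 - f) * decay / decay.sum() + f / decay.size
    p = params.sc_density_target * decay.size * shape
    if p.max() > 1.0:
        log.warning(
            "density target %.3f unreachable for %d pairs; clamping probabilities at 1",
            params.sc_density_target,
            int((p > 1.0).sum()),
        )
        p = np.minimum(p, 1.0)
    present = rng.random(p.size) < p
    w = np.zeros((n, n))
    weights = np.exp(-d[iu][present] / params.sc_decay_length) * rng.lognormal(
        0.0, 0.25, size=int(present.sum())
    )
    w[iu[0][present], iu[1][present]] = weights
    return StructuralConnectome(weights=w + w.T)


def _local_connected_sigma(
    fc_weights: np.ndarray,
    sc: StructuralConnectome,
    d: np.ndarray,
    pairs: np.ndarray,
    window_mm: float = 12.5,
    min_edges: int = 10,
) -> np.ndarray:
    """Sd of connected FC weights at distances comparable to each pair.

    Uses a symmetric distance window around each pair's length,
    widening it until at least ``min_edges`` connected edges fall
    inside, so the estimate never rests on a handful of edges.
    """
    iu = np.triu_indices(sc.n, k=1)
    conn = sc.binary_mask[iu]
    d_conn = d[iu][conn]
    w_conn = fc_weights[iu][conn]
    if d_conn.size < 2:
        raise ValueError("need at least 2 connected edges for a local sd")
    sig = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        width = window_mm
        while True:
            sel = np.abs(d_conn - d[i, j]) <= width
            if sel.sum() >= min(min_edges, d_conn.size):
                break
            width *= 1.5
        sig[k] = float(w_conn[sel].std(ddof=1))
    return sig


def _symmetrize_unit_diag(w: np.ndarray) -> np.ndarray:
    w = (w + w.T) / 2.0
    w = np.clip(w, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return w


def generate_fc(
    regions: RegionSet,
    sc: StructuralConnectome,
    params: SynthParams,
    project_correlation: bool = False,
) -> tuple[FunctionalConnectome, list[tuple[int, int]]]:
    """Functional connectome with planted anomalous long-range edges.

    Construction, applied to the upper triangle and symmetrized:

    1. baseline b(d) = fc_amplitude * exp(-d / fc_decay_length)
       (empirical short-range FC saturates well below 1);
    2. structurally connected pairs gain fc_connected_boost * b(d);
    3. a rank-1 term gradient_coupling * g_i g_j (g = gradient_truth)
       plants the smooth hierarchy: high-gradient ("transmodal")
       regions coactivate more with each other at every distance;
    3b. same-network pairs gain network_coupling, the bilateral
       intrinsic-network block structure of resting-state FC (this is
       what keeps homologous regions' connectivity profiles similar
       across hemispheres);
    4. Gaussian pair noise, sd noise_sd, inflated by
       connected_noise_inflation on connected pairs;
    5. ``planted_edge_count`` structurally unconnected pairs — drawn
       among pairs longer than the 75th distance percentile with both
       endpoints in the planted node subset (the top
       ``planted_node_fraction`` of regions by gradient_truth) — gain
       planted_edge_boost times the local sd of connected weights at
       comparable distance;
    6. clipping to [-1, 1], unit diagonal.

    Returns the functional connectome and the planted pair list.
    """
    if sc.n != regions.n:
        raise ValueError("sc must be defined on the same region set")
    rng = derive_rng(params.seed, "fc")
    n = regions.n
    d = euclidean_distances(regions)
    b = params.fc_amplitude * np.exp(-d / params.fc_decay_length)
    conn = sc.binary_mask

    w = b.copy()
    w[conn] += params.fc_connected_boost * b[conn]
    if params.gradient_similarity != 0.0 and regions.gradient_truth is not None:
        g = regions.gradient_truth
        dg = np.abs(g[:, None] - g[None, :])
        w += params.gradient_similarity * np.exp(-dg / params.gradient_similarity_scale)
    if params.network_coupling != 0.0 and regions.network_label is not None:
        same = regions.network_label[:, None] == regions.network_label[None, :]
        if regions.gradient_truth is not None:
            g = regions.gradient_truth
            gmean = (g[:, None] + g[None, :]) / 2.0
            ramp = (params.network_coupling_floor
                    + (1.0 - params.network_coupling_floor)
                    * gmean ** params.network_coupling_power)
        else:
            ramp = 1.0
        block = params.network_coupling * same * ramp
        block[conn] = 0.0  # polysynaptic block excess; keeps the reference clean
        np.fill_diagonal(block, 0.0)
        w += block

    noise = rng.normal(0.0, 1.0, size=(n, n))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    sd = np.full((n, n), params.noise_sd)
    sd[conn] *= params.connected_noise_inflation
    w = w + sd * noise

    planted: list[tuple[int, int]] = []
    if params.planted_edge_count > 0:
        if regions.gradient_truth is None:
            raise ValueError("planted edges require gradient_truth on the regions")
        n_planted_nodes = max(2, int(round(n * params.planted_node_fraction)))
        planted_nodes = np.argsort(regions.gradient_truth, kind="stable")[-n_planted_nodes:]
        in_set = np.zeros(n, dtype=bool)
        in_set[planted_nodes] = True
        iu = np.triu_indices(n, k=1)
        d75 = np.percentile(d[iu], 75)
        eligible = (
            ~conn[iu]
            & (d[iu] > d75)
            & in_set[iu[0]]
            & in_set[iu[1]]
        )
        n_eligible = int(eligible.sum())
        if n_eligible < params.planted_edge_count:
            raise ValueError(
                f"only {n_eligible} eligible long-distance unconnected pairs "
                f"inside the planted node set; {params.planted_edge_count} requested "
                f"(shortfall {params.planted_edge_count - n_eligible})"
            )
        pick = rng.choice(n_eligible, size=params.planted_edge_count, replace=False)
        ii = iu[0][eligible][pick]
        jj = iu[1][eligible][pick]
        pairs = np.column_stack([ii, jj])
        sigma_local = _local_connected_sigma(w, sc, d, pairs)
        for (i, j), s in zip(pairs, sigma_local):
            w[i, j] += params.planted_edge_boost * s
            w[j, i] = w[i, j]
        planted = [(int(i), int(j)) for i, j in pairs]

    w = _symmetrize_unit_diag(w)
    if project_correlation:
        w = project_nearest_correlation(w)
    return FunctionalConnectome(weights=w), planted


def project_nearest_correlation(
    w: np.ndarray, max_iter: int = 100, tol: float = 1e-7
) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections.

    Optional post-processing for consumers that need a positive
    semidefinite functional matrix; the sgFC transform itself does not.
    """
    x = np.asarray(w, float).copy()
    ds = np.zeros_like(x)
    y = x.copy()
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh(r)
        x_new = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        ds = x_new - r
        y_new = x_new.copy()
        np.fill_diagonal(y_new, 1.0)
        y_new = np.clip(y_new, -1.0, 1.0)
        if np.max(np.abs(y_new - y)) < tol:
            y = y_new
            break
        y = y_new
    return _symmetrize_unit_diag(y)


def generate_cohort(
    regions: RegionSet,
    params: SynthParams,
    n_subjects: int,
    perturbation: float = 0.1,
    length_bias: float = 2.0,
    weight_jitter: float = 0.0,
    group_sc: StructuralConnectome | None = None,
    n_length_bins: int = 10,
) -> list[StructuralConnectome]:
    """Per-subject structural connectomes around a shared group truth.

    Each subject independently deletes true edges — with probability
    increasing with edge length (mean ``perturbation``; the longest
    edges are dropped ``length_bias`` times more often than average,
    emulating long-streamline dropout in deterministic tractography) —
    and inserts an equal expected number of false edges whose lengths
    are drawn to match the group-truth edge length distribution
    (equal-width bins over the true edge lengths).  Inserted edge
    weights are sampled from the true weights of their bin.
    ``weight_jitter`` > 0 additionally applies lognormal jitter to
    retained edge weights.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not 0.0 <= perturbation < 1.0:
        raise ValueError("perturbation must be in [0, 1)")
    if group_sc is None:
        group_sc = generate_sc(regions, params)
    d = euclidean_distances(regions)
    n = regions.n
    edges = group_sc.edge_list()
    if len(edges) == 0:
        raise ValueError("group-truth connectome has no edges")
    m = len(edges)
    lengths = d[edges[:, 0], edges[:, 1]]
    weights = group_sc.weights[edges[:, 0], edges[:, 1]]
    # deletion probability ramps linearly with length rank: mean = 1,
    # longest edge deleted length_bias times more often than average
    rank = np.argsort(np.argsort(lengths, kind="stable"), kind="stable")
    u = rank / max(m - 1, 1)
    shape = np.clip((2.0 - length_bias) + 2.0 * (length_bias - 1.0) * u, 0.0, None)
    shape /= shape.mean()
    p_del = np.clip(perturbation * shape, 0.0, 0.95)

    lo, hi = lengths.min(), lengths.max()
    bins = np.linspace(lo, hi, n_length_bins + 1)
    e_bin = np.clip(np.searchsorted(bins, lengths, side="right") - 1, 0, n_length_bins - 1)
    bin_counts = np.bincount(e_bin, minlength=n_length_bins).astype(float)

    iu = np.triu_indices(n, k=1)
    non_mask = ~group_sc.binary_mask[iu]
    non_pairs = np.column_stack([iu[0][non_mask], iu[1][non_mask]])
    non_len = d[non_pairs[:, 0], non_pairs[:, 1]]
    non_bin = np.clip(np.searchsorted(bins, non_len, side="right") - 1, 0, n_length_bins - 1)
    non_bin[non_len < lo] = 0
    non_bin[non_len > hi] = n_length_bins - 1

    cohort = []
    for subj in range(n_subjects):
        rng = derive_rng(params.seed, "cohort", subj)
        w = group_sc.weights.copy()
        if perturbation > 0.0:
            drop = rng.random(m) < p_del
            n_drop = int(drop.sum())
            w[edges[drop, 0], edges[drop, 1]] = 0.0
            w[edges[drop, 1], edges[drop, 0]] = 0.0
            if n_drop:
                # insertion lengths follow the group-truth distribution
                ins_bins = rng.choice(
                    n_length_bins, size=n_drop, p=bin_counts / bin_counts.sum()
                )
                for b, k in zip(*np.unique(ins_bins, return_counts=True)):
                    cand = np.where(non_bin == b)[0]
                    if cand.size == 0:
                        log.warning("no false-edge candidates in length bin %d", b)
                        continue
                    take = rng.choice(cand.size, size=min(int(k), cand.size), replace=False)
                    src_w = weights[e_bin == b]
                    for t in cand[take]:
                        i, j = non_pairs[t]
                        w_new = float(rng.choice(src_w)) if src_w.size else float(weights.mean())
                        w[i, j] = w[j, i] = w_new
        if weight_jitter > 0.0:
            mask = np.triu(w > 0, k=1)
            jit = rng.lognormal(0.0, weight_jitter, size=int(mask.sum()))
            w[mask] *= jit
            w = np.triu(w, k=1)
            w = w + w.T
        cohort.append(StructuralConnectome(weights=w))
    return cohort
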