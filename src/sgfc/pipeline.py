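"""End-to-end orchestration and run comparison.

A run either synthesizes a dataset (regions + cohort of structural
connectomes + functional connectome) or loads matrices from TSV, then
chains: consensus (when a cohort is present) -> sgFC transform ->
structure-only baseline -> node/network summaries -> diffusion
gradient -> spin-based network enrichment, writing every artifact as
TSV plus a JSON manifest with content hashes.  Runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from ._rand import derive_seed
from .consensus import ConsensusConfig, binary_density, build_consensus
from .core import (
    SgfcConfig,
    euclidean_distances,
    smooth_sgfc,
    standardize_by_connected_global,
)
from .gradient import GradientConfig, embed_fc, orient_gradient
from .matrices import FunctionalConnectome, StructuralConnectome
from .nulls import network_enrichment, spin_permutations
from .summaries import (
    fit_exponential,
    positive_strength,
    residual_gradient_correlation,
    summary_ratios,
    within_between_means,
)
from .synth import SynthParams, generate_cohort, generate_fc, generate_sc, generate_regions

__all__ = ["RunConfig", "run_pipeline", "compare_runs"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of {input paths, synthesis}.

    For synthetic runs set ``synth`` (and optionally ``n_subjects`` for
    a cohort + consensus stage); for file runs set ``region_path``,
    ``fc_path`` and either ``sc_path`` or ``cohort_paths``.

    ``seed`` is the run's single source of randomness: each stochastic
    stage (synthesis, spins) derives its own sub-seed from it by stage
    name, so the seed carried inside ``synth`` is ignored and the same
    config always reproduces the same bytes.
    """

    out_dir: str | Path = "sgfc_run"
    seed: int = 0
    synth: SynthParams | None = None
    n_subjects: int = 0
    region_path: str | None = None
    fc_path: str | None = None
    sc_path: str | None = None
    cohort_paths: list[str] = field(default_factory=list)
    subject_perturbation: float = 0.1
    sgfc: SgfcConfig = field(default_factory=SgfcConfig)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    n_perms: int = 1000

    def __post_init__(self) -> None:
        has_paths = self.region_path is not None or self.fc_path is not None
        has_synth = self.synth is not None
        if has_paths == has_synth:
            raise ValueError(
                "exactly one of {input paths, synthesis parameters} must be supplied"
            )
        if has_paths and (self.region_path is None or self.fc_path is None):
            raise ValueError("file runs need region_path and fc_path")
        if has_paths and self.sc_path is None and not self.cohort_paths:
            raise ValueError("file runs need sc_path or cohort_paths")

    def to_jsonable(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, Path):
                return str(v)
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.synth is not None:
        params = dataclasses.replace(
            config.synth, seed=derive_seed(config.seed, "synth")
        )
        regions = generate_regions(params.n_regions, params.seed)
        group_sc = generate_sc(regions, params)
        fc, planted = generate_fc(regions, group_sc, params)
        cohort = None
        if config.n_subjects >= 2:
            cohort = generate_cohort(
                regions,
                params,
                config.n_subjects,
                perturbation=config.subject_perturbation,
                group_sc=group_sc,
            )
        return regions, group_sc, cohort, fc, planted
    regions = sio.read_regions(config.region_path)
    fc_w, _ = sio.read_matrix(config.fc_path)
    fc = FunctionalConnectome(weights=fc_w)
    cohort = None
    if config.cohort_paths:
        cohort = [
            StructuralConnectome(weights=sio.read_matrix(p)[0])
            for p in config.cohort_paths
        ]
        sc = None
    else:
        sc = StructuralConnectome(weights=sio.read_matrix(config.sc_path)[0])
    return regions, sc, cohort, fc, []


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "stages": [],
        "files": {},
    }
    artifacts: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = path

    try:
        stage = "inputs"
        regions, sc, cohort, fc, planted = _load_inputs(config)
        d = euclidean_distances(regions)
        emit("regions.tsv", lambda p: sio.write_regions(regions, p))
        emit("fc.tsv", lambda p: sio.write_matrix(fc.weights, regions.region_id, p))
        manifest["stages"].append(stage)

        if cohort is not None:
            stage = "consensus"
            sc = build_consensus(cohort, d, regions.hemisphere, config.consensus)
            rep = pd.DataFrame(getattr(sc, "bin_report", []))
            emit("consensus_bins.tsv", lambda p: rep.to_csv(p, sep="\t", index=False))
            manifest["consensus_density"] = binary_density(sc)
            manifest["stages"].append(stage)
        emit("sc.tsv", lambda p: sio.write_matrix(sc.weights, regions.region_id, p))

        stage = "sgfc"
        sg = smooth_sgfc(fc, sc, d, config.sgfc)
        baseline = standardize_by_connected_global(fc, sc)
        emit("sgfc.tsv", lambda p: sio.write_matrix(sg.z, regions.region_id, p))
        emit("sgfc_baseline.tsv",
             lambda p: sio.write_matrix(baseline, regions.region_id, p))
        (out / "sgfc_meta.json").write_text(
            json.dumps(sg.provenance, indent=2) + "\n"
        )
        artifacts["sgfc_meta.json"] = out / "sgfc_meta.json"
        manifest["stages"].append(stage)

        stage = "summaries"
        mask = sg.defined
        fc_strength = positive_strength(fc.weights, mask)
        sg_strength = positive_strength(sg.z, mask)
        fit = fit_exponential(fc_strength, sg_strength)
        table = pd.DataFrame(
            {
                "region_id": regions.region_id,
                "fc_strength": fc_strength,
                "sgfc_strength": sg_strength,
                "residual": fit.residuals,
            }
        )
        emit("strengths.tsv",
             lambda p: table.to_csv(p, sep="\t", index=False, na_rep="nan"))
        summary_rows = []
        if regions.network_label is not None:
            s_sg = within_between_means(sg.z, regions.network_label, mask)
            s_fc = within_between_means(baseline, regions.network_label, mask)
            ratios = summary_ratios(s_sg, s_fc)
            for lab in s_sg.within_mean:
                summary_rows.append(
                    {
                        "network": lab,
                        "sgfc_within_mean": s_sg.within_mean[lab],
                        "baseline_within_mean": s_fc.within_mean[lab],
                        "ratio": ratios[lab],
                        "n_entries": s_sg.within_count[lab],
                    }
                )
            summary_rows.append(
                {
                    "network": "__between__",
                    "sgfc_within_mean": s_sg.between_mean,
                    "baseline_within_mean": s_fc.between_mean,
                    "ratio": ratios["between"],
                    "n_entries": s_sg.between_count,
                }
            )
        net_df = pd.DataFrame(summary_rows)
        emit("network_summary.tsv",
             lambda p: net_df.to_csv(p, sep="\t", index=False, na_rep="nan"))
        fit_meta = {
            "a": fit.a, "b": fit.b, "r_squared": fit.r_squared,
            "n_excluded": fit.n_excluded,
        }
        manifest["stages"].append(stage)

        stage = "gradient"
        result = embed_fc(fc, config.gradient)
        if regions.gradient_truth is not None:
            result = orient_gradient(result, regions.gradient_truth)
            fit_meta["residual_gradient_r"] = residual_gradient_correlation(
                fit.residuals, result.components[:, 0]
            )
        grad_df = pd.DataFrame(
            result.components,
            columns=[f"g{i + 1}" for i in range(result.components.shape[1])],
        )
        grad_df.insert(0, "region_id", regions.region_id)
        emit("gradient.tsv", lambda p: grad_df.to_csv(p, sep="\t", index=False))
        (out / "fit_meta.json").write_text(json.dumps(fit_meta, indent=2) + "\n")
        artifacts["fit_meta.json"] = out / "fit_meta.json"
        manifest["stages"].append(stage)

        if (
            regions.sphere_coord is not None
            and regions.network_label is not None
            and config.n_perms >= 1
        ):
            stage = "enrichment"
            spins = spin_permutations(
                regions, config.n_perms, derive_seed(config.seed, "spins")
            )
            enr = network_enrichment(fit.residuals, regions.network_label, spins)
            emit("enrichment.tsv",
                 lambda p: enr.to_csv(p, sep="\t", index=False, na_rep="nan"))
            manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        for name, path in artifacts.items():
            manifest["files"][name] = _sha256(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed in stage '{stage}'") from exc

    if planted:
        pl = pd.DataFrame(planted, columns=["i", "j"])
        emit("planted_edges.tsv", lambda p: pl.to_csv(p, sep="\t", index=False))
    for name, path in artifacts.items():
        manifest["files"][name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def verify_manifest(run_dir: str | Path) -> bool:
    """Re-hash every listed artifact against the manifest."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    return all(
        _sha256(run_dir / name) == digest for name, digest in manifest["files"].items()
    )


def compare_runs(run_a: str | Path, run_b: str | Path) -> dict:
    """Consistency report between two runs sharing a region set.

    Pearson correlations of (a) the sgFC weights defined in both runs
    and (b) the sgFC positive node strengths.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    za, ids_a = sio.read_matrix(run_a / "sgfc.tsv")
    zb, ids_b = sio.read_matrix(run_b / "sgfc.tsv")
    if za.shape != zb.shape or not np.array_equal(ids_a, ids_b):
        raise ValueError("runs do not share a region set")
    iu = np.triu_indices(za.shape[0], k=1)
    both = np.isfinite(za[iu]) & np.isfinite(zb[iu])
    if both.sum() < 3:
        raise ValueError("fewer than 3 jointly defined sgFC edges")
    weight_r = float(np.corrcoef(za[iu][both], zb[iu][both])[0, 1])
    sa = positive_strength(za)
    sb = positive_strength(zb)
    strength_r = float(np.corrcoef(sa, sb)[0, 1])
    return {"sgfc_weight_r": weight_r, "sgfc_strength_r": strength_r}
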