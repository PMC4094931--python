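"""End-to-end analysis: standardize -> bandwidth -> MIM -> null -> network -> model.

:func:`analyze` runs the whole method on an in-memory
:class:`~minet.sample.SampleMatrix`; :func:`run_pipeline` wraps it with
file IO, writing every artifact plus a JSON run manifest (seeds, h, the
null-fit coefficients a and b, I0, package version) sufficient to
re-execute the run identically.  All randomness derives from one master
seed, split per stage, so a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .io import (
    PipelineConfig,
    load_dataset,
    write_json,
    write_mim_tsv,
)
from .kde import Bandwidth, select_bandwidth
from .linmodel import fit_output_models
from .mi import MIMatrix, compute_mim
from .network import Network, reconstruct, write_edgelist_tsv, write_graphml
from .sample import SampleMatrix
from .threshold import NullFit, calibrate_threshold

logger = logging.getLogger(__name__)


def stage_seeds(master_seed: int, n: int = 3) -> list[int]:
    """Derive one sub-seed per stochastic stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass
class PipelineResult:
    bandwidth: Bandwidth
    mim: MIMatrix
    null_fit: NullFit
    threshold: float
    network: Network
    model_metrics: dict | None
    manifest: dict


def analyze(data: SampleMatrix, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full reconstruction (and optional per-output models) in memory."""
    cfg = config or PipelineConfig()
    seed_bw, seed_perm, seed_split = stage_seeds(cfg.seed)

    if cfg.h_override is not None:
        bw = Bandwidth(h=cfg.h_override, method="fixed")
    else:
        bw = select_bandwidth(
            data, n_pairs=cfg.n_pairs, seed=seed_bw, mode=cfg.mode,
            deletion=cfg.deletion,
        )
    logger.info("bandwidth h=%.4f (%s)", bw.h, bw.method)

    mim = compute_mim(data, mode=cfg.mode, h=bw, deletion=cfg.deletion)
    null_fit, i0 = calibrate_threshold(
        data, mode=cfg.mode, h=bw, p_value=cfg.p_value,
        n_permutations=cfg.n_permutations, seed=seed_perm,
    )
    logger.info("null fit a=%.3f b=%.1f (R2=%.3f) -> I0=%.4f at p=%g",
                null_fit.a, null_fit.b, null_fit.fit_r2, i0, cfg.p_value)

    net = reconstruct(mim, i0)
    net.metadata.update({"p_value": cfg.p_value, "null_fit": null_fit.to_dict()})

    metrics = None
    if cfg.fit_models and data.output_names:
        metrics = fit_output_models(
            data, net, test_fraction=cfg.test_fraction, seed=seed_split
        )

    manifest = {
        "version": __version__,
        "dataset_label": data.dataset_label or cfg.dataset_label,
        "n_observations": data.n_observations,
        "n_complete": data.dropna().n_observations,
        "inputs": data.input_names,
        "outputs": data.output_names,
        "config": {
            "p_value": cfg.p_value,
            "n_permutations": cfg.n_permutations,
            "n_pairs": cfg.n_pairs,
            "h_override": cfg.h_override,
            "deletion": cfg.deletion,
            "mode": cfg.mode,
            "test_fraction": cfg.test_fraction,
            "seed": cfg.seed,
        },
        "stage_seeds": {"bandwidth": seed_bw, "permutation": seed_perm,
                        "split": seed_split},
        "h": bw.h,
        "h_method": bw.method,
        "null_fit": null_fit.to_dict(),
        "threshold": i0,
        "n_edges": len(net.edges),
    }
    return PipelineResult(
        bandwidth=bw, mim=mim, null_fit=null_fit, threshold=i0,
        network=net, model_metrics=metrics, manifest=manifest,
    )


def run_pipeline(
    inputs_path, outputs_path, out_dir, config: PipelineConfig | None = None
) -> PipelineResult:
    """File-to-file pipeline: read the two blocks, analyze, write artifacts.

    Writes ``mim.tsv``, ``null_fit.json``, ``network.graphml``,
    ``edges.tsv``, ``model_metrics.json`` (when models are fitted) and
    ``manifest.json`` under ``out_dir``.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = load_dataset(
        inputs_path, outputs_path,
        missing_token=cfg.missing_token, dataset_label=cfg.dataset_label,
    )
    result = analyze(data, cfg)

    write_mim_tsv(result.mim, out / "mim.tsv")
    write_json(result.null_fit.to_dict(), out / "null_fit.json")
    write_graphml(result.network, out / "network.graphml")
    write_edgelist_tsv(result.network, out / "edges.tsv")
    if result.model_metrics is not None:
        write_json(result.model_metrics, out / "model_metrics.json")
    write_json(result.manifest, out / "manifest.json")
    return result
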