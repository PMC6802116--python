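"""End-to-end de novo deconvolution pipeline.

Filter → for each scheduled trial rank: seed training, final seeded
factorisation, per-sample and per-gene NNLS projections, factor scoring
and linkage → compartment identification → minor labelling → final W/H
assembly → marker selection.

Runs are checkpointed per trial rank (TSV matrices plus a JSON manifest
recording the configuration and random seed), so an interrupted run
resumes at the last completed rank and reproduces the uninterrupted
result bit for bit.  All randomness derives from a single master seed;
each rank and each resampling repetition receives its own deterministic
stream, independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import factor_tree as ft
from .compartments import assemble_final, identify_compartments, label_minor
from .markers import select_markers
from .preprocess import filter_atac_loci, filter_expression_features
from .projection import project_compartment_weights, project_gene_weights
from .seed_training import train_seed
from .types import (
    CompartmentSet,
    ExpressionMatrix,
    FactorTree,
    FilteredMatrix,
    MarkerList,
    RunResult,
    ScheduleResult,
    TrainingConfig,
    ValidationError,
)

log = logging.getLogger("decompart")

__all__ = ["PipelineConfig", "DenovoResult", "run_denovo", "save_results"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and rank."""


@dataclass
class PipelineConfig:
    """Resolved configuration of a de novo run."""

    R: int = 10_000
    n_inits: int = 20
    mult_steps: int = 10
    resample_fraction: float = 0.8
    top_genes_consensus: int = 50
    seed_high: float = 1.0
    seed_low: float = 0.01
    rng_seed: int = 0
    datatype: str = "expression"  # or "atac"
    n_keep: Optional[int] = None  # default 5000 (expression) / 8000 (atac)
    K_min: int = 2
    K_max: int = 30
    include_unstable: bool = False
    checkpoint_dir: Optional[str] = None
    als_tol: float = 1e-6
    als_max_iter: int = 500

    def training_config(self, K_tilde: int) -> TrainingConfig:
        return TrainingConfig(
            K_tilde=K_tilde,
            R=self.R,
            n_inits=self.n_inits,
            mult_steps=self.mult_steps,
            resample_fraction=self.resample_fraction,
            top_genes_consensus=self.top_genes_consensus,
            seed_high=self.seed_high,
            seed_low=self.seed_low,
            rng_seed=self.rng_seed,
            als_tol=self.als_tol,
            als_max_iter=self.als_max_iter,
        )

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("checkpoint_dir")  # location does not affect the result
        return d


@dataclass
class DenovoResult:
    compartments: CompartmentSet
    tree: FactorTree
    markers: list[MarkerList]
    filtered: FilteredMatrix
    schedule: ScheduleResult
    config: PipelineConfig = field(default=None)


def _rank_rng_seq(cfg: PipelineConfig, K: int) -> np.random.SeedSequence:
    # per-rank stream independent of the order ranks are executed in
    return np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(K,))


def _compute_run(
    A: ExpressionMatrix, A_prime: FilteredMatrix, cfg: PipelineConfig, K: int
) -> RunResult:
    tcfg = cfg.training_config(K)
    seq = _rank_rng_seq(cfg, K)
    if K == 1:
        # rank-1 pseudo-run: no resampling/consensus, just one factorisation
        from .seed_training import inner_nmf

        rng = np.random.default_rng(seq)
        W, _ = inner_nmf(A_prime, 1, tcfg, rng)
    else:
        W = train_seed(A_prime, tcfg, seed_seq=seq).W_prime
    H_tilde = project_compartment_weights(W, A_prime)
    W_tilde = project_gene_weights(H_tilde, A)
    return RunResult(
        K_tilde=K,
        factor_ids=[f"{K}.{j + 1}" for j in range(K)],
        W_tilde=W_tilde,
        H_tilde=H_tilde,
        feature_ids=list(A.feature_ids),
        sample_ids=list(A.sample_ids),
    )


# ---------------------------------------------------------------------------
# checkpointing

def _ckpt_paths(directory: str, K: int) -> tuple[str, str]:
    return (
        os.path.join(directory, f"run_K{K}.W.tsv"),
        os.path.join(directory, f"run_K{K}.H.tsv"),
    )


def _manifest_path(directory: str) -> str:
    return os.path.join(directory, "manifest.json")


def _prepare_checkpoints(cfg: PipelineConfig) -> None:
    d = cfg.checkpoint_dir
    os.makedirs(d, exist_ok=True)
    mpath = _manifest_path(d)
    manifest = cfg.manifest()
    if os.path.exists(mpath):
        with open(mpath) as fh:
            if json.load(fh) != manifest:
                raise ValidationError(
                    f"checkpoint directory {d!r} belongs to a different "
                    "configuration; remove it or change checkpoint_dir"
                )
    else:
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1)


def _load_checkpoint(cfg: PipelineConfig, K: int) -> Optional[RunResult]:
    wpath, hpath = _ckpt_paths(cfg.checkpoint_dir, K)
    if not (os.path.exists(wpath) and os.path.exists(hpath)):
        return None
    Wdf = pd.read_csv(wpath, sep="\t", index_col=0, float_precision="round_trip")
    Hdf = pd.read_csv(hpath, sep="\t", index_col=0, float_precision="round_trip")
    return RunResult(
        K_tilde=K,
        factor_ids=[str(c) for c in Wdf.columns],
        W_tilde=Wdf.to_numpy(float),
        H_tilde=Hdf.to_numpy(float),
        feature_ids=[str(i) for i in Wdf.index],
        sample_ids=[str(c) for c in Hdf.columns],
    )


def _save_checkpoint(cfg: PipelineConfig, run: RunResult) -> None:
    wpath, hpath = _ckpt_paths(cfg.checkpoint_dir, run.K_tilde)
    # %.17g guarantees bit-exact float64 round-trips on resume
    pd.DataFrame(run.W_tilde, index=run.feature_ids, columns=run.factor_ids).to_csv(
        wpath, sep="\t", float_format="%.17g"
    )
    pd.DataFrame(run.H_tilde, index=run.factor_ids, columns=run.sample_ids).to_csv(
        hpath, sep="\t", float_format="%.17g"
    )


# ---------------------------------------------------------------------------

def run_denovo(A: ExpressionMatrix, config: PipelineConfig) -> DenovoResult:
    """Run the full de novo deconvolution on a non-negative matrix."""
    cfg = config
    if cfg.checkpoint_dir:
        _prepare_checkpoints(cfg)

    def stage(name: str, K, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            where = f"stage {name!r}" + (f" at K_tilde={K}" if K else "")
            raise PipelineError(f"{where}: {exc}") from exc

    if cfg.datatype == "expression":
        n_keep = cfg.n_keep or 5000
        A_prime = stage("filter", None, filter_expression_features, A, n_keep)
    elif cfg.datatype == "atac":
        n_keep = cfg.n_keep or 8000
        A_prime = stage("filter", None, filter_atac_loci, A, n_keep)
    else:
        raise ValidationError(f"unknown datatype {cfg.datatype!r}")
    log.info("filtered %d -> %d features", A.n_features, A_prime.n_features)

    tree = FactorTree()

    def get_run(K: int) -> RunResult:
        run = _load_checkpoint(cfg, K) if cfg.checkpoint_dir else None
        if run is None:
            run = stage("seed_training", K, _compute_run, A, A_prime, cfg, K)
            if cfg.checkpoint_dir:
                _save_checkpoint(cfg, run)
        return run

    def median_for_K(K: int) -> float:
        if (K - 1) not in tree.runs:
            ft.add_run(tree, get_run(K - 1))
        ft.add_run(tree, get_run(K))
        ft.link_runs(tree, K)
        med = ft.median_score(tree, K)
        log.info("K_tilde=%d median factor score %.3f", K, med)
        return med

    schedule = stage("schedule", None, ft.schedule_K, median_for_K, cfg.K_min, cfg.K_max)
    tree.considered_range = (schedule.considered_start, schedule.considered_end)

    selected = stage("identify", None, identify_compartments, tree)
    selected = stage("label_minor", None, label_minor, selected, tree)
    compset = stage(
        "assemble", None, assemble_final, selected, tree, cfg.include_unstable
    )
    log.info(
        "selected %d compartments (%s)",
        compset.n_compartments,
        ", ".join(f"{c.name}{c.label[0]}" for c in compset.compartments),
    )
    marker_lists = [
        stage("markers", None, select_markers, compset, k)
        for k in range(compset.n_compartments)
    ]
    return DenovoResult(
        compartments=compset,
        tree=tree,
        markers=marker_lists,
        filtered=A_prime,
        schedule=schedule,
        config=cfg,
    )


def save_results(result: DenovoResult, outdir: str) -> None:
    """Write compartments.tsv, W.tsv, H.tsv, markers.gmt, tree.json and the
    resolved configuration."""
    os.makedirs(outdir, exist_ok=True)
    cs = result.compartments
    pd.DataFrame(
        {
            "factor_id": [c.factor_id for c in cs.compartments],
            "label": [c.label for c in cs.compartments],
            "K_tilde": [c.K_tilde for c in cs.compartments],
            "score": [c.score for c in cs.compartments],
        }
    ).to_csv(os.path.join(outdir, "compartments.tsv"), sep="\t", index=False)
    pd.DataFrame(cs.W_final, index=cs.feature_ids, columns=cs.names).to_csv(
        os.path.join(outdir, "W.tsv"), sep="\t"
    )
    pd.DataFrame(cs.H_final, index=cs.names, columns=cs.sample_ids).to_csv(
        os.path.join(outdir, "H.tsv"), sep="\t"
    )
    from .io import write_gmt

    write_gmt(
        {ml.compartment_id: ml.markers for ml in result.markers},
        os.path.join(outdir, "markers.gmt"),
    )
    with open(os.path.join(outdir, "tree.json"), "w") as fh:
        fh.write(ft.tree_to_json(result.tree))
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(result.config.manifest(), fh, indent=1)
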