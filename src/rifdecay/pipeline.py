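"""Pipeline orchestration: configuration, stage wiring, run manifest.

A run executes simulate (optional) -> preprocess -> fit -> analyze, writes
every stage's tables, logs each discard/exclusion with a reason code, and
records a machine-readable manifest (package and library versions, seed,
thresholds, input hashes) so a run can be reproduced exactly.
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
import yaml

from . import __version__
from .synthetic_data import (
    DEFAULT_TIME_GRID,
    ExperimentConfig,
    generate_genome,
    simulate_stochastic,
    write_dataset,
)
from . import analysis, fitting, preprocess

logger = logging.getLogger("rifdecay")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML identically."""

    rng_seed: int = 0
    # inputs (ignored when simulate=True)
    annotation: str | None = None
    dataset_manifest: str | None = None
    spikes: str | None = None
    out_dir: str = "rifdecay_out"
    # simulation
    simulate: bool = True
    n_transcripts: int = 50
    scenario: str = "initiation_inhibitor"
    time_grid: list = field(default_factory=lambda: list(DEFAULT_TIME_GRID))
    depth: float = 400.0
    # thresholds
    bin_size: int = 300
    min_length: int = 1200
    min_t0_count: float = 20.0
    max_se_ratio: float = 1.0
    same_strand_only: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def segments_frame(fits) -> pd.DataFrame:
    return pd.DataFrame(
        [{"transcript_id": f.transcript_id, "bin_start": f.bin_start,
          "P": f.P, "T": f.T, "A": f.A, "se_P": f.se_P, "se_T": f.se_T,
          "se_A": f.se_A, "residual_norm": f.residual_norm,
          "converged": f.converged, "qc": f.qc} for f in fits]
    )


def results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dataclasses.asdict(r)
        row["discard_reasons"] = ";".join(row["discard_reasons"])
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of in-memory artifacts
    and writes segments.tsv, transcripts.tsv, analysis.json, exclusions.log
    and manifest.json under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "exclusions.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    input_hashes = {}
    try:
        if cfg.simulate:
            stage = "simulate"
            kins = generate_genome(cfg.n_transcripts, rng_seed=cfg.rng_seed)
            exp_cfg = ExperimentConfig(
                rng_seed=cfg.rng_seed, time_grid=tuple(cfg.time_grid),
                scenario=cfg.scenario, bin_size=cfg.bin_size, depth=cfg.depth,
            )
            ds = simulate_stochastic(kins, exp_cfg)
            manifest_path = write_dataset(ds, out / "simulated")
            ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        else:
            stage = "load"
            if cfg.dataset_manifest is None:
                raise FileNotFoundError(
                    "dataset_manifest is required when simulate is false"
                )
            manifest_path = Path(cfg.dataset_manifest)

        stage = "preprocess"
        for p in sorted(Path(manifest_path).parent.iterdir()):
            if p.is_file():
                input_hashes[p.name] = _sha256(p)
        matrices = preprocess.preprocess_dataset(
            manifest_path, bin_size=cfg.bin_size,
            min_t0_count=cfg.min_t0_count,
            same_strand_only=cfg.same_strand_only,
        )
        if not matrices:
            raise ValueError("no transcription units survived preprocessing")
        preprocess.write_matrices(matrices, out / "bins")

        stage = "fit"
        units = preprocess.exclude_overlapping(
            preprocess.load_annotation(
                Path(manifest_path).parent
                / yaml.safe_load(open(manifest_path))["annotation"]),
            same_strand_only=cfg.same_strand_only,
        )
        lengths = units.set_index("transcript_id")["length"].to_dict()
        fits, kept, discarded = fitting.fit_dataset(
            matrices, lengths, bin_size=cfg.bin_size,
            min_length=cfg.min_length, max_se_ratio=cfg.max_se_ratio,
        )
        segments_frame(fits).to_csv(out / "segments.tsv", sep="\t",
                                    index=False)
        results_frame(kept + discarded).to_csv(out / "transcripts.tsv",
                                               sep="\t", index=False)

        stage = "analyze"
        kept_df = results_frame(kept)
        abundance = pd.Series(
            {tid: float(m.raw_counts[:, 0].mean())
             for tid, m in matrices.items()}, name="abundance",
        )
        abundance.rename_axis("transcript_id").reset_index().to_csv(
            out / "abundance.tsv", sep="\t", index=False)
        summary = analysis.summarize_condition(cfg.scenario, kept_df,
                                               abundance)
        table, frac = analysis.classify_cotranscriptional(kept_df)
        table.to_csv(out / "cotranscriptional.tsv", sep="\t", index=False)
        report = {
            "condition": dataclasses.asdict(summary),
            "fraction_ratio_gt1": frac,
            "n_kept": len(kept), "n_discarded": len(discarded),
        }
        with open(out / "analysis.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    except Exception as exc:
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    logger.removeHandler(handler)
    handler.close()

    manifest = {
        "rifdecay_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.rng_seed,
        "config": dataclasses.asdict(cfg),
        "input_hashes": input_hashes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"matrices": matrices, "fits": fits, "kept": kept,
            "discarded": discarded, "report": report, "out_dir": out}
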