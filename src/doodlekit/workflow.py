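"""Configuration-driven end-to-end characterization runs.

``run_characterization`` ties the stages together for one FASTQ pool:
QC (trim, concatemer flagging, length/quality filters) -> per-read
statistics -> motif fraction table -> hierarchical clustering per length
class (< 250 nt and >= 250 nt) -> summary JSON with read-length statistics
(% of reads > 250 nt and > 1000 nt). All randomness flows from the single
``seed`` in the config, so re-running a config byte-reproduces its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as _clustering
from . import motifs as _motifs
from . import qc as _qc
from . import seqstats as _seqstats
from .reads import AdapterSet, ReadPool, load_fastq, write_fastq
from .simulate import DEFAULT_ADAPTER

__all__ = ["RunConfig", "ConfigurationError", "run_characterization", "load_config"]


class ConfigurationError(ValueError):
    """Bad or incomplete run configuration (raised before any computation)."""


@dataclass
class RunConfig:
    input_fastq: str
    output_dir: str
    seed: int = 0
    adapters: tuple[str, ...] = (DEFAULT_ADAPTER,)
    filter_params: _qc.FilterParams = field(default_factory=_qc.FilterParams)
    panel: _motifs.MotifPanel = field(default_factory=_motifs.MotifPanel)
    split_length: int = 250
    subsample: int = 500
    n_top: int = 7
    max_lag: int = 24
    n_sample: int = 600


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config document into a :class:`RunConfig`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "filter_params" in doc:
        doc["filter_params"] = _qc.FilterParams(**doc["filter_params"])
    if "panel" in doc:
        p = doc["panel"]
        doc["panel"] = _motifs.MotifPanel(
            motifs=tuple(p.get("motifs", _motifs.DEFAULT_PANEL_MOTIFS)),
            thresholds={int(k): int(v) for k, v in p.get(
                "thresholds", _motifs.DEFAULT_THRESHOLDS).items()},
            canonicalize_rotations=bool(p.get("canonicalize_rotations", False)),
        )
    if "adapters" in doc:
        doc["adapters"] = tuple(doc["adapters"])
    try:
        return RunConfig(**doc)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def _empty_report(outdir: Path, report: _qc.FilterReport) -> dict:
    summary = {
        "filter_report": report.to_dict(),
        "n_reads": 0,
        "pct_gt_250nt": 0.0,
        "pct_gt_1000nt": 0.0,
        "median_length_nt": None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_characterization(config: RunConfig) -> dict:
    """Run the full pool characterization described in the module docstring.

    Writes into ``config.output_dir``: filtered.fastq, filter_report.json,
    read_stats.tsv (per-read composition + autocorrelation profile),
    motif_fractions.tsv, cluster_assignments.tsv, transition_matrix.json and
    summary.json. Returns the summary dict.
    """
    in_path = Path(config.input_fastq)
    if not in_path.exists():
        raise ConfigurationError(f"input FASTQ not found: {in_path}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    pool = load_fastq(in_path)
    adapters = AdapterSet(config.adapters)
    filtered, report = _qc.qc_pipeline(pool, adapters, config.filter_params)
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    write_fastq(filtered, outdir / "filtered.fastq")

    if len(filtered) == 0:
        return _empty_report(outdir, report)

    lengths = filtered.lengths()
    max_lag = config.max_lag

    # per-read statistics table
    rows = []
    for r in filtered:
        comp = _seqstats.base_composition(r.sequence).as_dict()
        lag = min(max_lag, len(r) - 1)
        prof = _seqstats.autocorrelation_profile(r.sequence, lag)
        row = {"read_id": r.id, "length": len(r), **{f"frac_{b}": v for b, v in comp.items()}}
        for k in range(1, max_lag + 1):
            row[f"r_{k}"] = prof.r[k] if k <= lag else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "read_stats.tsv", sep="\t", index=False)

    # pooled transition matrix over reads > 65 nt
    try:
        tm = _seqstats.aggregate_transitions(filtered, config.filter_params.min_length_exclusive)
        tm_payload = {
            "bases": list(_seqstats.BASES),
            "probabilities": [
                [None if np.isnan(v) else float(v) for v in row] for row in tm.probabilities
            ],
            "support_counts": [int(v) for v in tm.support_counts],
        }
    except ValueError:
        tm_payload = None
    (outdir / "transition_matrix.json").write_text(json.dumps(tm_payload, indent=2))

    # motif fraction table on a seeded sample of reads > 65 nt
    try:
        table = _motifs.motif_fraction_table(
            filtered,
            config.panel,
            n_sample=config.n_sample,
            min_length=config.filter_params.min_length_exclusive,
            seed=config.seed,
        )
        table.to_csv(outdir / "motif_fractions.tsv", sep="\t")
        fractions = {m: float(v) for m, v in table["fraction"].items()}
    except ValueError:
        fractions = {}

    # clustering per length class
    results = _clustering.cluster_pool_by_length(
        filtered,
        panel=config.panel,
        split_length=config.split_length,
        subsample=config.subsample,
        n_top=config.n_top,
        max_lag=max_lag,
        seed=config.seed + 1,
    )
    _clustering.assignments_frame(results).to_csv(
        outdir / "cluster_assignments.tsv", sep="\t", index=False
    )

    summary = {
        "filter_report": report.to_dict(),
        "n_reads": int(len(filtered)),
        "pct_gt_250nt": float(100.0 * np.mean(lengths > 250)),
        "pct_gt_1000nt": float(100.0 * np.mean(lengths > 1000)),
        "median_length_nt": float(np.median(lengths)),
        "motif_fractions": fractions,
        "cluster_labels": {
            name: (sorted(set(res.labels.values())) if res is not None else [])
            for name, res in results.items()
        },
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
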