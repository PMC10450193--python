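"""End-to-end orchestration: simulate/load -> call operons -> termination
statistics -> motif profiling -> machine-readable summary.

Every run is driven by a :class:`RunConfig`; outputs are TSV tables plus
one ``summary.json`` stamped with the seed and a hash of the
configuration, and re-running the same configuration into a fresh
directory reproduces all bytes.
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

from opterm import genome_io
from opterm.genome_io import CoverageTrack, FullLengthRead, SiteRecord
from opterm.motif import (
    build_motif_profile,
    extract_terminator_windows,
    profile_to_frame,
    u_tract_score,
)
from opterm.operons import (
    CallerParams,
    build_transcription_units,
    call_operons,
    operons_to_frame,
    summarize_operons,
)
from opterm.simulate import (
    SimulationConfig,
    SimulationTruth,
    simulate_dataset,
    write_dataset,
)
from opterm.termination import (
    abundance_table,
    analyze_all_iotts,
    records_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``simulation`` (generate the dataset) or ``input_dir`` (a
    directory previously written by the simulator, located via its
    ``manifest.json``) must be given.
    """

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    caller: CallerParams = field(default_factory=CallerParams)
    pseudocount: float = 0.1
    window_up: int = 36
    window_down: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation/input_dir is required")
        if self.simulation is not None:
            self.simulation.seed = self.seed

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        fields = enc(dataclasses.asdict(self))
        fields.pop("out_dir", None)  # idempotent across output directories
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Dataset:
    """In-memory view of all evidence layers for one run."""

    sequences: dict
    genes: list
    tss: dict  # condition -> list[SiteRecord]
    tts: dict
    reads: dict  # condition -> list[FullLengthRead]
    coverage: dict  # (condition, replicate) -> list[CoverageTrack]
    conditions: list
    reference_condition: str
    depletion_condition: str | None


def load_dataset(input_dir: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`simulate.write_dataset`."""
    root = Path(input_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    files = manifest["files"]

    def paths(role):
        return [f for f in files if f["role"] == role]

    def require(role):
        hits = paths(role)
        if not hits:
            raise FileNotFoundError(f"manifest lists no {role!r} file")
        for f in hits:
            if not (root / f["path"]).exists():
                raise FileNotFoundError(f"missing input file: {root / f['path']}")
        return hits

    sequences = genome_io.read_genome(root / require("genome")[0]["path"])
    lengths = genome_io.contig_lengths(sequences)
    genes = genome_io.read_annotation(root / require("annotation")[0]["path"])
    conditions = list(manifest["conditions"])

    tss, tts, reads, coverage = {}, {}, {}, {}
    for f in require("tss"):
        tss[f["condition"]] = genome_io.read_sites(root / f["path"], "TSS", f["condition"])
    for f in require("tts"):
        tts[f["condition"]] = genome_io.read_sites(root / f["path"], "TTS", f["condition"])
    for f in require("reads"):
        reads[f["condition"]] = genome_io.read_reads(root / f["path"])
    for f in require("coverage"):
        key = (f["condition"], f["replicate"])
        coverage.setdefault(key, []).extend(genome_io.read_coverage(
            root / f["path"], f["strand"], f["condition"], f["replicate"], lengths))
    return Dataset(
        sequences=sequences,
        genes=genes,
        tss=tss,
        tts=tts,
        reads=reads,
        coverage=coverage,
        conditions=conditions,
        reference_condition=conditions[0],
        depletion_condition=conditions[1] if len(conditions) > 1 else None,
    )


def _dataset_from_simulation(truth, evidence, config: SimulationConfig) -> Dataset:
    return Dataset(
        sequences=truth.sequences,
        genes=truth.genes,
        tss=evidence.tss,
        tts=evidence.tts,
        reads=evidence.reads,
        coverage=evidence.coverage,
        conditions=config.conditions,
        reference_condition=config.reference_condition,
        depletion_condition=config.depletion_condition,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    Any stage failure propagates with the stage name prefixed, so the
    offending input is always identifiable from the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: SimulationTruth | None = None

    stage = "input"
    try:
        if config.simulation is not None:
            truth, evidence = simulate_dataset(config.simulation)
            write_dataset(truth, evidence, out / "dataset")
            data = _dataset_from_simulation(truth, evidence, config.simulation)
        else:
            data = load_dataset(config.input_dir)

        stage = "call-operons"
        all_tss = [s for sites in data.tss.values() for s in sites]
        all_tts = [s for sites in data.tts.values() for s in sites]
        all_reads = [r for rs in data.reads.values() for r in rs]
        tus = build_transcription_units(
            data.genes, all_tss, all_tts, all_reads, config.caller)
        operons, singles = call_operons(tus, all_tss, all_tts, data.genes)
        summary_ops = summarize_operons(operons, singles)
        operons_to_frame(operons).to_csv(out / "operons.tsv", sep="\t", index=False)
        _write_internal_sites(operons, out / "internal_sites.bed")

        stage = "termination-stats"
        tracks = [t for ts in data.coverage.values() for t in ts]
        abundances = abundance_table(tracks, data.genes, config.pseudocount)
        records = analyze_all_iotts(
            operons, abundances, data.reference_condition, data.depletion_condition)
        tder_frame = records_to_frame(records)
        tder_frame.to_csv(out / "tder.tsv", sep="\t", index=False)

        stage = "motif"
        iotts_sites = _unique_internal_tts(operons)
        windows = extract_terminator_windows(
            data.sequences, iotts_sites, config.window_up, config.window_down)
        motif_summary = {}
        if windows:
            profile = build_motif_profile(windows)
            profile_to_frame(profile).to_csv(
                out / "motif_profile.tsv", sep="\t", index=False)
            scores = [u_tract_score(w) for w in windows]
            motif_summary = {
                "n_windows": len(windows),
                "info_content": [round(float(x), 6) for x in profile.info_content],
                "mean_u_tract_score": float(np.mean(scores)),
            }

        stage = "summary"
        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "outputs": {
                "operons": "operons.tsv",
                "internal_sites": "internal_sites.bed",
                "tder": "tder.tsv",
                "motif_profile": "motif_profile.tsv" if windows else None,
            },
            "operon_summary": summary_ops,
            "tder_tier_counts": _tier_counts(tder_frame),
            "tte_summary": _tte_summary(tder_frame),
            "motif": motif_summary,
            "warnings": {},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        if truth is not None:
            report = compare_to_truth(operons, tder_frame, truth)
            with open(out / "recovery.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            summary["recovery"] = report
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_internal_sites(operons, path: Path) -> None:
    with open(path, "w") as fh:
        for op in operons:
            for kind, sites in (("ioTSS", op.internal_tss), ("ioTTS", op.internal_tts)):
                for s in sites:
                    fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t"
                             f"{kind}|{op.operon_id}\t{s.count}\t{s.strand}\n")


def _unique_internal_tts(operons) -> list[SiteRecord]:
    seen = set()
    out = []
    for op in operons:
        for s in op.internal_tts:
            key = (s.contig, s.position, s.strand)
            if key not in seen:
                seen.add(key)
                out.append(s)
    return out


def _tier_counts(tder_frame: pd.DataFrame) -> dict:
    if tder_frame.empty:
        return {}
    return {
        cond: sub["tier"].value_counts().to_dict()
        for cond, sub in tder_frame.groupby("condition")
    }


def _tte_summary(tder_frame: pd.DataFrame) -> dict:
    if tder_frame.empty:
        return {}
    out = {}
    for cond, sub in tder_frame.groupby("condition"):
        tte = sub["TTE"].to_numpy(dtype=float)
        out[cond] = {
            "n": int(len(tte)),
            "mean": float(np.mean(tte)),
            "median": float(np.median(tte)),
            "min": float(np.min(tte)),
            "max": float(np.max(tte)),
        }
    return out


def compare_to_truth(
    operons, tder_frame: pd.DataFrame, truth: SimulationTruth
) -> dict:
    """Parameter-recovery report for a run on simulated data.

    Operons are matched to truth by their exact gene set (order-free);
    type accuracy is computed over matched pairs.  Each truth
    terminator is matched to a TDER record at the same position/strand
    in the reference condition, giving (eps, TTE) pairs and, when a
    depletion condition exists, per-terminator dependency errors
    against the closed form (1 - eps) / (1 - f*eps).
    """
    config = truth.config
    truth_by_genes = {
        frozenset(g.locus_tag for g in op.genes): op for op in truth.operons
    }
    called_sets = [frozenset(g.locus_tag for g in op.genes) for op in operons]
    matched = [(called, truth_by_genes[gs])
               for called, gs in zip(operons, called_sets) if gs in truth_by_genes]
    n_called, n_truth = len(operons), len(truth.operons)
    precision = len(matched) / n_called if n_called else None
    recall = len(matched) / n_truth if n_truth else None
    type_acc = (
        sum(1 for c, t in matched if c.type_label == t.type_label) / len(matched)
        if matched else None
    )

    ref = config.reference_condition
    rec_idx = {}
    if not tder_frame.empty:
        sub = tder_frame[tder_frame["condition"] == ref]
        rec_idx = {(r.iotts_position, r.strand): r for r in sub.itertuples(index=False)}
    eps_pairs = []
    dep_errors = []
    for term in truth.terminators:
        rec = rec_idx.get((term.position, term.strand))
        if rec is None:
            continue
        eps = term.eps_by_condition[ref]
        eps_pairs.append((eps, float(rec.TTE)))
        if config.depletion_condition and rec.dependency is not None \
                and not (isinstance(rec.dependency, float) and np.isnan(rec.dependency)):
            f = config.depletion_factor
            expected = (1.0 - eps) / (1.0 - f * eps)
            dep_errors.append(abs(float(rec.dependency) - expected))

    if eps_pairs:
        eps_arr = np.array([p[0] for p in eps_pairs])
        tte_arr = np.array([p[1] for p in eps_pairs])
        abs_err = np.abs(tte_arr - eps_arr)
        tte_metrics = {
            "n_matched_terminators": int(len(eps_pairs)),
            "mae": float(abs_err.mean()),
            "max_abs_error": float(abs_err.max()),
        }
        if len(eps_pairs) >= 2 and np.ptp(eps_arr) > 0:
            slope = float(np.polyfit(eps_arr, tte_arr, 1)[0])
            tte_metrics["slope_tte_on_eps"] = slope
    else:
        tte_metrics = {"n_matched_terminators": 0, "mae": None, "max_abs_error": None}

    return {
        "n_called_operons": n_called,
        "n_truth_operons": n_truth,
        "operon_precision": precision,
        "operon_recall": recall,
        "type_accuracy": type_acc,
        "tte_recovery": tte_metrics,
        "dependency_mae": float(np.mean(dep_errors)) if dep_errors else None,
        "dependency_max_abs_error": float(np.max(dep_errors)) if dep_errors else None,
    }
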