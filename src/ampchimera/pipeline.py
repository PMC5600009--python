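"""End-to-end pipeline: simulate (or load) reads, map them against the
panel, classify, confirm mixed-batch candidates in the raw signal, and
report.  The computational mirror of the wet-lab workflow that the barcode
design was built to interrogate."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import align, classify, report, signal, synth
from .config import PipelineConfig
from .panel import BarcodeMap, ReferencePanel

log = logging.getLogger("ampchimera")

# fixed per-stage seed offsets so a stage rerun alone reproduces its output
_STAGE_SEED_OFFSETS = {"simulate": 0, "map": 101, "classify": 202, "signal": 303}


@dataclasses.dataclass
class Manifest:
    out_dir: str
    artifacts: dict[str, str]
    hashes: dict[str, str]
    counts: dict[str, int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def annotate_reads(reads, panel: ReferencePanel, scheme, max_gap: int):
    """scan + merge for a list of reads -> (all matches, annotations)."""
    matches_all = []
    annotations = []
    for r in reads:
        ms = align.scan_read(r, panel, scheme)
        ms = align.merge_colinear(ms, max_gap=max_gap)
        ms = align.filter_matches(ms)
        matches_all.extend(ms)
        annotations.append(classify.ReadAnnotation(r.id, ms, len(r.sequence)))
    return matches_all, annotations


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Run every stage in order, writing all intermediates under
    ``config.out_dir``.  Deterministic under ``config.seed``."""
    out = Path(config.out_dir)
    for path_attr in ("reads", "panel", "barcode_map", "traces"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured {path_attr} path does not exist: {p}")
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    # --- inputs / simulate -------------------------------------------------
    if config.panel:
        panel = ReferencePanel.from_fasta(config.panel)
    else:
        panel = synth.make_default_panel(config.seed)
    if config.barcode_map:
        bcmap = BarcodeMap.from_csv(config.barcode_map)
    else:
        bcmap = synth.default_barcode_map()

    truth = None
    if config.reads:
        reads = synth.read_fastq(config.reads)
    else:
        params = dataclasses.replace(
            config.sim, seed=config.seed + _STAGE_SEED_OFFSETS["simulate"])
        reads, truth = synth.simulate_library(params, panel, bcmap)
        synth.write_fastq(reads, out / "reads.fastq")
        synth.write_truth(truth, out / "truth.csv")
        panel.to_fasta(out / "panel.fasta")
        bcmap.to_csv(out / "barcode_map.csv")
        artifacts.update(reads=str(out / "reads.fastq"), truth=str(out / "truth.csv"),
                         panel=str(out / "panel.fasta"),
                         barcode_map=str(out / "barcode_map.csv"))
    counts["called_reads"] = len(reads)
    log.info("stage simulate/load: %d reads", len(reads))

    # --- map ---------------------------------------------------------------
    matches, annotations = annotate_reads(reads, panel, config.scoring, config.max_gap)
    align.write_matches(matches, out / "matches.csv")
    artifacts["matches"] = str(out / "matches.csv")
    counts["matches"] = len(matches)
    log.info("stage map: %d merged matches", len(matches))

    # --- classify ----------------------------------------------------------
    calls = [classify.categorize(a, panel, bcmap) for a in annotations]
    classify.write_calls(calls, out / "calls.csv")
    artifacts["calls"] = str(out / "calls.csv")
    counts["mapped_reads"] = sum(1 for c in calls if c.nonchimeric_class != "unmapped"
                                 or c.definitive)
    counts["definitive_chimeric"] = sum(c.definitive for c in calls)
    for cls in classify.NONCHIMERIC_CLASSES:
        if cls != "none":
            counts[f"nonchimeric_{cls}"] = sum(
                c.nonchimeric_class == cls for c in calls)
    log.info("stage classify: %d definitive chimeric; non-chimeric classes: %s",
             counts["definitive_chimeric"],
             {k: v for k, v in counts.items() if k.startswith("nonchimeric_")})

    # --- signal ------------------------------------------------------------
    candidates = classify.mixed_batch_reads(calls)
    counts["mixed_batch_candidates"] = len(candidates)
    reload_rows = []
    if truth is not None and candidates:
        rng = np.random.default_rng(config.seed + _STAGE_SEED_OFFSETS["signal"])
        by_id = {t.read_id: t for t in truth}
        per_read_segments = {}
        for rid in candidates[: config.max_signal_traces]:
            trace, _ = signal.simulate_trace(by_id[rid], config.signal_model, panel, rng=rng)
            segs = signal.segment_trace(trace, config.signal_model)
            per_read_segments[rid] = segs
            flagged, junctions = signal.flag_reload(segs)
            reload_rows.append({"read_id": rid, "reload": flagged,
                                "junctions": ";".join(map(str, junctions))})
        signal.write_segments_csv(per_read_segments, out / "segments.csv")
        artifacts["segments"] = str(out / "segments.csv")
    elif config.traces:
        traces = signal.read_traces(config.traces)
        per_read_segments = {}
        for tr in traces[: config.max_signal_traces]:
            segs = signal.segment_trace(tr, config.signal_model)
            per_read_segments[tr.read_id] = segs
            flagged, junctions = signal.flag_reload(segs)
            reload_rows.append({"read_id": tr.read_id, "reload": flagged,
                                "junctions": ";".join(map(str, junctions))})
        signal.write_segments_csv(per_read_segments, out / "segments.csv")
        artifacts["segments"] = str(out / "segments.csv")
    if reload_rows:
        import pandas as pd

        pd.DataFrame(reload_rows).to_csv(out / "reloads.csv", index=False)
        artifacts["reloads"] = str(out / "reloads.csv")
    counts["reload_flagged"] = sum(r["reload"] for r in reload_rows)
    log.info("stage signal: %d candidates, %d reload-flagged",
             len(candidates), counts["reload_flagged"])

    # --- report ------------------------------------------------------------
    table = report.tabulate(calls, min_count=config.min_count)
    table.to_tsv(out / "summary_table.tsv")
    artifacts["summary_table"] = str(out / "summary_table.tsv")
    rate_report = report.headline_rates(calls, n_called=len(reads))
    rate_report.to_csv(out / "rates.csv")
    (out / "rates.txt").write_text(str(rate_report) + "\n")
    artifacts["rates"] = str(out / "rates.csv")
    report.length_plot([len(r.sequence) for r in reads], out / "lengths.png"
                       ).to_csv(out / "lengths.csv", index=False)
    artifacts["lengths"] = str(out / "lengths.csv")
    if truth is not None:
        ev = report.evaluate(calls, synth.read_truth(out / "truth.csv"))
        ev.to_csv(out / "evaluation.csv")
        artifacts["evaluation"] = str(out / "evaluation.csv")
        counts["truth_chimeric"] = int(round(ev.rate_truth * len(calls)))
    log.info("stage report: headline counts %s",
             {k: counts[k] for k in ("called_reads", "mapped_reads",
                                     "definitive_chimeric", "reload_flagged")})

    hashes = {name: _sha256(p) for name, p in artifacts.items()}
    manifest = Manifest(str(out), artifacts, hashes, counts)
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Input validation


def validate_inputs(paths: dict[str, str]) -> dict[str, dict]:
    """Per-file record counts and format diagnostics.

    ``paths`` maps a role ('reads', 'panel', 'traces') to a path.  Raises
    on unreadable files; format problems (truncated FASTQ records,
    duplicate read ids) are reported as diagnostics.
    """
    out: dict[str, dict] = {}
    for role, path in paths.items():
        if path is None:
            continue
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"cannot read {role} file: {path}")
        info: dict = {"path": str(path), "n_records": 0, "issues": []}
        if role == "reads":
            _validate_fastq(p, info)
        elif role == "panel":
            from Bio import SeqIO

            names = [rec.id for rec in SeqIO.parse(str(p), "fasta")]
            info["n_records"] = len(names)
            dups = sorted({n for n in names if names.count(n) > 1})
            if dups:
                info["issues"].append(f"duplicate panel names: {dups}")
        elif role == "traces":
            traces = signal.read_traces(p)
            info["n_records"] = len(traces)
        out[role] = info
    return out


def _validate_fastq(path, info: dict) -> None:
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    n_full, rem = divmod(len(lines), 4)
    for i in range(n_full):
        header = lines[4 * i]
        if not header.startswith("@"):
            info["issues"].append(f"line {4 * i + 1}: expected '@' header")
            continue
        rid = header[1:].split()[0]
        if rid in seen:
            info["issues"].append(f"duplicate read id: {rid}")
        seen.add(rid)
        if len(lines[4 * i + 1]) != len(lines[4 * i + 3]):
            info["issues"].append(f"line {4 * i + 2}: sequence/quality length mismatch")
    info["n_records"] = n_full
    if rem:
        info["issues"].append(
            f"line {4 * n_full + 1}: truncated FASTQ record ({rem} trailing line(s))")
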