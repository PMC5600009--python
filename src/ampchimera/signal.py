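"""Raw nanopore current trace simulation and segmentation.

A trace is modelled as a walk through four states: a high, uniform
*open-pore* current while the pore is empty; an intermediate, uniform
*stall* while the leader is held in the pore; the highly variable
*sequence* signal (one level per base, held for ``samples_per_base``
samples); and a distinctive three-level *hairpin* bridge a little over
halfway through a 2D trace.  An in-silico chimera shows a very short
return to the open-pore level (a "blip") followed by a fresh stall in the
middle of the trace — the signature of a pore that emptied and reloaded
fast enough for the base-caller to merge two molecules into one read.

Per-base levels are drawn from the sequence band by hashing the base's
3-mer context; the band deliberately excludes a guard zone around the
stall level so that states are level-identifiable (see docs/methods.md for
what this simplification does and does not let the tests show).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .panel import BarcodeMap, ReferencePanel
from .synth import GroundTruthRecord

SEGMENT_LABELS = ("open_pore", "stall", "sequence", "hairpin")

DEFAULT_MIN_DURATIONS = {"open_pore": 20, "stall": 100, "sequence": 200, "hairpin": 30}


@dataclass
class SignalModel:
    """Current levels (pA), noise, and timing of the trace generator.

    The published traces give durations but no current values; the defaults
    here are typical R9.4 magnitudes and are fully configurable.
    """

    open_pore_level: float = 220.0
    open_pore_sd: float = 5.0
    stall_level: float = 110.0
    stall_sd: float = 5.0
    sequence_min: float = 50.0
    sequence_max: float = 130.0
    sequence_sd: float = 5.0
    stall_guard: float = 14.0  # sequence levels keep this far from stall_level
    hairpin_levels: tuple[float, ...] = (160.0, 70.0, 160.0)
    hairpin_sd: float = 5.0
    hairpin_samples_per_level: int = 60
    samples_per_base: float = 14.0
    sample_rate: float = 4000.0
    open_pore_s: float = 2.0
    stall_s: float = 0.3
    reload_open_s: float = 0.08
    reload_stall_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.open_pore_level <= self.sequence_max:
            raise ValueError("open_pore_level must exceed the sequence band")
        if min(self.open_pore_level, self.stall_level, self.sequence_min) <= 0:
            raise ValueError("current levels must be positive")

    @property
    def open_threshold(self) -> float:
        return (self.open_pore_level + self.sequence_max) / 2.0

    @property
    def hairpin_threshold(self) -> float | None:
        top = max(self.hairpin_levels)
        if top > self.sequence_max:
            return (top + self.sequence_max) / 2.0
        return None


@dataclass
class SignalTrace:
    samples: np.ndarray
    sample_rate: float
    read_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment interval [{self.start},{self.end})")


# ---------------------------------------------------------------------------
# Per-base levels


def _base_levels(seq: str, model: SignalModel) -> np.ndarray:
    """One level per base from a hash of its 3-mer context, mapped into the
    sequence band minus the stall guard zone."""
    codes = encode(seq)
    padded = np.concatenate([[0], codes, [0]]).astype(np.int64)
    padded = np.where(padded >= 4, 0, padded)
    k3 = padded[:-2] * 16 + padded[1:-1] * 4 + padded[2:]
    u = ((k3 * np.int64(2654435761)) % np.int64(2**31)) / float(2**31)
    lo, hi = model.sequence_min, model.sequence_max
    g0 = max(lo, model.stall_level - model.stall_guard)
    g1 = min(hi, model.stall_level + model.stall_guard)
    below = max(0.0, g0 - lo)
    above = max(0.0, hi - g1)
    span = below + above
    x = u * span
    return np.where(x < below, lo + x, g1 + (x - below))


# ---------------------------------------------------------------------------
# Trace simulation


def simulate_trace(record: GroundTruthRecord, model: SignalModel,
                   panel: ReferencePanel, rng: np.random.Generator | None = None,
                   durations: tuple[float, float, float] | None = None
                   ) -> tuple[SignalTrace, list[Segment]]:
    """Emit the raw-current trace of one ground-truth construct.

    Returns the trace and its true segmentation.  ``durations`` optionally
    fixes (open_pore_s, stall_s, total_sequence_s); when the sequence
    duration is given, samples_per_base is rescaled to fit it.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    open_s, stall_s = model.open_pore_s, model.stall_s
    spb = model.samples_per_base
    n_bases = record.length
    if durations is not None:
        open_s, stall_s, seq_s = durations
        spb = seq_s * model.sample_rate / n_bases

    junction_set = set(record.junctions)
    pieces: list[np.ndarray] = []
    labels: list[tuple[int, str]] = []  # (n_samples, label) in order

    def emit_flat(level: float, sd: float, n: int, label: str) -> None:
        pieces.append(level + (rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)))
        labels.append((n, label))

    base_pos = 0  # global base index so per-segment sample counts telescope

    def emit_bases(seq: str) -> None:
        nonlocal base_pos
        levels = _base_levels(seq, model)
        counts = _sample_counts(len(seq), spb, offset=base_pos)
        base_pos += len(seq)
        per = np.repeat(levels, counts)
        noise = rng.normal(0.0, model.sequence_sd, per.size) if model.sequence_sd > 0 else 0.0
        pieces.append(per + noise)
        labels.append((per.size, "sequence"))

    def emit_hairpin() -> None:
        for lvl in model.hairpin_levels:
            emit_flat(lvl, model.hairpin_sd, model.hairpin_samples_per_level, "hairpin")

    emit_flat(model.open_pore_level, model.open_pore_sd,
              int(round(open_s * model.sample_rate)), "open_pore")
    emit_flat(model.stall_level, model.stall_sd,
              int(round(stall_s * model.sample_rate)), "stall")

    for seg in record.segments:
        if seg.start in junction_set and seg.start > 0:
            emit_flat(model.open_pore_level, model.open_pore_sd,
                      int(round(model.reload_open_s * model.sample_rate)), "open_pore")
            emit_flat(model.stall_level, model.stall_sd,
                      int(round(model.reload_stall_s * model.sample_rate)), "stall")
        entry = panel.get(seg.name) if seg.name in panel else None
        if entry is not None and entry.kind == "hairpin":
            emit_hairpin()
        else:
            seq = entry.sequence if entry is not None else "A" * (seg.end - seg.start)
            if seg.orientation == "rev":
                seq = revcomp(seq)
            emit_bases(seq)

    samples = np.concatenate(pieces)
    trace = SignalTrace(samples, model.sample_rate, record.read_id)
    segments = _labels_to_segments(labels)
    return trace, segments


def _sample_counts(n_bases: int, spb: float, offset: int = 0) -> np.ndarray:
    """Integer samples per base; totals over consecutive segments telescope
    to round(total_bases * spb) when ``offset`` carries the global index."""
    edges = np.round((offset + np.arange(n_bases + 1)) * spb).astype(np.int64)
    return np.diff(edges)


def _labels_to_segments(labels: list[tuple[int, str]]) -> list[Segment]:
    segments: list[Segment] = []
    pos = 0
    for n, label in labels:
        if n == 0:
            continue
        if segments and segments[-1].label == label:
            segments[-1] = Segment(segments[-1].start, pos + n, label)
        else:
            segments.append(Segment(pos, pos + n, label))
        pos += n
    return segments


# ---------------------------------------------------------------------------
# Segmentation


def segment_trace(trace: SignalTrace, model: SignalModel,
                  min_durations: dict[str, int] | None = None) -> list[Segment]:
    """Threshold-based state labelling of a raw trace.

    Samples above the open-pore threshold are open_pore; within the hairpin
    bridge band, hairpin; within the stall band, stall; everything else,
    sequence.  Runs shorter than their label's minimum duration are absorbed
    into the surrounding label, so isolated noise excursions never split a
    state.  The output always tiles [0, n) with no two adjacent segments
    sharing a label.
    """
    mins = dict(DEFAULT_MIN_DURATIONS)
    if min_durations:
        mins.update(min_durations)
    x = trace.samples
    lab = np.full(x.size, 2, dtype=np.int8)  # 2 = sequence
    lab[np.abs(x - model.stall_level) <= model.stall_guard - 2.0] = 1  # stall
    hp_thr = model.hairpin_threshold
    if hp_thr is not None:
        lab[x > hp_thr] = 3  # hairpin
    lab[x > model.open_threshold] = 0  # open_pore

    names = {0: "open_pore", 1: "stall", 2: "sequence", 3: "hairpin"}
    runs = _runs(lab)
    runs = _absorb_short(runs, {k: mins[v] for k, v in names.items()})
    return [Segment(s, e, names[l]) for s, e, l in runs]


def _runs(lab: np.ndarray) -> list[list[int]]:
    change = np.flatnonzero(np.diff(lab)) + 1
    bounds = np.concatenate([[0], change, [lab.size]])
    return [[int(bounds[i]), int(bounds[i + 1]), int(lab[bounds[i]])]
            for i in range(len(bounds) - 1)]


def _absorb_short(runs: list[list[int]], min_len: dict[int, int]) -> list[list[int]]:
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        # shortest run below its minimum duration, leftmost on ties
        idx = -1
        shortest = None
        for i, (s, e, l) in enumerate(runs):
            n = e - s
            if n < min_len[l] and (shortest is None or n < shortest):
                shortest = n
                idx = i
        if idx < 0:
            break
        s, e, l = runs[idx]
        left = runs[idx - 1] if idx > 0 else None
        right = runs[idx + 1] if idx < len(runs) - 1 else None
        if left is not None and right is not None and left[2] == right[2]:
            left[1] = right[1]
            del runs[idx:idx + 2]
        elif left is None:
            right[0] = s
            del runs[idx]
        elif right is None:
            left[1] = e
            del runs[idx]
        else:
            # absorb into the longer neighbour (left on ties)
            if (left[1] - left[0]) >= (right[1] - right[0]):
                left[1] = e
            else:
                right[0] = s
            del runs[idx]
    return runs


def flag_reload(segments: list[Segment]) -> tuple[bool, list[int]]:
    """True iff an open-pore segment occurs after sequencing has begun.

    Leading open-pore/stall segments (the pore waiting for, then holding, a
    molecule) are normal; an open-pore return anywhere after the first
    sequence or hairpin segment marks a pore reload — the raw-signal
    signature of an in-silico chimera.  Returns the flag and the start
    positions of all such segments.
    """
    started = False
    junctions: list[int] = []
    for seg in segments:
        if seg.label in ("sequence", "hairpin"):
            started = True
        elif seg.label == "open_pore" and started:
            junctions.append(seg.start)
    return bool(junctions), junctions


# ---------------------------------------------------------------------------
# Trace container (HDF5): one dataset per read under /reads, with
# sample_rate and read_id attributes.  ``read_fast5_raw`` additionally
# accepts the dataset layout used by nanopore FAST5 files.


def write_traces(traces: list[SignalTrace], path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group("reads")
        for tr in traces:
            ds = grp.create_dataset(tr.read_id, data=tr.samples)
            ds.attrs["sample_rate"] = tr.sample_rate
            ds.attrs["read_id"] = tr.read_id


def read_traces(path) -> list[SignalTrace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as fh:
        if "reads" not in fh:
            raise ValueError(f"{path}: no /reads group — not a trace container")
        for name, ds in fh["reads"].items():
            traces.append(SignalTrace(ds[()], float(ds.attrs.get("sample_rate", 4000.0)),
                                      str(ds.attrs.get("read_id", name))))
    return traces


def read_fast5_raw(path, default_sample_rate: float = 4000.0) -> list[SignalTrace]:
    """Extract raw signal datasets from a FAST5-layout HDF5 file
    (``.../Raw/Reads/Read_*/Signal`` or multi-read ``read_*/Raw/Signal``)."""
    import h5py

    traces: list[SignalTrace] = []

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset) and name.split("/")[-1] == "Signal" and "Raw" in name:
            parent = obj.parent
            read_id = str(parent.attrs.get("read_id", name.split("/")[-2]))
            rate = default_sample_rate
            for anc in (parent, parent.parent):
                if "sampling_rate" in getattr(anc, "attrs", {}):
                    rate = float(anc.attrs["sampling_rate"])
            traces.append(SignalTrace(obj[()].astype(np.float64), rate, read_id))

    with h5py.File(path, "r") as fh:
        fh.visititems(visit)
    return traces


def write_segments_csv(per_read: dict[str, list[Segment]], path) -> None:
    import pandas as pd

    rows = [{"read_id": rid, "start": s.start, "end": s.end, "label": s.label}
            for rid, segs in per_read.items() for s in segs]
    pd.DataFrame(rows, columns=["read_id", "start", "end", "label"]).to_csv(path, index=False)
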