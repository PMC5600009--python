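"""Synthetic barcoded-amplicon library generator.

Emulates the construct grammar of a native-barcoded 2D-ligation MinION run of
three murine amplicons (an Ifna-family consensus, Ifnb1 and Actb): each
amplicon is blunt-end ligated to a batch-specific barcode on both sides,
pooled, and adapter/hairpin ligated in one of two batches (overnight at 4 C,
or quick 10-minute).  Chimeras form *after* barcoding, so chimeric reads are
concatenations of whole barcode-flanked constructs; a separate mechanism
joins two complete molecules in software when the pore reloads too fast
(an "in-silico" chimera, marked in ground truth by its junction position).

Every read comes with a :class:`GroundTruthRecord` giving the construct
grammar and the exact interval of each segment on the pre-corruption read,
so alignment, classification and signal segmentation can all be scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import random_dna, revcomp
from .panel import BATCHES, BarcodeMap, PanelEntry, ReferencePanel

# Published primer sequences; degenerate bases are resolved deterministically
# (R -> A, Y -> C) so fixture panels are reproducible.
PRIMERS = {
    "IfnaF": "ATGGCTAGRCTCTGTGCTTTCCT",
    "IfnaR": "AGGGCTCTCCAGAYTTCTGCTCTG",
    "IfnbF": "CTGGCTTCCATCATGAACAA",
    "IfnbR": "GCAACCACCACTCATTCTGA",
    "ActbF": "AGGGAAATCGTGCGTGACAT",
    "ActbR": "ACGCAGCTCAGTAACAGTCC",
}

AMPLICON_LENGTHS = {"Ifna": 535, "Ifnb1": 600, "Actb": 524}

_DEGENERATE = str.maketrans({"R": "A", "Y": "C"})

CHIMERA_CLASSES = (
    "chimera_repeat",
    "chimera_multi_amplicon",
    "chimera_multi_barcode",
    "chimera_disagreement",
)
TRUTH_CLASSES = ("clean",) + CHIMERA_CLASSES + ("insilico_join",)

BARCODE_LENGTH = 24
MIN_BARCODE_EDIT_DISTANCE = 8

# Default barcode design: one barcode per (gene, batch).  The kit's actual
# barcode-to-sample layout is a user decision; this default is arbitrary but
# fixed, and consistent with NB04/NB05 marking overnight products and
# NB11/NB06 marking the two batches of Actb.
DEFAULT_BARCODE_DESIGN = {
    ("Ifna", "overnight"): "NB04",
    ("Ifnb1", "overnight"): "NB05",
    ("Actb", "overnight"): "NB11",
    ("Ifna", "quick"): "NB01",
    ("Ifnb1", "quick"): "NB03",
    ("Actb", "quick"): "NB06",
}


def _resolve(primer: str) -> str:
    return primer.translate(_DEGENERATE)


def _make_amplicon(name: str, length: int, fwd_primer: str, rev_primer: str,
                   rng: np.random.Generator) -> str:
    """Amplicon = forward primer + random interior + revcomp(reverse primer)."""
    left = _resolve(fwd_primer)
    right = revcomp(_resolve(rev_primer))
    interior = random_dna(rng, length - len(left) - len(right))
    return left + interior + right


def _make_barcodes(names: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Seeded-random 24-mers with pairwise edit distance >= 8."""
    import edlib

    chosen: dict[str, str] = {}
    for name in names:
        while True:
            cand = random_dna(rng, BARCODE_LENGTH)
            if all(
                edlib.align(cand, other)["editDistance"] >= MIN_BARCODE_EDIT_DISTANCE
                for other in chosen.values()
            ):
                chosen[name] = cand
                break
    return chosen


def make_default_panel(seed: int) -> ReferencePanel:
    """Build the default reference panel: three amplicons with the published
    primer termini and lengths (Ifna 535, Ifnb1 600, Actb 524), six 24-nt
    barcodes, one hairpin adapter, one leader adapter and a control strand.

    Interior amplicon bases are seeded-random; two panels built with the same
    seed are identical, and panels from different seeds differ only in those
    random interiors.
    """
    rng = np.random.default_rng(seed)
    entries = [
        PanelEntry("Ifna", "amplicon", "Ifna",
                   _make_amplicon("Ifna", AMPLICON_LENGTHS["Ifna"],
                                  PRIMERS["IfnaF"], PRIMERS["IfnaR"], rng)),
        PanelEntry("Ifnb1", "amplicon", "Ifnb1",
                   _make_amplicon("Ifnb1", AMPLICON_LENGTHS["Ifnb1"],
                                  PRIMERS["IfnbF"], PRIMERS["IfnbR"], rng)),
        PanelEntry("Actb", "amplicon", "Actb",
                   _make_amplicon("Actb", AMPLICON_LENGTHS["Actb"],
                                  PRIMERS["ActbF"], PRIMERS["ActbR"], rng)),
    ]
    barcode_names = [DEFAULT_BARCODE_DESIGN[(g, b)]
                     for b in BATCHES for g in ("Ifna", "Ifnb1", "Actb")]
    for name, seq in _make_barcodes(barcode_names, rng).items():
        entries.append(PanelEntry(name, "barcode", "", seq))
    entries.append(PanelEntry("HP", "hairpin", "", random_dna(rng, 60)))
    entries.append(PanelEntry("LEADER", "leader", "", random_dna(rng, 40)))
    entries.append(PanelEntry("CS", "control", "", random_dna(rng, 300)))
    return ReferencePanel(entries)


def default_barcode_map() -> BarcodeMap:
    return BarcodeMap(dict(DEFAULT_BARCODE_DESIGN))


# ---------------------------------------------------------------------------
# Construct grammar


@dataclass(frozen=True)
class ConstructSpec:
    """The grammar of one molecule handed to the sequencer.

    ``segments`` lists (panel entry name, orientation) in read order for the
    1D block; if ``is_2d`` the built sequence is that block, then the hairpin,
    then the block's reverse complement.  ``join_after`` holds indices into
    ``segments`` after which the pore reloaded (in-silico junctions).
    """

    segments: tuple[tuple[str, str], ...]
    batch: str  # overnight | quick | mixed
    is_2d: bool = False
    truth_class: str = "clean"
    join_after: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth_class {self.truth_class!r}")
        if self.batch not in BATCHES + ("mixed",):
            raise ValueError(f"unknown batch {self.batch!r}")
        for _, orient in self.segments:
            if orient not in ("fwd", "rev"):
                raise ValueError(f"orientation must be fwd/rev, got {orient!r}")
        if self.truth_class == "insilico_join" and not self.join_after:
            raise ValueError("insilico_join constructs must mark their junction(s)")


@dataclass(frozen=True)
class SegmentInterval:
    """One laid-out construct segment on the (pre-corruption) read."""

    name: str
    orientation: str
    start: int
    end: int


@dataclass
class GroundTruthRecord:
    """Per-read ground truth: construct spec, laid-out segment intervals
    (0-based half-open, pre-corruption coordinates) and in-silico junction
    base positions."""

    read_id: str
    spec: ConstructSpec
    segments: list[SegmentInterval]
    junctions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end <= seg.start:
                raise ValueError(
                    f"{self.read_id}: truth intervals must tile the read "
                    f"(segment {seg.name} at [{seg.start},{seg.end}) after {pos})"
                )
            pos = seg.end

    @property
    def length(self) -> int:
        return self.segments[-1].end if self.segments else 0


def _segment_sequence(name: str, orientation: str, panel: ReferencePanel) -> str:
    try:
        seq = panel.get(name).sequence
    except KeyError:
        raise KeyError(f"construct segment {name!r} is not in the panel") from None
    return seq if orientation == "fwd" else revcomp(seq)


def expand_construct(spec: ConstructSpec, panel: ReferencePanel) -> tuple[str, list[SegmentInterval], tuple[int, ...]]:
    """Build the full base sequence and its segment layout.

    Returns (sequence, segment intervals, junction base positions).  For 2D
    constructs the layout includes the hairpin entry and the mirrored,
    orientation-flipped copy of the 1D block.
    """
    parts: list[tuple[str, str]] = list(spec.segments)
    junction_idx = set(spec.join_after)
    if spec.is_2d:
        hairpins = [e for e in panel if e.kind == "hairpin"]
        if not hairpins:
            raise ValueError("2D construct requested but panel has no hairpin entry")
        flipped = [(name, "rev" if o == "fwd" else "fwd") for name, o in reversed(parts)]
        parts = parts + [(hairpins[0].name, "fwd")] + flipped

    seq_parts: list[str] = []
    layout: list[SegmentInterval] = []
    junctions: list[int] = []
    pos = 0
    for i, (name, orient) in enumerate(parts):
        s = _segment_sequence(name, orient, panel)
        layout.append(SegmentInterval(name, orient, pos, pos + len(s)))
        pos += len(s)
        seq_parts.append(s)
        if i in junction_idx:
            junctions.append(pos)
    return "".join(seq_parts), layout, tuple(junctions)


def build_construct(spec: ConstructSpec, panel: ReferencePanel,
                    barcode_map: BarcodeMap | None = None) -> str:
    """Concatenate the named panel sequences of ``spec`` in order (reverse
    complemented where orientation is ``rev``); 2D constructs append the
    hairpin and the reverse complement of the preceding block."""
    seq, _, _ = expand_construct(spec, panel)
    return seq


def clean_spec(gene: str, batch: str, barcode_map: BarcodeMap, is_2d: bool = False) -> ConstructSpec:
    """Barcode-amplicon-barcode with a consistent (gene, batch) assignment."""
    bc = barcode_map.barcode_for(gene, batch)
    return ConstructSpec(((bc, "fwd"), (gene, "fwd"), (bc, "fwd")),
                         batch=batch, is_2d=is_2d, truth_class="clean")


# ---------------------------------------------------------------------------
# Error model


def corrupt(bases: str, rates: tuple[float, float, float], rng: np.random.Generator) -> str:
    """Apply an iid substitution/insertion/deletion error model.

    Each position is deleted with probability ``del_rate``, otherwise emitted
    (substituted to a different base with probability ``sub_rate``); after
    each original position one random base is inserted with probability
    ``ins_rate``.  Expected output length is ``n * (1 + ins - del)``.
    """
    sub, ins, dele = rates
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError("error rates must be in [0, 1]")
    n = len(bases)
    if n == 0:
        return bases
    codes = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    enc = lut[codes]

    keep = rng.random(n) >= dele
    do_sub = rng.random(n) < sub
    # substitution: shift by 1..3 so the base always changes
    shifted = (enc + rng.integers(1, 4, size=n)) % 4
    out_enc = np.where(do_sub, shifted, enc)
    do_ins = rng.random(n) < ins
    ins_bases = rng.integers(0, 4, size=n)

    alpha = np.frombuffer(b"ACGT", dtype=np.uint8)
    pieces = []
    emit = alpha[out_enc]
    for i in range(n):
        if keep[i]:
            pieces.append(emit[i])
        if do_ins[i]:
            pieces.append(alpha[ins_bases[i]])
    return np.array(pieces, dtype=np.uint8).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Library simulation


@dataclass
class SimParams:
    """Simulation conditions.

    Defaults mirror the study's observed library composition: 77.8% overnight
    ligation, amplicon mix Ifna/Ifnb1/Actb = 42.7/23.7/33.6%, 40.8% 2D
    molecules, ~2% chimeric constructs dominated by same-amplicon repeats,
    and a small in-silico join rate.  Error rates are representative of R9.4
    1D base-calls.
    """

    n_reads: int = 1000
    chimera_rate: float = 0.02
    insilico_rate: float = 0.001
    batch_mix: float = 0.778  # P(overnight)
    amplicon_mix: dict[str, float] = field(
        default_factory=lambda: {"Ifna": 0.427, "Ifnb1": 0.237, "Actb": 0.336}
    )
    twod_fraction: float = 0.408
    chimera_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "chimera_repeat": 0.55,
            "chimera_multi_amplicon": 0.20,
            "chimera_multi_barcode": 0.15,
            "chimera_disagreement": 0.10,
        }
    )
    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chimera_rate", "insilico_rate", "batch_mix", "twod_fraction",
                     "sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.amplicon_mix.values()) - 1.0) > 1e-9:
            raise ValueError("amplicon_mix must sum to 1")
        if abs(sum(self.chimera_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("chimera_class_mix must sum to 1")

    @property
    def error_rates(self) -> tuple[float, float, float]:
        return (self.sub_rate, self.ins_rate, self.del_rate)


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = "I" * len(self.sequence)


def _draw(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    p = np.array([weights[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]


def _chimera_spec(mechanism: str, rng: np.random.Generator, params: SimParams,
                  barcode_map: BarcodeMap) -> ConstructSpec:
    genes = list(params.amplicon_mix)
    g1 = _draw(rng, params.amplicon_mix)
    batch = "overnight" if rng.random() < params.batch_mix else "quick"
    if mechanism == "chimera_repeat":
        bc = barcode_map.barcode_for(g1, batch)
        block = ((bc, "fwd"), (g1, "fwd"), (bc, "fwd"))
        return ConstructSpec(block * 2, batch=batch, truth_class=mechanism)
    if mechanism == "chimera_multi_amplicon":
        g2 = rng.choice([g for g in genes if g != g1])
        b1 = barcode_map.barcode_for(g1, batch)
        b2 = barcode_map.barcode_for(g2, batch)
        segs = ((b1, "fwd"), (g1, "fwd"), (b1, "fwd"),
                (b2, "fwd"), (g2, "fwd"), (b2, "fwd"))
        return ConstructSpec(segs, batch=batch, truth_class=mechanism)
    if mechanism == "chimera_multi_barcode":
        # one amplicon flanked by its two batch barcodes (barcode swap during
        # barcoding clean-up): distinct barcodes, single amplicon, no
        # barcode/amplicon gene conflict
        b_on = barcode_map.barcode_for(g1, "overnight")
        b_q = barcode_map.barcode_for(g1, "quick")
        segs = ((b_on, "fwd"), (g1, "fwd"), (b_q, "fwd"))
        return ConstructSpec(segs, batch="mixed", truth_class=mechanism)
    if mechanism == "chimera_disagreement":
        g_bc = rng.choice([g for g in genes if g != g1])
        bc = barcode_map.barcode_for(g_bc, batch)
        segs = ((bc, "fwd"), (g1, "fwd"), (bc, "fwd"))
        return ConstructSpec(segs, batch=batch, truth_class=mechanism)
    raise ValueError(f"unknown chimera mechanism {mechanism!r}")


def _insilico_spec(rng: np.random.Generator, params: SimParams,
                   barcode_map: BarcodeMap) -> ConstructSpec:
    segs: list[tuple[str, str]] = []
    batches = []
    for _ in range(2):
        g = _draw(rng, params.amplicon_mix)
        batch = "overnight" if rng.random() < params.batch_mix else "quick"
        bc = barcode_map.barcode_for(g, batch)
        segs.extend([(bc, "fwd"), (g, "fwd"), (bc, "fwd")])
        batches.append(batch)
    batch = batches[0] if batches[0] == batches[1] else "mixed"
    return ConstructSpec(tuple(segs), batch=batch, truth_class="insilico_join",
                         join_after=(2,))


def _flip_truth(layout: list[SegmentInterval], junctions: tuple[int, ...],
                length: int) -> tuple[list[SegmentInterval], tuple[int, ...]]:
    flipped = [
        SegmentInterval(s.name, "rev" if s.orientation == "fwd" else "fwd",
                        length - s.end, length - s.start)
        for s in reversed(layout)
    ]
    return flipped, tuple(sorted(length - j for j in junctions))


def simulate_library(params: SimParams, panel: ReferencePanel,
                     barcode_map: BarcodeMap) -> tuple[list[FastqRead], list[GroundTruthRecord]]:
    """Simulate ``params.n_reads`` reads with per-read ground truth.

    Deterministic for a fixed seed: identical params produce byte-identical
    FASTQ records and truth tables.
    """
    barcode_map.validate_against(panel)
    rng = np.random.default_rng(params.seed)
    reads: list[FastqRead] = []
    truth: list[GroundTruthRecord] = []
    for i in range(params.n_reads):
        r = rng.random()
        if r < params.insilico_rate:
            spec = _insilico_spec(rng, params, barcode_map)
        elif r < params.insilico_rate + params.chimera_rate:
            mech = _draw(rng, params.chimera_class_mix)
            spec = _chimera_spec(mech, rng, params, barcode_map)
        else:
            gene = _draw(rng, params.amplicon_mix)
            batch = "overnight" if rng.random() < params.batch_mix else "quick"
            spec = clean_spec(gene, batch, barcode_map,
                              is_2d=bool(rng.random() < params.twod_fraction))
        seq, layout, junctions = expand_construct(spec, panel)
        if rng.random() < 0.5:  # sequencing strand
            seq = revcomp(seq)
            layout, junctions = _flip_truth(layout, junctions, len(seq))
        read_id = f"simread-{i:06d}"
        corrupted = corrupt(seq, params.error_rates, rng)
        reads.append(FastqRead(read_id, corrupted))
        truth.append(GroundTruthRecord(read_id, spec, layout, junctions))
    return reads, truth


# ---------------------------------------------------------------------------
# File formats


def write_fastq(reads: list[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[FastqRead]:
    from Bio import SeqIO

    return [FastqRead(rec.id, str(rec.seq),
                      "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(str(path), "fastq")]


def _truth_segments_str(rec: GroundTruthRecord) -> str:
    parts = [f"{s.name}:{s.orientation}:{s.start}-{s.end}" for s in rec.segments]
    for j in rec.junctions:
        parts.append(f"reload::{j}-{j}")
    return ";".join(parts)


def write_truth(truth: list[GroundTruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id,truth_class,batch,segments\n")
        for rec in truth:
            fh.write(f"{rec.read_id},{rec.spec.truth_class},{rec.spec.batch},"
                     f"{_truth_segments_str(rec)}\n")


def read_truth(path):
    """Truth table as a pandas DataFrame (segments kept as encoded strings)."""
    import pandas as pd

    return pd.read_csv(path)
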