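"""Chimera classification of annotated reads.

A read's merged match list is turned into a verdict over four (possibly
co-occurring) chimera categories:

1. repeated identical amplicons aligned in the same direction,
2. at least two distinct amplicons,
3. at least two distinct barcodes,
4. disagreement between barcode and amplicon (or between two barcodes).

One pattern is deliberately excluded: exactly two matches to the same gene
in *opposite* orientations (with or without an intervening hairpin match) is
indistinguishable at the base level from a 2D read (template, hairpin,
complement) and sets no flag.  A read with any flag is definitively
chimeric; every other read receives exactly one non-chimeric class.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import Match
from .panel import BarcodeMap, ReferencePanel

NONCHIMERIC_CLASSES = ("amplicon_and_barcode", "barcode_only", "sequence_only",
                       "unmapped", "none")


@dataclass
class ReadAnnotation:
    """A read's ordered, merged match list — the unit of classification."""

    read_id: str
    matches: list[Match]
    read_length: int = 0

    def __post_init__(self) -> None:
        for m in self.matches:
            if m.read_id != self.read_id:
                raise ValueError(
                    f"annotation {self.read_id}: match belongs to {m.read_id}"
                )
        starts = [m.read_start for m in self.matches]
        if starts != sorted(starts):
            raise ValueError(f"annotation {self.read_id}: matches must be sorted by read_start")


@dataclass(frozen=True)
class Signature:
    """Per-gene amplicon counts x barcode batches seen, plus the disagreement
    marker — the grouping key of the summary table."""

    amplicon_counts: tuple[tuple[str, int], ...]
    batches: frozenset
    disagreement: bool

    def counts_dict(self) -> dict[str, int]:
        return dict(self.amplicon_counts)


@dataclass
class ChimeraCall:
    read_id: str
    repeated_amplicon: bool
    multi_amplicon: bool
    multi_barcode: bool
    disagreement: bool
    definitive: bool
    signature: Signature
    nonchimeric_class: str

    def __post_init__(self) -> None:
        flags = any([self.repeated_amplicon, self.multi_amplicon,
                     self.multi_barcode, self.disagreement])
        if self.definitive != flags:
            raise ValueError("definitive must equal 'any flag set'")
        if self.definitive != (self.nonchimeric_class == "none"):
            raise ValueError("definitive reads must have nonchimeric_class 'none'")
        if self.nonchimeric_class not in NONCHIMERIC_CLASSES:
            raise ValueError(f"unknown nonchimeric_class {self.nonchimeric_class!r}")

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "repeated_amplicon": self.repeated_amplicon,
            "multi_amplicon": self.multi_amplicon,
            "multi_barcode": self.multi_barcode,
            "disagreement": self.disagreement,
        }


def gene_identity(match: Match, panel: ReferencePanel) -> str:
    """The gene a matched amplicon counts as (family members collapse to
    their shared gene_id, e.g. Ifna2 -> Ifna)."""
    if match.kind != "amplicon":
        raise ValueError(f"gene_identity needs an amplicon match, got kind {match.kind!r}")
    return panel.gene_of(match.target)


def batch_of(barcode_name: str, barcode_map: BarcodeMap) -> str:
    """Ligation batch (overnight or quick) a barcode marks."""
    return barcode_map.batch_of(barcode_name)


def categorize(annotation: ReadAnnotation, panel: ReferencePanel,
               barcode_map: BarcodeMap) -> ChimeraCall:
    """Apply the four chimera rules (and the 2D-ambiguity exclusion) to a
    merged annotation.

    The exclusion needs no special case here: the repeated-amplicon rule
    demands two same-gene matches in the *same* orientation, so the
    two-opposite-orientation pattern never fires it, while three or more
    same-gene matches flag whenever any two share a direction.
    """
    starts = [m.read_start for m in annotation.matches]
    if starts != sorted(starts):
        raise ValueError(f"{annotation.read_id}: matches must be merged and sorted")

    amp = [m for m in annotation.matches if m.kind == "amplicon"]
    bcs = [m for m in annotation.matches if m.kind == "barcode"]
    genes = [gene_identity(m, panel) for m in amp]
    gene_orient = Counter((g, m.orientation) for g, m in zip(genes, amp))

    repeated = any(c >= 2 for c in gene_orient.values())
    multi_amplicon = len(set(genes)) >= 2
    bc_targets = {m.target for m in bcs}
    multi_barcode = len(bc_targets) >= 2
    bc_genes = {barcode_map.gene_of(t) for t in bc_targets}
    disagreement = any(gb != ga for gb in bc_genes for ga in set(genes)) or len(bc_genes) >= 2

    definitive = repeated or multi_amplicon or multi_barcode or disagreement

    counts = Counter(genes)
    signature = Signature(
        amplicon_counts=tuple((g, counts.get(g, 0)) for g in panel.gene_ids),
        batches=frozenset(barcode_map.batch_of(t) for t in bc_targets),
        disagreement=disagreement,
    )

    if definitive:
        nonchimeric = "none"
    elif amp and bcs:
        nonchimeric = "amplicon_and_barcode"
    elif bcs:
        nonchimeric = "barcode_only"
    elif amp:
        nonchimeric = "sequence_only"
    else:
        nonchimeric = "unmapped"

    return ChimeraCall(annotation.read_id, repeated, multi_amplicon,
                       multi_barcode, disagreement, definitive, signature,
                       nonchimeric)


def mixed_batch_reads(calls: list[ChimeraCall]) -> list[str]:
    """Reads whose base-called barcodes span both ligation batches — the
    candidates for in-silico chimerism, to be confirmed in the raw signal."""
    both = frozenset(("overnight", "quick"))
    return [c.read_id for c in calls if c.signature.batches == both]


# ---------------------------------------------------------------------------
# CSV round trip

CALL_COLUMNS = ["read_id", "repeated_amplicon", "multi_amplicon", "multi_barcode",
                "disagreement", "definitive", "amplicon_counts", "batches",
                "nonchimeric_class"]


def _counts_str(sig: Signature) -> str:
    return ";".join(f"{g}:{c}" for g, c in sig.amplicon_counts)


def _batches_str(sig: Signature) -> str:
    return "|".join(sorted(sig.batches))


def write_calls(calls: list[ChimeraCall], path) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "read_id": c.read_id,
            "repeated_amplicon": c.repeated_amplicon,
            "multi_amplicon": c.multi_amplicon,
            "multi_barcode": c.multi_barcode,
            "disagreement": c.disagreement,
            "definitive": c.definitive,
            "amplicon_counts": _counts_str(c.signature),
            "batches": _batches_str(c.signature),
            "nonchimeric_class": c.nonchimeric_class,
        })
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, index=False)


def read_calls(path) -> list[ChimeraCall]:
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False)
    calls = []
    for r in df.itertuples(index=False):
        counts = tuple(
            (part.split(":")[0], int(part.split(":")[1]))
            for part in str(r.amplicon_counts).split(";") if part
        )
        batches = frozenset(b for b in str(r.batches).split("|") if b)
        sig = Signature(counts, batches, bool(r.disagreement))
        calls.append(ChimeraCall(
            r.read_id, bool(r.repeated_amplicon), bool(r.multi_amplicon),
            bool(r.multi_barcode), bool(r.disagreement), bool(r.definitive),
            sig, r.nonchimeric_class,
        ))
    return calls
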