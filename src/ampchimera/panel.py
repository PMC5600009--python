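"""Reference panels: the named amplicon, barcode and adapter sequences that
reads are scanned against, plus the barcode-to-(gene, ligation batch) design.

A panel entry has a *kind* (amplicon, barcode, hairpin, leader, control) and,
for amplicons, a *gene_id* grouping highly similar family members (all Ifna
family entries collapse to gene_id ``"Ifna"``) so that classification counts
genes, not individual consensus variants.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

PANEL_KINDS = ("amplicon", "barcode", "hairpin", "leader", "control")
BATCHES = ("overnight", "quick")

_DNA_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class PanelEntry:
    name: str
    kind: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in PANEL_KINDS:
            raise ValueError(f"unknown panel kind {self.kind!r} for entry {self.name!r}")
        if not self.sequence or not _DNA_RE.match(self.sequence):
            raise ValueError(f"entry {self.name!r}: sequence must be non-empty over A,C,G,T")
        if self.kind == "amplicon" and not self.gene_id:
            raise ValueError(f"amplicon {self.name!r} must carry a gene_id")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferencePanel:
    """An ordered collection of uniquely named :class:`PanelEntry`."""

    def __init__(self, entries: list[PanelEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate panel entry names: {dup}")
        self.entries: list[PanelEntry] = list(entries)
        self._by_name = {e.name: e for e in entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> PanelEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no panel entry named {name!r}") from None

    def of_kind(self, kind: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.kind == kind]

    @property
    def amplicons(self) -> list[PanelEntry]:
        return self.of_kind("amplicon")

    @property
    def barcodes(self) -> list[PanelEntry]:
        return self.of_kind("barcode")

    @property
    def gene_ids(self) -> list[str]:
        """Unique amplicon gene ids in panel order."""
        seen: list[str] = []
        for e in self.amplicons:
            if e.gene_id not in seen:
                seen.append(e.gene_id)
        return seen

    def gene_of(self, target: str) -> str:
        entry = self.get(target)
        if entry.kind != "amplicon":
            raise ValueError(f"panel entry {target!r} has kind {entry.kind!r}, not amplicon")
        return entry.gene_id

    # -- FASTA round trip -------------------------------------------------
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name} kind={e.kind} gene_id={e.gene_id}\n{e.sequence}\n")

    @classmethod
    def from_fasta(cls, path) -> "ReferencePanel":
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(
                part.split("=", 1) for part in rec.description.split()[1:] if "=" in part
            )
            entries.append(
                PanelEntry(
                    name=rec.id,
                    kind=fields.get("kind", "amplicon"),
                    gene_id=fields.get("gene_id", ""),
                    sequence=str(rec.seq).upper(),
                )
            )
        return cls(entries)


@dataclass
class BarcodeMap:
    """Which barcode flanks which amplicon in which ligation batch.

    ``assignments`` maps ``(gene_id, batch)`` to a barcode name; the map must
    be injective and use exactly the two batches (overnight, quick).
    """

    assignments: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.assignments.values())
        if len(set(names)) != len(names):
            raise ValueError("barcode map is not injective: a barcode is assigned twice")
        batches = {b for (_, b) in self.assignments}
        if batches - set(BATCHES):
            raise ValueError(f"unknown batches in barcode map: {sorted(batches - set(BATCHES))}")
        if self.assignments and batches != set(BATCHES):
            raise ValueError("barcode map must cover exactly the overnight and quick batches")
        self._reverse = {name: key for key, name in self.assignments.items()}

    def barcode_for(self, gene_id: str, batch: str) -> str:
        try:
            return self.assignments[(gene_id, batch)]
        except KeyError:
            raise KeyError(f"no barcode assigned to gene {gene_id!r}, batch {batch!r}") from None

    def gene_of(self, barcode: str) -> str:
        try:
            return self._reverse[barcode][0]
        except KeyError:
            raise KeyError(f"barcode {barcode!r} is not in the barcode map") from None

    def batch_of(self, barcode: str) -> str:
        try:
            return self._reverse[barcode][1]
        except KeyError:
            raise KeyError(f"barcode {barcode!r} is not in the barcode map") from None

    @property
    def barcode_names(self) -> list[str]:
        return list(self.assignments.values())

    def validate_against(self, panel: ReferencePanel) -> None:
        """Check that every amplicon gene has both batch assignments and every
        assigned barcode exists in the panel."""
        for gene in panel.gene_ids:
            for batch in BATCHES:
                if (gene, batch) not in self.assignments:
                    raise ValueError(f"barcode map misses gene {gene!r}, batch {batch!r}")
        for name in self.barcode_names:
            if name not in panel or panel.get(name).kind != "barcode":
                raise ValueError(f"assigned barcode {name!r} is not a barcode panel entry")

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id,batch,barcode\n")
            for (gene, batch), name in sorted(self.assignments.items()):
                fh.write(f"{gene},{batch},{name}\n")

    @classmethod
    def from_csv(cls, path) -> "BarcodeMap":
        assignments = {}
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header != ["gene_id", "batch", "barcode"]:
                raise ValueError(f"unexpected barcode map header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                gene, batch, name = line.strip().split(",")
                assignments[(gene, batch)] = name
        return cls(assignments)
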