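"""Summary artifacts: the signature table of definitive chimeras, headline
rates with their printed rounding, read-length "digital electrophoresis"
plots, and truth-based evaluation of simulated libraries."""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classify import ChimeraCall

CHIMERIC_TRUTH_CLASSES = frozenset((
    "chimera_repeat", "chimera_multi_amplicon", "chimera_multi_barcode",
    "chimera_disagreement", "insilico_join",
))


# ---------------------------------------------------------------------------
# Signature table


@dataclass
class SummaryRow:
    amplicon_counts: tuple[tuple[str, int], ...]
    overnight: bool
    quick: bool
    disagreement: bool
    count: int


@dataclass
class SummaryTable:
    genes: tuple[str, ...]
    rows: list[SummaryRow]          # displayed rows (count >= min_count)
    total_definitive: int           # includes suppressed rows
    suppressed: int                 # reads hidden by the display threshold
    min_count: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(list(self.genes) +
                               ["overnight", "quick", "disagreement", "count"]) + "\n")
            for r in self.rows:
                counts = dict(r.amplicon_counts)
                fh.write("\t".join(
                    [str(counts.get(g, 0)) for g in self.genes]
                    + ["o" if r.overnight else "", "o" if r.quick else "",
                       "o" if r.disagreement else "", str(r.count)]
                ) + "\n")

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = dict(r.amplicon_counts)
            rec.update(overnight=r.overnight, quick=r.quick,
                       disagreement=r.disagreement, count=r.count)
            recs.append(rec)
        cols = list(self.genes) + ["overnight", "quick", "disagreement", "count"]
        return pd.DataFrame(recs, columns=cols)


def tabulate(calls: list[ChimeraCall], min_count: int = 5) -> SummaryTable:
    """Group definitive calls by signature (per-gene amplicon counts x
    batches seen x disagreement), count-descending; signatures seen fewer
    than ``min_count`` times are suppressed from display but kept in the
    total."""
    definitive = [c for c in calls if c.definitive]
    genes: tuple[str, ...] = ()
    counts: dict[tuple, int] = {}
    for c in definitive:
        sig = c.signature
        if not genes:
            genes = tuple(g for g, _ in sig.amplicon_counts)
        key = (sig.amplicon_counts, "overnight" in sig.batches,
               "quick" in sig.batches, sig.disagreement)
        counts[key] = counts.get(key, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [SummaryRow(*key, count=n) for key, n in ordered if n >= min_count]
    shown = sum(r.count for r in rows)
    return SummaryTable(genes, rows, total_definitive=len(definitive),
                        suppressed=len(definitive) - shown, min_count=min_count)


# ---------------------------------------------------------------------------
# Headline rates


def _round_half_up(value: Decimal, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class RateEntry:
    name: str
    numerator: int
    denominator: int
    percent: float
    decimals: int


@dataclass
class RateReport:
    entries: dict[str, RateEntry]

    def percent(self, name: str) -> float:
        return self.entries[name].percent

    def to_csv(self, path) -> None:
        rows = [{"name": e.name, "numerator": e.numerator, "denominator": e.denominator,
                 "percent": e.percent} for e in self.entries.values()]
        pd.DataFrame(rows).to_csv(path, index=False)

    def __str__(self) -> str:
        lines = []
        for e in self.entries.values():
            pct = f"{e.percent:.{e.decimals}f}"
            lines.append(f"{e.name}: {e.numerator}/{e.denominator} = {pct}%")
        return "\n".join(lines)


def rates(counts: dict[str, tuple[int, int]],
          whole_percent: tuple[str, ...] = ("repeated_of_definitive",)) -> RateReport:
    """Compute named percentages from (numerator, denominator) pairs.

    Rounding is half-up to one decimal place, except names listed in
    ``whole_percent`` (by convention the repeated-amplicon share of
    definitive chimeras) which are reported as whole percents.
    """
    entries: dict[str, RateEntry] = {}
    for name, (num, den) in counts.items():
        if den == 0:
            raise ValueError(f"rate {name!r} has a zero denominator")
        decimals = 0 if name in whole_percent else 1
        pct = _round_half_up(Decimal(100 * num) / Decimal(den), decimals)
        entries[name] = RateEntry(name, num, den, pct, decimals)
    return RateReport(entries)


def headline_rates(calls: list[ChimeraCall], n_sequenced: int | None = None,
                   n_called: int | None = None, n_2d: int = 0) -> RateReport:
    """The standard named rates from a set of calls.

    ``n_called``/``n_2d`` let callers supply run-level totals (base-called
    reads, 2D-aligned reads); when absent, call-level rates only.
    """
    mappable = [c for c in calls if c.nonchimeric_class != "unmapped"]
    definitive = [c for c in calls if c.definitive]
    nonchim = [c for c in calls if not c.definitive and c.nonchimeric_class != "unmapped"]
    counts: dict[str, tuple[int, int]] = {}
    if mappable:
        counts["definitive_of_mappable"] = (len(definitive), len(mappable))
    if definitive:
        counts["repeated_of_definitive"] = (
            sum(c.repeated_amplicon for c in definitive), len(definitive))
        for batch, key in (("overnight", "overnight_chimera"), ("quick", "quick_chimera")):
            with_batch = [c for c in calls if batch in c.signature.batches
                          and any(n for _, n in c.signature.amplicon_counts)]
            if with_batch:
                counts[key] = (sum(c.definitive for c in with_batch), len(with_batch))
    if nonchim:
        counts["barcode_only_of_nonchimeric"] = (
            sum(c.nonchimeric_class == "barcode_only" for c in nonchim), len(nonchim))
    if n_called:
        counts["twod_of_called"] = (n_2d, n_called)
        counts["oned_of_called"] = (n_called - n_2d, n_called)
        counts["mappable_of_1d"] = (len(mappable), n_called - n_2d)
    return rates(counts)


# ---------------------------------------------------------------------------
# Digital electrophoresis


def length_plot(lengths, out_png=None) -> pd.DataFrame:
    """Read-length density table and (optionally) a gel-lane style image
    with a density curve alongside."""
    lengths = [int(x) for x in lengths]
    if not lengths:
        return pd.DataFrame(columns=["length", "count"])
    vals, cnts = np.unique(lengths, return_counts=True)
    table = pd.DataFrame({"length": vals, "count": cnts})
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        lo, hi = min(lengths), max(lengths)
        bins = np.linspace(lo, hi + 1, min(200, hi - lo + 2))
        hist, edges = np.histogram(lengths, bins=bins)
        fig, (ax_lane, ax_den) = plt.subplots(
            1, 2, figsize=(6, 6), sharey=True, width_ratios=[1, 3])
        lane = hist[::-1, None].astype(float)
        ax_lane.imshow(lane, aspect="auto", cmap="Greys",
                       extent=(0, 1, edges[0], edges[-1]))
        ax_lane.set_xticks([])
        ax_lane.set_ylabel("read length (bases)")
        ax_lane.set_title("lane")
        centers = (edges[:-1] + edges[1:]) / 2
        ax_den.plot(hist, centers)
        ax_den.set_xlabel("reads")
        ax_den.set_title("density")
        fig.tight_layout()
        fig.savefig(out_png, dpi=100)
        plt.close(fig)
    return table


# ---------------------------------------------------------------------------
# Truth-based evaluation


@dataclass
class EvaluationResult:
    confusion: pd.DataFrame        # truth_class x predicted label
    per_class: pd.DataFrame        # precision/recall per truth class
    precision: float
    recall: float
    rate_estimate: float
    rate_truth: float
    rate_ci: tuple[float, float]   # 95% binomial CI of the truth fraction
    rate_inside: bool

    def to_csv(self, path) -> None:
        self.per_class.to_csv(path, index=False)


def evaluate(calls: list[ChimeraCall], truth: pd.DataFrame) -> EvaluationResult:
    """Score calls against a simulation truth table.

    Truth-positive reads are those whose construct was chimeric (the four
    ligation mechanisms plus in-silico joins); clean constructs — including
    2D molecules, whose two-opposite-orientation pattern is deliberately
    not called — count as negatives.  Also recovers the chimera rate with
    the 95% binomial interval of the truth fraction.
    """
    from scipy.stats import binomtest

    call_ids = {c.read_id for c in calls}
    truth_ids = set(truth["read_id"])
    if call_ids != truth_ids:
        missing = sorted(truth_ids - call_ids)[:10] or sorted(call_ids - truth_ids)[:10]
        raise ValueError(f"call and truth read sets differ; e.g. {missing}")

    truth_class = dict(zip(truth["read_id"], truth["truth_class"]))
    pred = {c.read_id: ("definitive" if c.definitive else c.nonchimeric_class)
            for c in calls}

    cm = pd.crosstab(
        pd.Series({r: truth_class[r] for r in pred}, name="truth_class"),
        pd.Series(pred, name="predicted"),
    )

    tp = fp = fn = tn = 0
    per_class_rows = []
    for c in calls:
        positive_truth = truth_class[c.read_id] in CHIMERIC_TRUTH_CLASSES
        if c.definitive and positive_truth:
            tp += 1
        elif c.definitive:
            fp += 1
        elif positive_truth:
            fn += 1
        else:
            tn += 1
    for cls in sorted(set(truth_class.values())):
        ids = [r for r, t in truth_class.items() if t == cls]
        called = sum(1 for r in ids if pred[r] == "definitive")
        detect = called / len(ids)
        per_class_rows.append({
            "truth_class": cls,
            "n": len(ids),
            "recall": detect if cls in CHIMERIC_TRUTH_CLASSES else float("nan"),
            "false_positive_rate": float("nan") if cls in CHIMERIC_TRUTH_CLASSES else detect,
        })
    per_class = pd.DataFrame(per_class_rows)

    n = len(calls)
    k_truth = sum(1 for t in truth_class.values() if t in CHIMERIC_TRUTH_CLASSES)
    est = (tp + fp) / n if n else 0.0
    ci = binomtest(k_truth, n).proportion_ci(0.95) if n else (0.0, 1.0)
    ci_t = (float(ci.low), float(ci.high))
    return EvaluationResult(
        confusion=cm,
        per_class=per_class,
        precision=tp / (tp + fp) if (tp + fp) else 1.0,
        recall=tp / (tp + fn) if (tp + fn) else 1.0,
        rate_estimate=est,
        rate_truth=k_truth / n if n else 0.0,
        rate_ci=ci_t,
        rate_inside=ci_t[0] <= est <= ci_t[1],
    )
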