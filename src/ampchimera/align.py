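"""Panel-vs-read local alignment: find every occurrence of every panel
sequence on each read (both strands), express hits in forward read
coordinates, and merge co-linear fragments of the same target.

The aligner is an affine-gap Smith-Waterman (Gotoh) dynamic program with
traceback, JIT-compiled with numba.  Repeated occurrences of the same target
are found by iterative masking: after each accepted hit the covered read
interval is masked and the target is re-aligned until the score drops below
threshold.  Long targets are pre-filtered with a shared k-mer count so that
reads are only fully aligned against targets they plausibly contain.

Coordinates are 0-based, half-open and always refer to the forward strand of
the read; a reverse-strand hit is an alignment of the reverse-complemented
target, so its read interval needs no projection while its target interval
is mirrored back into original target coordinates.

A gap of length L costs ``gap_open + L * gap_extend``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import encode, revcomp
from .panel import ReferencePanel

_NEG = -1_000_000


@njit(cache=True)
def _sw_affine(q, t, qmask, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.size
    m = t.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    PH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    PE = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extension
    PF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        masked = qmask[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                PE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                PF[i, j] = 1
            else:
                F[i, j] = f_open
            if masked:
                s = _NEG
            elif qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = -mismatch
            h = 0
            p = 0
            d = H[i - 1, j - 1] + s
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    nmatch = 0
    ncols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                ncols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    nmatch += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ncols += 1
            ext = PE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            ncols += 1
            ext = PF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi, j, bj, nmatch, ncols


@dataclass
class ScoringScheme:
    """Alignment scoring and per-kind acceptance thresholds.

    ``min_score`` and ``min_coverage`` are per panel kind; coverage is the
    aligned fraction of the *target*, which keeps short spurious barcode hits
    out while full-length (if error-eroded) barcode ligations pass.
    """

    match_reward: int = 1
    mismatch_penalty: int = 1
    gap_open: int = 2
    gap_extend: int = 1
    min_score: dict[str, int] = field(
        default_factory=lambda: {"barcode": 12, "amplicon": 50, "hairpin": 18,
                                 "leader": 14, "control": 50}
    )
    min_identity: float = 0.70
    min_coverage: dict[str, float] = field(
        default_factory=lambda: {"barcode": 0.70, "hairpin": 0.50, "leader": 0.50}
    )

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")

    def min_score_for(self, kind: str) -> int:
        return self.min_score.get(kind, 25)

    def min_coverage_for(self, kind: str) -> float:
        return self.min_coverage.get(kind, 0.0)


@dataclass
class Match:
    """One local alignment of a panel entry to a read, in forward read
    coordinates regardless of orientation."""

    read_id: str
    target: str
    kind: str
    read_start: int
    read_end: int
    orientation: str
    score: int
    identity: float
    target_start: int = 0
    target_end: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.read_start < self.read_end:
            raise ValueError(
                f"{self.read_id}/{self.target}: bad read interval "
                f"[{self.read_start},{self.read_end})"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0,1], got {self.identity}")
        if self.orientation not in ("fwd", "rev"):
            raise ValueError(f"orientation must be fwd/rev, got {self.orientation!r}")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


def local_align(query: str, target: str, scheme: ScoringScheme | None = None
                ) -> tuple[int, tuple[int, int], tuple[int, int], float]:
    """Best affine-gap local alignment of ``target`` within ``query``.

    Returns (score, query interval, target interval, identity); identity is
    matched columns over all alignment columns (gaps included).  The empty
    alignment scores 0, so an all-mismatch pair returns at best a single
    forced-match column or (0, (0,0), (0,0), 0.0).
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    q = encode(query)
    t = encode(target)
    mask = np.zeros(q.size, dtype=np.uint8)
    score, qs, qe, ts, te, nmatch, ncols = _sw_affine(
        q, t, mask, scheme.match_reward, scheme.mismatch_penalty,
        scheme.gap_open, scheme.gap_extend
    )
    if score <= 0:
        return 0, (0, 0), (0, 0), 0.0
    identity = nmatch / ncols if ncols else 0.0
    return int(score), (int(qs), int(qe)), (int(ts), int(te)), identity


# ---------------------------------------------------------------------------
# Read scanning

_SEED_K = 11
_SEED_MIN = 2
_SEED_TARGET_MIN_LEN = 100  # only prefilter long targets; barcodes always align
_MAX_HITS_PER_TARGET = 12


def _kmers(codes: np.ndarray, k: int) -> np.ndarray:
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    if np.any(codes >= 4):
        codes = np.where(codes >= 4, 0, codes)
    vals = np.zeros(codes.size - k + 1, dtype=np.int64)
    for off in range(k):
        vals = vals * 4 + codes[off:off + codes.size - k + 1]
    return vals


def _unmasked_kmer_set(codes: np.ndarray, mask: np.ndarray, k: int) -> set:
    vals = _kmers(codes, k)
    if vals.size == 0:
        return set()
    bad = np.convolve(mask.astype(np.int32), np.ones(k, dtype=np.int32), mode="valid") > 0
    return set(vals[~bad].tolist())


def _normalize_read(read) -> tuple[str, str]:
    if isinstance(read, tuple):
        return read
    seq = getattr(read, "sequence", None)
    if seq is None:
        seq = str(getattr(read, "seq"))
    return getattr(read, "id"), seq


def scan_read(read, panel: ReferencePanel, scheme: ScoringScheme | None = None
              ) -> list[Match]:
    """All above-threshold occurrences of every panel entry on a read, both
    strands, sorted by forward read start."""
    read_id, seq = _normalize_read(read)
    if not seq:
        raise ValueError(f"read {read_id!r} is empty")
    scheme = scheme or ScoringScheme()
    q = encode(seq)
    matches: list[Match] = []
    for entry in panel:
        m = len(entry.sequence)
        min_score = scheme.min_score_for(entry.kind)
        min_cov = scheme.min_coverage_for(entry.kind)
        for orientation in ("fwd", "rev"):
            tseq = entry.sequence if orientation == "fwd" else revcomp(entry.sequence)
            t = encode(tseq)
            use_seeds = m >= _SEED_TARGET_MIN_LEN
            tkmers = set(_kmers(t, _SEED_K).tolist()) if use_seeds else None
            mask = np.zeros(q.size, dtype=np.uint8)
            for _ in range(_MAX_HITS_PER_TARGET):
                if use_seeds:
                    rset = _unmasked_kmer_set(q, mask, _SEED_K)
                    shared = sum(1 for km in tkmers if km in rset)
                    if shared < _SEED_MIN:
                        break
                score, qs, qe, ts, te, nmatch, ncols = _sw_affine(
                    q, t, mask, scheme.match_reward, scheme.mismatch_penalty,
                    scheme.gap_open, scheme.gap_extend
                )
                if score < min_score or qe <= qs:
                    break
                identity = nmatch / ncols if ncols else 0.0
                coverage = (te - ts) / m
                accept = identity >= scheme.min_identity and coverage >= min_cov
                if accept:
                    if orientation == "fwd":
                        t0, t1 = int(ts), int(te)
                    else:
                        t0, t1 = m - int(te), m - int(ts)
                    matches.append(Match(read_id, entry.name, entry.kind,
                                         int(qs), int(qe), orientation,
                                         int(score), identity, t0, t1))
                mask[qs:qe] = 1
                if not accept:
                    break
    matches.sort(key=lambda x: (x.read_start, x.read_end, x.target, x.orientation))
    return _dedup_identical(matches)


def _dedup_identical(matches: list[Match]) -> list[Match]:
    """Identical-interval duplicate hits keep only the highest score, ties
    broken lexicographically by target name."""
    out: list[Match] = []
    for m in matches:
        if out and (m.read_start, m.read_end) == (out[-1].read_start, out[-1].read_end):
            prev = out[-1]
            if m.score > prev.score or (m.score == prev.score and m.target < prev.target):
                out[-1] = m
            continue
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Co-linear merging

_TARGET_OVERLAP_TOL = 5


def merge_colinear(matches: list[Match], max_gap: int = 50) -> list[Match]:
    """Merge runs of matches to the same target in the same orientation that
    are separated on the read by at most ``max_gap`` bases and advance
    consistently along the target.

    Scores are summed and identities length-weighted; anything else is
    returned unchanged.  Matches that repeat a target from its start (a
    genuine repeated-amplicon chimera) do not advance along the target and
    are therefore never merged.
    """
    if any(matches[i].read_start > matches[i + 1].read_start
           for i in range(len(matches) - 1)):
        raise ValueError("merge_colinear requires matches sorted by read_start")
    ids = {m.read_id for m in matches}
    if len(ids) > 1:
        raise ValueError(f"merge_colinear requires a single read, got {sorted(ids)}")

    groups: dict[tuple[str, str], list[Match]] = {}
    for m in matches:
        groups.setdefault((m.target, m.orientation), []).append(m)

    out: list[Match] = []
    for (_, orientation), group in groups.items():
        group.sort(key=lambda m: (m.read_start, m.read_end, m.target_start))
        # single passes to a fixpoint: chains of fragments collapse fully
        while True:
            merged = _merge_pass(group, orientation, max_gap)
            if len(merged) == len(group):
                break
            group = merged
        out.extend(group)
    out.sort(key=lambda x: (x.read_start, x.read_end, x.target, x.orientation))
    return out


def _merge_pass(group: list[Match], orientation: str, max_gap: int) -> list[Match]:
    out: list[Match] = []
    cur = group[0]
    acc_len = cur.read_span
    acc_ident = cur.identity * cur.read_span
    for nxt in group[1:]:
        gap = nxt.read_start - cur.read_end
        if orientation == "fwd":
            advances = nxt.target_start >= cur.target_end - _TARGET_OVERLAP_TOL
        else:
            advances = nxt.target_end <= cur.target_start + _TARGET_OVERLAP_TOL
        if -_TARGET_OVERLAP_TOL <= gap <= max_gap and advances:
            acc_len += nxt.read_span
            acc_ident += nxt.identity * nxt.read_span
            cur = Match(
                cur.read_id, cur.target, cur.kind,
                cur.read_start, max(cur.read_end, nxt.read_end), orientation,
                cur.score + nxt.score, acc_ident / acc_len,
                min(cur.target_start, nxt.target_start),
                max(cur.target_end, nxt.target_end),
            )
        else:
            out.append(cur)
            cur = nxt
            acc_len = cur.read_span
            acc_ident = cur.identity * cur.read_span
    out.append(cur)
    out.sort(key=lambda m: (m.read_start, m.read_end, m.target_start))
    return out


_CONTAINER_KINDS = ("amplicon", "control")
_SHORT_KINDS = ("barcode", "hairpin", "leader")


def filter_matches(matches: list[Match], margin: int = 10,
                   overlap_frac: float = 0.5) -> list[Match]:
    """Structural cleanup of a merged match list.

    Two rules, both reflecting that a read position holds exactly one
    physical element:

    * *containment*: a short-element hit (barcode/adapter) lying strictly
      inside a single amplicon or control alignment, at least ``margin``
      bases from either end, can only be a chance similarity of the long
      sequence's interior and is dropped.  Hits overlapping an amplicon's
      edges are kept — classification needs barcodes adjacent to the
      amplicons they disagree with.
    * *same-locus competition*: when two short-element hits overlap by at
      least ``overlap_frac`` of the shorter one, only the best-scoring hit
      (ties broken lexicographically by target) survives; distinct barcodes
      on a genuine chimera occupy distinct loci and are unaffected.
    """
    containers = [m for m in matches if m.kind in _CONTAINER_KINDS]
    kept_long = [m for m in matches if m.kind not in _SHORT_KINDS]
    short = [m for m in matches if m.kind in _SHORT_KINDS]

    short.sort(key=lambda m: (-m.score, m.target, m.read_start))
    accepted: list[Match] = []
    for m in short:
        if any(c.read_start + margin <= m.read_start and m.read_end <= c.read_end - margin
               for c in containers):
            continue
        conflict = False
        for a in accepted:
            ov = min(m.read_end, a.read_end) - max(m.read_start, a.read_start)
            if ov > 0 and ov >= overlap_frac * min(m.read_span, a.read_span):
                conflict = True
                break
        if not conflict:
            accepted.append(m)

    out = kept_long + accepted
    out.sort(key=lambda x: (x.read_start, x.read_end, x.target, x.orientation))
    return out


# ---------------------------------------------------------------------------
# MAF input


def read_maf(path, panel: ReferencePanel | None = None) -> list[Match]:
    """Parse pairwise MAF blocks (reference ``s`` line then read ``s`` line)
    into :class:`Match` records with forward-oriented read coordinates.

    Minus-strand read coordinates are converted with
    ``forward_start = srcSize - start - size``.
    """
    matches: list[Match] = []
    block_idx = -1
    with open(path) as fh:
        score = 0
        s_lines: list[list[str]] = []
        in_block = False

        def finish():
            nonlocal s_lines, in_block
            if not in_block:
                return
            if len(s_lines) < 2:
                raise ValueError(f"malformed MAF block {block_idx}: expected two 's' lines")
            tname, tstart, tsize, tstrand, tsrc, ttext = s_lines[0]
            rname, rstart, rsize, rstrand, rsrc, rtext = s_lines[1]
            tstart, tsize = int(tstart), int(tsize)
            rstart, rsize, rsrc_i = int(rstart), int(rsize), int(rsrc)
            if rstrand == "+":
                r0, r1 = rstart, rstart + rsize
                orientation = "fwd"
            else:
                r0, r1 = rsrc_i - rstart - rsize, rsrc_i - rstart
                orientation = "rev"
            ncols = len(ttext)
            nmatch = sum(1 for a, b in zip(ttext.upper(), rtext.upper())
                         if a == b and a != "-")
            identity = nmatch / ncols if ncols else 0.0
            kind = "unknown"
            if panel is not None and tname in panel:
                kind = panel.get(tname).kind
            matches.append(Match(rname, tname, kind, r0, r1, orientation,
                                 score, identity, tstart, tstart + tsize))
            s_lines = []
            in_block = False

        for line in fh:
            line = line.strip()
            if line.startswith("a"):
                finish()
                in_block = True
                block_idx += 1
                score = 0
                for tok in line.split()[1:]:
                    if tok.startswith("score="):
                        score = int(float(tok[6:]))
            elif line.startswith("s"):
                if not in_block:
                    raise ValueError(f"malformed MAF: 's' line outside a block near block {block_idx}")
                parts = line.split()
                if len(parts) != 7:
                    raise ValueError(f"malformed MAF block {block_idx}: bad 's' line")
                s_lines.append(parts[1:])
        finish()
    return matches


# ---------------------------------------------------------------------------
# CSV round trip

MATCH_COLUMNS = ["read_id", "target", "kind", "read_start", "read_end",
                 "orientation", "score", "identity", "target_start", "target_end"]


def write_matches(matches: list[Match], path) -> None:
    import pandas as pd

    rows = [{c: getattr(m, c) for c in MATCH_COLUMNS} for m in matches]
    pd.DataFrame(rows, columns=MATCH_COLUMNS).to_csv(path, index=False)


def read_matches(path) -> list[Match]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        Match(r.read_id, r.target, r.kind, int(r.read_start), int(r.read_end),
              r.orientation, int(r.score), float(r.identity),
              int(r.target_start), int(r.target_end))
        for r in df.itertuples(index=False)
    ]
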