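"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the aligner oracle is a
plain-Python affine-gap dynamic program over dict-free nested lists, and the
classification oracle literally enumerates the four chimera rules (plus the
two-opposite-orientation exclusion) over match pairs.
"""
from __future__ import annotations


def gotoh_local_score(query: str, target: str, match: int = 1, mismatch: int = 1,
                      gap_open: int = 2, gap_extend: int = 1) -> int:
    """Best local affine-gap alignment score; a gap of length L costs
    gap_open + L * gap_extend.  O(n*m) with explicit three-state recurrence."""
    n, m = len(query), len(target)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if query[i - 1] == target[j - 1] else -mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def literal_chimera_rules(matches, panel, barcode_map):
    """Literal four-rule enumerator over an annotation's matches.

    ``matches`` is a list of objects with target/kind/orientation; rules are
    checked by explicit pairwise loops, with the exclusion spelled out:
    exactly two amplicon matches to the same gene in opposite orientations
    set no repeated-amplicon flag.
    """
    amps = [m for m in matches if m.kind == "amplicon"]
    bcs = [m for m in matches if m.kind == "barcode"]

    # rule 1: repeated identical amplicons aligned in the same direction
    repeated = False
    for i in range(len(amps)):
        for j in range(i + 1, len(amps)):
            if (panel.gene_of(amps[i].target) == panel.gene_of(amps[j].target)
                    and amps[i].orientation == amps[j].orientation):
                repeated = True
    # exclusion: exactly two same-gene matches in opposite orientations
    if len(amps) == 2 and panel.gene_of(amps[0].target) == panel.gene_of(amps[1].target) \
            and amps[0].orientation != amps[1].orientation:
        repeated = False

    # rule 2: at least two distinct amplicons
    multi_amplicon = False
    for i in range(len(amps)):
        for j in range(i + 1, len(amps)):
            if panel.gene_of(amps[i].target) != panel.gene_of(amps[j].target):
                multi_amplicon = True

    # rule 3: at least two distinct barcodes
    multi_barcode = False
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            if bcs[i].target != bcs[j].target:
                multi_barcode = True

    # rule 4: disagreement between barcode and amplicon, or barcode pair
    disagreement = False
    for b in bcs:
        for a in amps:
            if barcode_map.gene_of(b.target) != panel.gene_of(a.target):
                disagreement = True
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            if barcode_map.gene_of(bcs[i].target) != barcode_map.gene_of(bcs[j].target):
                disagreement = True

    return {
        "repeated_amplicon": repeated,
        "multi_amplicon": multi_amplicon,
        "multi_barcode": multi_barcode,
        "disagreement": disagreement,
    }
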