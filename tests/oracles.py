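"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package internals: the partition
oracle paints one label per base into dense arrays (lowest-precedence class
first so higher precedence overwrites), the assignment oracle tallies
per-base labels over a read's blocks, and the proportion-test oracle is the
textbook closed-form 2x2 chi-square with continuity correction.
"""

import numpy as np
from scipy.stats import chi2

# class codes mirror the documented precedence (low wins); painting order is
# the reverse so the final array holds the winning class per base
CODES = {
    "RRNA": 0, "CDS": 1, "UTR5": 2, "UTR3": 3,
    "INTRON": 4, "UP1K": 5, "DOWN1K": 6, "INTERGENIC": 7,
}
PAINT_ORDER = ["DOWN1K", "UP1K", "INTRON", "UTR3", "UTR5", "CDS", "RRNA"]
STRAND_CODE = {"+": 1, "-": -1, ".": 0}


def paint_partition(genes, rrna, chrom_sizes, flank=1000):
    """Per-base class and feature-strand arrays for every chromosome."""
    classes = {c: np.full(n, CODES["INTERGENIC"], dtype=np.uint8) for c, n in chrom_sizes.items()}
    strands = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_sizes.items()}

    feats = {name: [] for name in PAINT_ORDER}
    for g in genes:
        lo, hi = g.span
        size = chrom_sizes[g.chrom]
        up = (lo - flank, lo) if g.strand == "+" else (hi, hi + flank)
        down = (hi, hi + flank) if g.strand == "+" else (lo - flank, lo)
        feats["UP1K"].append((g.chrom, max(0, up[0]), min(size, up[1]), g.strand))
        feats["DOWN1K"].append((g.chrom, max(0, down[0]), min(size, down[1]), g.strand))
        for s, e in g.introns:
            feats["INTRON"].append((g.chrom, s, e, g.strand))
        for s, e in g.utr3:
            feats["UTR3"].append((g.chrom, s, e, g.strand))
        for s, e in g.utr5:
            feats["UTR5"].append((g.chrom, s, e, g.strand))
        for s, e in g.cds:
            feats["CDS"].append((g.chrom, s, e, g.strand))
    for r in rrna:
        feats["RRNA"].append((r.chrom, r.start, r.end, r.strand))

    for name in PAINT_ORDER:
        for chrom, s, e, strand in feats[name]:
            classes[chrom][s:e] = CODES[name]
            strands[chrom][s:e] = STRAND_CODE[strand]
    return classes, strands


def paint_repeats(repeats, chrom_sizes):
    """Per-base repeat-entry index (-1 where no repeat); repeats are disjoint."""
    arr = {c: np.full(n, -1, dtype=np.int32) for c, n in chrom_sizes.items()}
    for i, r in enumerate(repeats):
        arr[r["chrom"]][r["start"]:r["end"]] = i
    return arr


def oracle_assign(read, classes, strands, rep_arr, repeats):
    """(region label, family or None, orientation) by per-base majority."""
    base_classes = np.concatenate([classes[read.chrom][s:e] for s, e in read.blocks])
    base_reps = np.concatenate([rep_arr[read.chrom][s:e] for s, e in read.blocks])
    total = len(base_classes)
    rep_bases = int((base_reps >= 0).sum())
    if 2 * rep_bases > total:
        idx, counts = np.unique(base_reps[base_reps >= 0], return_counts=True)
        best = min(
            zip(idx.tolist(), counts.tolist()),
            key=lambda t: (-t[1], repeats[t[0]]["start"], repeats[t[0]]["family"]),
        )[0]
        rep = repeats[best]
        orient = "sense" if read.strand == rep["strand"] else "antisense"
        return "REPEAT", rep["family"], orient
    codes, counts = np.unique(base_classes, return_counts=True)
    win = min(zip(codes.tolist(), counts.tolist()), key=lambda t: (-t[1], t[0]))[0]
    label = {v: k for k, v in CODES.items()}[win]
    if label == "INTERGENIC":
        return label, None, ("plus" if read.strand == "+" else "minus")
    base_strands = np.concatenate([strands[read.chrom][s:e] for s, e in read.blocks])
    sel = base_strands[base_classes == win]
    vals, cnts = np.unique(sel, return_counts=True)
    fstrand = {1: "+", -1: "-", 0: "."}[int(vals[np.argmax(cnts)])]
    return label, None, ("sense" if read.strand == fstrand else "antisense")


def yates_two_proportion(x1, n1, x2, n2):
    """Closed-form 2x2 chi-square with continuity correction (clamped at 0)."""
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if c1 == 0 or c2 == 0:
        return 0.0, 1.0
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    return stat, float(chi2.sf(stat, 1))
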