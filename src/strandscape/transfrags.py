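"""Transfrag (assembled transcribed fragment) classification and expression.

Externally assembled transfrags are classified against the genome
partition: a transfrag is called intronic (or intergenic) when strictly
more than 80% of its exonic bases fall in intron (or intergenic) primary
classes; anything else is "other".  Repeat-overlay bases count toward
their host primary class here, and the share is computed over interval
(exonic) bases only.  Expression is the number of overlapping reads
divided by the transfrag length, per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import intervals as ivl
from .annotation import PartitionIndex, RegionClass
from .assignment import AlignedRead
from .intervals import Interval

DEFAULT_CLASS_SHARE = 0.8


@dataclass
class Transfrag:
    id: str
    chrom: str
    strand: str
    intervals: List[Interval]

    def __post_init__(self) -> None:
        self.intervals = ivl.normalize(self.intervals)
        if not self.intervals:
            raise ValueError(f"transfrag {self.id} has zero length")

    @property
    def total_length(self) -> int:
        return ivl.total_length(self.intervals)


def read_bed12(path: str) -> List[Transfrag]:
    """BED12 transfrags: block-defined exon intervals, 0-based half-open."""
    out: List[Transfrag] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            out.append(Transfrag(name, chrom, strand, blocks))
    return out


def read_gtf_transfrags(path: str) -> List[Transfrag]:
    """Cufflinks-style GTF: exon records grouped by transcript_id."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    grouped: Dict[str, Tuple[str, str, List[Interval]]] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        chrom, strand, blocks = grouped.setdefault(tid, (feat.seqid, feat.strand, []))
        blocks.append((feat.start - 1, feat.end))
    return [Transfrag(tid, c, s, b) for tid, (c, s, b) in sorted(grouped.items())]


def class_shares(tf: Transfrag, index: PartitionIndex) -> Dict[str, float]:
    """Fraction of the transfrag's exonic bases per primary class (sums to 1)."""
    total = tf.total_length
    bases: Dict[str, int] = {}
    for bs, be in tf.intervals:
        for s, e, cls, _g, _st in index.segments(tf.chrom, bs, be):
            bases[cls.name] = bases.get(cls.name, 0) + (e - s)
    return {k: v / total for k, v in bases.items()}


def classify_transfrags(
    transfrags: Sequence[Transfrag],
    index: PartitionIndex,
    class_share: float = DEFAULT_CLASS_SHARE,
) -> pd.DataFrame:
    """Classify transfrags by the strict >``class_share`` base-share rule.

    Returns one row per transfrag with its class, length and per-class
    shares.  The threshold is a strict inequality: a transfrag with exactly
    80% intronic bases is "other".
    """
    rows = []
    for tf in transfrags:
        shares = class_shares(tf, index)
        intronic = shares.get(RegionClass.INTRON.name, 0.0)
        intergenic = shares.get(RegionClass.INTERGENIC.name, 0.0)
        if intronic > class_share:
            cls = "intronic"
        elif intergenic > class_share:
            cls = "intergenic"
        else:
            cls = "other"
        row = {
            "id": tf.id,
            "chrom": tf.chrom,
            "class": cls,
            "length": tf.total_length,
            "share_intronic": intronic,
            "share_intergenic": intergenic,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def length_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Count and mean/median length per transfrag class."""
    return (
        classified.groupby("class")["length"]
        .agg(n="count", mean_length="mean", median_length="median")
        .reset_index()
    )


def transfrag_expression(
    transfrags: Sequence[Transfrag],
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
) -> pd.DataFrame:
    """Per-sample expression: overlapping reads / transfrag length.

    A read counts once per transfrag it touches (any aligned base overlap);
    transfrags are an overlay, so one read may count toward several.
    """
    trees: Dict[str, IntervalTree] = {}
    for i, tf in enumerate(transfrags):
        tree = trees.setdefault(tf.chrom, IntervalTree())
        for s, e in tf.intervals:
            tree.addi(s, e, i)
    counts = {sid: np.zeros(len(transfrags), dtype=np.int64) for sid in reads_by_sample}
    for sid, reads in reads_by_sample.items():
        vec = counts[sid]
        for read in reads:
            tree = trees.get(read.chrom)
            if tree is None:
                continue
            hit: set = set()
            for s, e in read.blocks:
                for node in tree.overlap(s, e):
                    hit.add(node.data)
            for i in hit:
                vec[i] += 1
    out = pd.DataFrame({"id": [tf.id for tf in transfrags],
                        "length": [tf.total_length for tf in transfrags]})
    for sid in sorted(reads_by_sample):
        out[f"reads_{sid}"] = counts[sid]
        out[f"expression_{sid}"] = counts[sid] / out["length"]
    return out


def expression_histogram(
    expression: pd.Series, n_bins: int = 20
) -> pd.DataFrame:
    """Log-spaced histogram of positive expression values (zeros binned apart)."""
    x = expression.to_numpy(dtype=float)
    pos = x[x > 0]
    rows = [{"bin_lo": 0.0, "bin_hi": 0.0, "count": int((x == 0).sum())}]
    if len(pos):
        edges = np.logspace(np.log10(pos.min()), np.log10(pos.max()), n_bins + 1)
        hist, _ = np.histogram(pos, bins=edges)
        rows += [
            {"bin_lo": float(lo), "bin_hi": float(hi), "count": int(n)}
            for lo, hi, n in zip(edges[:-1], edges[1:], hist)
        ]
    return pd.DataFrame(rows)
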