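"""Gene annotations and divergent (head-to-head) gene pair detection.

A head-to-head (h2h) gene pair is a pair of adjacent genes transcribed
divergently from opposite DNA strands, with their transcription start
sites (TSSs) facing each other.  The intergenic stretch between the two
TSSs — typically under 1 kb — is the bidirectional promoter.  This module
parses gene annotations (GFF3 or a simple TSV), detects h2h pairs, builds
the two standard control pair sets (same-strand adjacent neighbours of
h2h genes, and uniformly random gene pairs), and bins signed TSS
distances into the interval histogram used for the distance analysis.

Coordinates are 1-based inclusive throughout.  The TSS distance of a pair
is signed: ``plus_gene.tss - minus_gene.tss``; a non-positive distance
means the two transcription units overlap.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")

__all__ = [
    "GeneRecord",
    "H2HPair",
    "PairSet",
    "canonical_key",
    "read_annotation",
    "detect_h2h_pairs",
    "same_strand_adjacent_pairs",
    "sample_random_pairs",
    "bin_tss_distances",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotations."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: id, chromosome, strand, and 1-based TSS / TES coordinates.

    For a ``+`` strand gene the TSS precedes the TES (tss < tes); for a
    ``-`` strand gene transcription runs leftward so tss > tes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.strand == "+" and not self.tss < self.tes:
            raise AnnotationError(
                f"gene {self.gene_id!r}: + strand requires tss < tes "
                f"(got tss={self.tss}, tes={self.tes})"
            )
        if self.strand == "-" and not self.tss > self.tes:
            raise AnnotationError(
                f"gene {self.gene_id!r}: - strand requires tss > tes "
                f"(got tss={self.tss}, tes={self.tes})"
            )


def canonical_key(a: str, b: str) -> tuple[str, str]:
    """Order-free identity of a gene pair: the sorted id tuple."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class H2HPair:
    """A divergent adjacent gene pair with signed TSS distance.

    ``tss_distance = plus_gene.tss - minus_gene.tss``; ``overlapping`` is
    true exactly when the distance is non-positive.
    """

    minus_gene: str
    plus_gene: str
    chrom: str
    tss_distance: int

    @property
    def overlapping(self) -> bool:
        return self.tss_distance <= 0

    @property
    def key(self) -> tuple[str, str]:
        return canonical_key(self.minus_gene, self.plus_gene)


@dataclass
class PairSet:
    """A labelled collection of unordered gene-id pairs.

    Curated sets (h2h, adjacent controls) are unique by canonical key and
    contain no self-pairs.  Random control sets drawn with replacement
    across replicates are built with ``unique=False``: duplicates across
    replicates are then allowed, self-pairs never are.
    """

    label: str
    pairs: list[tuple[str, str]]
    unique: bool = True
    replicate: list[int] | None = None

    def __post_init__(self) -> None:
        canon = [canonical_key(*p) for p in self.pairs]
        for a, b in canon:
            if a == b:
                raise ValueError(f"pair set {self.label!r}: self-pair {a!r}")
        if self.unique and len(set(canon)) != len(canon):
            raise ValueError(f"pair set {self.label!r}: duplicate pairs")
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def keys(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    @classmethod
    def from_h2h(cls, pairs: Iterable[H2HPair], label: str = "h2h") -> "PairSet":
        return cls(label=label, pairs=[p.key for p in pairs])


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _record_from_bounds(gene_id, chrom, strand, start, end, line_no=None):
    """Build a GeneRecord from 1-based inclusive [start, end] gene bounds."""
    if end < start:
        raise AnnotationError(
            f"line {line_no}: gene {gene_id!r} has end < start ({end} < {start})"
        )
    if strand == "+":
        return GeneRecord(gene_id, chrom, strand, tss=start, tes=end)
    if strand == "-":
        return GeneRecord(gene_id, chrom, strand, tss=end, tes=start)
    raise AnnotationError(f"line {line_no}: gene {gene_id!r} has strand {strand!r}")


def _read_gff3(path: str) -> list[GeneRecord]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except ValueError as exc:  # gffutils signals duplicate IDs with ValueError
        raise AnnotationError(f"{path}: {exc}") from exc
    records = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise AnnotationError(f"{path}: duplicate gene id {gid!r}")
        seen.add(gid)
        records.append(
            _record_from_bounds(gid, feat.seqid, feat.strand, feat.start, feat.end)
        )
    return records


TSV_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes"]


def _read_tsv(path: str) -> list[GeneRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise AnnotationError(f"{path}: duplicate gene ids {dups[:5]}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                GeneRecord(row.gene_id, row.chrom, row.strand, int(row.tss), int(row.tes))
            )
        except (AnnotationError, ValueError) as exc:
            raise AnnotationError(f"{path} line {i}: {exc}") from exc
    return records


def read_annotation(path: str, dialect: str = "auto") -> list[GeneRecord]:
    """Read gene records from a GFF3 file or a 5-column TSV.

    The TSV dialect has columns gene_id/chrom/strand/tss/tes with TSS and
    TES already strand-resolved; in GFF3 the TSS is the ``start`` of a
    ``+`` strand gene and the ``end`` of a ``-`` strand gene (1-based,
    inclusive, as the format specifies).
    """
    if dialect == "auto":
        dialect = "gff3" if str(path).endswith((".gff", ".gff3")) else "tsv"
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if os.path.getsize(path) == 0:
        logger.warning("annotation file %s is empty", path)
        return []
    records = _read_gff3(path) if dialect == "gff3" else _read_tsv(path)
    if not records:
        logger.warning("annotation file %s contains no gene records", path)
    return records


# ---------------------------------------------------------------------------
# Pair detection
# ---------------------------------------------------------------------------

def detect_h2h_pairs(
    genes: Iterable[GeneRecord],
    max_distance: int = 1000,
    max_overlap: int | None = 2000,
) -> list[H2HPair]:
    """Find divergent adjacent (head-to-head) gene pairs.

    A pair consists of a ``-`` strand gene M and a ``+`` strand gene P on
    the same chromosome with no other gene's TSS strictly between their
    TSSs, signed distance ``P.tss - M.tss`` at most ``max_distance``, and
    an overlap ``M.tss - P.tss`` of at most ``max_overlap`` base pairs
    (``None`` = unlimited).  The overlap cap matters: without it, a
    convergent tail-to-tail neighbour pair — plus gene upstream of a
    minus gene, TSSs pointing at each other across both gene bodies —
    satisfies the distance and adjacency predicates and would be misread
    as a deeply overlapping divergent pair.  Output is sorted by
    chromosome, then the minus gene's TSS, and is independent of input
    ordering.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs: list[H2HPair] = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.tss, g.gene_id))
        tss_sorted = [g.tss for g in chrom_genes]
        minus = [g for g in chrom_genes if g.strand == "-"]
        plus = [g for g in chrom_genes if g.strand == "+"]
        for m in minus:
            for p in plus:
                d = p.tss - m.tss
                if d > max_distance:
                    continue
                if max_overlap is not None and -d > max_overlap:
                    continue
                lo, hi = min(m.tss, p.tss), max(m.tss, p.tss)
                # adjacency: no third gene's TSS strictly inside (lo, hi)
                n_between = bisect_left(tss_sorted, hi) - bisect_right(tss_sorted, lo)
                if n_between > 0:
                    continue
                pairs.append(H2HPair(m.gene_id, p.gene_id, chrom, d))
    tss_of = {g.gene_id: g.tss for gs in by_chrom.values() for g in gs}
    pairs.sort(key=lambda p: (p.chrom, tss_of[p.minus_gene], p.minus_gene))
    return pairs


def same_strand_adjacent_pairs(
    genes: Sequence[GeneRecord], focal_genes: Iterable[str]
) -> PairSet:
    """Pair each focal gene with its nearest same-strand neighbour per side.

    For every focal gene, the closest gene (by TSS order on the same
    chromosome) carrying the same strand is taken on the left and on the
    right; the resulting pairs are deduplicated by canonical key.  This is
    the standard "same-strand adjacent" control for h2h gene sets.
    """
    by_id = {g.gene_id: g for g in genes}
    focal = list(focal_genes)
    for gid in focal:
        if gid not in by_id:
            raise KeyError(f"focal gene {gid!r} absent from annotation")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.tss, g.gene_id))

    keys: set[tuple[str, str]] = set()
    for gid in focal:
        g = by_id[gid]
        chrom_genes = by_chrom[g.chrom]
        i = chrom_genes.index(g)
        for step in (-1, 1):
            j = i + step
            while 0 <= j < len(chrom_genes):
                if chrom_genes[j].strand == g.strand:
                    keys.add(canonical_key(gid, chrom_genes[j].gene_id))
                    break
                j += step
    return PairSet(label="adjacent-control", pairs=sorted(keys))


def sample_random_pairs(
    gene_ids: Iterable[str], n_per_rep: int, n_reps: int, seed: int
) -> PairSet:
    """Sample ``n_per_rep * n_reps`` uniform random gene pairs (no self-pairs).

    Pairs are drawn with replacement, so duplicates across (and within)
    replicates can occur; the replicate index of each pair is retained.
    Identical seeds give identical samples.
    """
    ids = sorted(set(gene_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 genes to sample pairs")
    rng = np.random.default_rng(seed)
    n_total = n_per_rep * n_reps
    a = rng.integers(0, len(ids), size=n_total)
    b = rng.integers(0, len(ids), size=n_total)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, len(ids), size=int(clash.sum()))
        clash = a == b
    pairs = [canonical_key(ids[i], ids[j]) for i, j in zip(a, b)]
    reps = list(np.repeat(np.arange(n_reps), n_per_rep))
    return PairSet(label="random-control", pairs=pairs, unique=False, replicate=reps)


# ---------------------------------------------------------------------------
# TSS distance binning
# ---------------------------------------------------------------------------

def bin_tss_distances(
    pairs: Iterable[H2HPair], edges: Sequence[int] = (0, 100, 200, 400, 1000)
) -> pd.DataFrame:
    """Histogram signed TSS distances into left-open right-closed intervals.

    Non-overlapping pairs (distance > 0) fall into ``(lo, hi]`` bins built
    from ``edges``; overlapping pairs (distance <= 0) are counted in a
    separate ``overlapping`` category, and distances beyond the last edge
    in an overflow category, so that counts always sum to the number of
    pairs.  Percentages are relative to the total pair count.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("edges must be non-empty")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    dists = [p.tss_distance for p in pairs]
    total = len(dists)
    labels = ["overlapping"]
    if edges[0] > 0:
        labels.append(f"(0, {edges[0]}]")
    labels += [f"({lo}, {hi}]" for lo, hi in zip(edges, edges[1:])]
    labels += [f">{edges[-1]}"]
    counts = dict.fromkeys(labels, 0)
    for d in dists:
        if d <= 0:
            counts["overlapping"] += 1
        elif d <= edges[0]:
            counts[f"(0, {edges[0]}]"] += 1
        elif d > edges[-1]:
            counts[f">{edges[-1]}"] += 1
        else:
            for lo, hi in zip(edges, edges[1:]):
                if lo < d <= hi:
                    counts[f"({lo}, {hi}]"] += 1
                    break
    df = pd.DataFrame(
        {
            "bin": labels,
            "count": [counts[b] for b in labels],
        }
    )
    df["percent"] = 100.0 * df["count"] / total if total else 0.0
    return df
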