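"""Gene and GC environment of LTRs within +/-50 kb.

Distances are measured edge-to-edge from the LTR limits; a gene overlapping
the LTR has distance 0 and makes the LTR intronic.  Upstream/downstream is
defined in the LTR's transcription orientation (mirrored on the minus
strand), and a neighbor's orientation is *sense* when gene and LTR share a
strand.  Cumulative gene-occurrence curves over intergenic LTR groups
resolve, per direction and orientation, how quickly cellular genes appear
away from the LTR -- the representation in which promoter LTRs show a
sense-gene-free zone immediately upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 50_000
DEFAULT_CURVE_MAX = 25_000
DEFAULT_CURVE_STEP = 100

GENE_COLUMNS = ["gene_id", "chrom", "tx_start", "tx_end", "strand"]


@dataclass(frozen=True)
class Neighbor:
    gene_id: str
    distance: int  # signed edge gap; negative = upstream of the LTR
    orientation: str  # sense | antisense
    overlaps: bool


@dataclass
class LtrContext:
    locus_id: str
    neighbors: list[Neighbor]
    gc_fraction: float | None
    placement: str  # intronic_sense | intronic_antisense | intergenic
    ambiguous_placement: bool = False

    @property
    def is_intergenic(self) -> bool:
        return self.placement == "intergenic"


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table lacks columns: {missing}")
    if (genes["tx_start"] >= genes["tx_end"]).any():
        raise ValueError("gene with tx_start >= tx_end")
    return genes


def find_neighbor_genes(
    ltr, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> list[Neighbor]:
    """Genes whose span lies within ``window`` bp of the LTR span.

    The distance is the nearest-edge gap (0 for overlap), negative when the
    gene sits upstream of the LTR in the LTR-strand orientation.
    """
    genes = _validate_genes(genes)
    sub = genes[genes["chrom"] == ltr.chrom]
    starts = sub["tx_start"].to_numpy()
    ends = sub["tx_end"].to_numpy()
    gap_left = ltr.start - ends  # positive when the gene is left of the LTR
    gap_right = starts - ltr.end
    gap = np.maximum(np.maximum(gap_left, gap_right), 0)
    keep = gap <= window
    neighbors = []
    for idx in np.nonzero(keep)[0]:
        row = sub.iloc[idx]
        overlaps = gap_left[idx] < 0 and gap_right[idx] < 0
        if overlaps:
            distance = 0
        else:
            left_of_ltr = gap_left[idx] > gap_right[idx]
            magnitude = int(gap[idx])
            upstream = left_of_ltr if ltr.strand == "+" else not left_of_ltr
            distance = -magnitude if upstream else magnitude
        orientation = "sense" if row["strand"] == ltr.strand else "antisense"
        neighbors.append(
            Neighbor(
                gene_id=str(row["gene_id"]),
                distance=distance,
                orientation=orientation,
                overlaps=bool(overlaps),
            )
        )
    return neighbors


def classify_placement(ltr, genes: pd.DataFrame) -> tuple[str, bool]:
    """Intronic (sense/antisense) vs intergenic placement of an LTR.

    Intronic iff the LTR span overlaps any gene span; with overlapping
    genes on both strands the larger overlap wins and an exact tie is
    flagged ambiguous (resolved to sense for determinism).
    """
    genes = _validate_genes(genes)
    sub = genes[genes["chrom"] == ltr.chrom]
    overlaps = []
    for _, row in sub.iterrows():
        lo = max(ltr.start, int(row["tx_start"]))
        hi = min(ltr.end, int(row["tx_end"]))
        if lo < hi:
            overlaps.append((hi - lo, row["strand"]))
    if not overlaps:
        return "intergenic", False
    best = max(o for o, _ in overlaps)
    winners = {strand for o, strand in overlaps if o == best}
    ambiguous = len(winners) > 1
    strand = ltr.strand if ltr.strand in winners else next(iter(winners))
    sense = strand == ltr.strand
    return ("intronic_sense" if sense else "intronic_antisense"), ambiguous


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); Ns are excluded from the denominator."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def build_context(
    ltr,
    genes: pd.DataFrame,
    genome: Mapping[str, str] | None = None,
    window: int = DEFAULT_WINDOW,
    include_ltr_in_gc: bool = False,
) -> LtrContext:
    """Assemble the full +/-window context of one LTR.

    %GC is computed over the flanking window, excluding the LTR span itself
    unless ``include_ltr_in_gc``.
    """
    neighbors = find_neighbor_genes(ltr, genes, window)
    placement, ambiguous = classify_placement(ltr, genes)
    gc = None
    if genome is not None:
        chrom_seq = genome[ltr.chrom]
        lo = max(0, ltr.start - window)
        hi = min(len(chrom_seq), ltr.end + window)
        if include_ltr_in_gc:
            seq = chrom_seq[lo:hi]
        else:
            seq = chrom_seq[lo : ltr.start] + chrom_seq[ltr.end : hi]
        gc = gc_content(seq)
    return LtrContext(
        locus_id=ltr.locus_id,
        neighbors=neighbors,
        gc_fraction=gc,
        placement=placement,
        ambiguous_placement=ambiguous,
    )


def gene_density_ratio(ltr_group: Sequence[LtrContext]) -> float:
    """Total neighboring genes normalized by the number of LTRs."""
    if not ltr_group:
        raise ValueError("empty LTR group")
    return sum(len(ctx.neighbors) for ctx in ltr_group) / len(ltr_group)


def cumulative_gene_occurrence(
    ltr_group: Sequence[LtrContext],
    direction: str,
    orientation: str | None,
    max_distance: int = DEFAULT_CURVE_MAX,
    step: int = DEFAULT_CURVE_STEP,
) -> pd.DataFrame:
    """Cumulative neighbor-gene count vs distance for an intergenic group.

    For each grid distance d, counts the (LTR, gene) neighbor pairs on the
    requested side (upstream: negative distances, downstream: positive)
    with the requested relative orientation (None = both) and |distance|
    <= d, accumulated over the whole group.  Monotone non-decreasing in d.
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError("direction must be 'upstream' or 'downstream'")
    if orientation not in ("sense", "antisense", None):
        raise ValueError("orientation must be 'sense', 'antisense' or None")
    distances = []
    for ctx in ltr_group:
        if not ctx.is_intergenic:
            raise ValueError(f"LTR {ctx.locus_id} is not intergenic")
        for nb in ctx.neighbors:
            if nb.overlaps:
                continue
            on_side = nb.distance < 0 if direction == "upstream" else nb.distance > 0
            if not on_side:
                continue
            if orientation is not None and nb.orientation != orientation:
                continue
            distances.append(abs(nb.distance))
    distances = np.sort(np.asarray(distances))
    grid = np.arange(0, max_distance + 1, step)
    counts = np.searchsorted(distances, grid, side="right")
    return pd.DataFrame({"distance": grid, "count": counts})


def contexts_to_table(contexts: Iterable[LtrContext]) -> pd.DataFrame:
    rows = []
    for ctx in contexts:
        rows.append(
            {
                "locus_id": ctx.locus_id,
                "n_neighbors": len(ctx.neighbors),
                "gc_fraction": ctx.gc_fraction,
                "placement": ctx.placement,
                "ambiguous_placement": ctx.ambiguous_placement,
                "neighbors": ";".join(
                    f"{n.gene_id}:{n.distance}:{n.orientation}" for n in ctx.neighbors
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "n_neighbors",
            "gc_fraction",
            "placement",
            "ambiguous_placement",
            "neighbors",
        ],
    )
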