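"""Annotated database of repeated-element (HERV) loci.

A HERV family is described by a *prototype* sequence whose functional parts
(U3/R/U5 for the LTR, gag/ppol/pol/env for the internal region) are labelled.
Genome-wide masking against the prototypes yields per-part hits; hits on the
same strand belonging to the same family are assembled into loci (elements)
whose structure is then classified as a solo LTR, a complete provirus
(two LTR blocks flanking internal parts) or a partial provirus.

Coordinates are 0-based half-open internally.  The hit-table reader is the
only place where the RepeatMasker-style 1-based inclusive convention (and its
``C`` complement-strand symbol) appears.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

LTR_PART_NAMES = ("U3", "R", "U5")
INTERNAL_PART_NAMES = ("gag", "ppol", "pol", "env")
KNOWN_PART_NAMES = LTR_PART_NAMES + INTERNAL_PART_NAMES

#: canonical structure labels
SOLO_LTR = "solo_LTR"
COMPLETE_PROVIRUS = "complete_provirus"
PARTIAL_PROVIRUS = "partial_provirus"

HIT_TABLE_COLUMNS = [
    "score",
    "divergence",
    "chrom",
    "begin",
    "end",
    "strand",
    "family_id",
    "part_name",
]


@dataclass(frozen=True)
class Prototype:
    """Reference sequence of a repeat family with labelled functional parts.

    ``parts`` holds ``(part_name, start, end)`` triples in prototype
    coordinates (0-based half-open).  LTR subparts must appear in U3 < R < U5
    order within each contiguous LTR block.
    """

    family_id: str
    sequence: str
    parts: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, start, end in self.parts:
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"part {name} [{start},{end}) outside prototype of length {n}"
                )
            if name not in KNOWN_PART_NAMES:
                raise ValueError(f"unknown part name {name!r}")
        ltr = sorted(
            (start, name) for name, start, _ in self.parts if name in LTR_PART_NAMES
        )
        # each LTR block must run U3 < R < U5; a new block may only open at U3
        prev_idx = None
        for _, name in ltr:
            idx = LTR_PART_NAMES.index(name)
            if prev_idx is not None and idx <= prev_idx and idx != 0:
                raise ValueError("LTR subparts must be ordered U3 < R < U5")
            prev_idx = idx

    def part_sequence(self, part_name: str) -> str:
        for name, start, end in self.parts:
            if name == part_name:
                return self.sequence[start:end]
        raise KeyError(part_name)


@dataclass(frozen=True)
class RepeatHit:
    """A single masking hit of one functional part on the genome."""

    chrom: str
    start: int
    end: int
    strand: str
    family_id: str
    part_name: str
    divergence: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit with start >= end: {self.start} >= {self.end}")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class DbConfig:
    """Database construction parameters.

    ``max_divergence`` (percent) drops hits too diverged from the family
    prototype; the published threshold is 20%.  ``max_intra_element_gap`` is
    the largest genomic gap (bp) bridged when assembling same-family,
    same-strand hits into one locus.
    """

    max_divergence: float = 20.0
    max_intra_element_gap: int = 1000
    genome_build_label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.max_divergence <= 100:
            raise ValueError("max_divergence must be in (0, 100]")


@dataclass
class ParseReport:
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_divergence: int = 0
    n_skipped_unknown_part: int = 0


@dataclass(frozen=True)
class LtrBlock:
    """One contiguous LTR (U3/R/U5 run) within an element."""

    role: str  # 5prime | 3prime | solo | ambiguous
    start: int
    end: int
    part_names: tuple[str, ...]

    @property
    def is_complete(self) -> bool:
        return set(self.part_names) >= set(LTR_PART_NAMES)


@dataclass(frozen=True)
class HervElement:
    """An assembled genomic repeat locus.

    ``parts`` are ``(part_name, start, end)`` in genome order; ``ltr_blocks``
    carries the strand-aware 5prime/3prime/solo role of each LTR block.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    structure: str
    parts: tuple[tuple[str, int, int], ...]
    family_id: str
    ltr_blocks: tuple[LtrBlock, ...] = ()
    ambiguous: bool = False

    @property
    def ltr_roles(self) -> tuple[str, ...]:
        return tuple(block.role for block in self.ltr_blocks)


def parse_repeat_hits(
    source: str | Path | io.TextIOBase, config: DbConfig
) -> tuple[list[RepeatHit], ParseReport]:
    """Read a RepeatMasker-style hit table.

    Expected tab-delimited columns (with header): score, divergence, chrom,
    begin (1-based), end (inclusive), strand (+/C), family_id, part_name.
    Hits with divergence above ``config.max_divergence`` are dropped and
    counted; rows naming an unknown functional part are skipped and counted.
    Malformed rows raise :class:`ValueError` naming the offending line.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            lines = handle.read().splitlines()
    else:
        lines = source.read().splitlines()
    report = ParseReport()
    hits: list[RepeatHit] = []
    if not lines:
        return hits, report
    header = lines[0].rstrip("\n").split("\t")
    if header != HIT_TABLE_COLUMNS:
        raise ValueError(
            f"line 1: expected header {HIT_TABLE_COLUMNS}, got {header}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(HIT_TABLE_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(HIT_TABLE_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        report.n_rows += 1
        row = dict(zip(HIT_TABLE_COLUMNS, fields))
        if row["part_name"] not in KNOWN_PART_NAMES:
            report.n_skipped_unknown_part += 1
            continue
        try:
            divergence = float(row["divergence"])
            begin = int(row["begin"])
            end = int(row["end"])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        if row["strand"] == "+":
            strand = "+"
        elif row["strand"] in ("C", "-"):
            strand = "-"
        else:
            raise ValueError(f"line {lineno}: bad strand {row['strand']!r}")
        if end < begin:
            raise ValueError(f"line {lineno}: end < begin ({end} < {begin})")
        if divergence > config.max_divergence:
            report.n_dropped_divergence += 1
            continue
        hits.append(
            RepeatHit(
                chrom=row["chrom"],
                start=begin - 1,
                end=end,
                strand=strand,
                family_id=row["family_id"],
                part_name=row["part_name"],
                divergence=divergence,
            )
        )
        report.n_kept += 1
    return hits, report


def assemble_elements(
    hits: Sequence[RepeatHit], config: DbConfig
) -> list[HervElement]:
    """Merge same-family, same-strand hits into annotated elements.

    Successive hits (genome order, per chromosome/strand/family) whose gap is
    at most ``config.max_intra_element_gap`` join the same element
    (single-linkage).  The locus id is ``{family}_{chrom}_{start}`` and is
    therefore deterministic.
    """
    groups: dict[tuple[str, str, str], list[RepeatHit]] = {}
    for hit in hits:
        groups.setdefault((hit.chrom, hit.strand, hit.family_id), []).append(hit)
    elements: list[HervElement] = []
    for (chrom, strand, family), members in groups.items():
        members = sorted(members, key=lambda h: (h.start, h.end))
        cluster: list[RepeatHit] = []
        cluster_end = None
        for hit in members:
            if cluster and hit.start - cluster_end > config.max_intra_element_gap:
                elements.append(_build_element(chrom, strand, family, cluster))
                cluster = []
                cluster_end = None
            cluster.append(hit)
            cluster_end = hit.end if cluster_end is None else max(cluster_end, hit.end)
        if cluster:
            elements.append(_build_element(chrom, strand, family, cluster))
    elements.sort(key=lambda e: (e.chrom, e.start, e.family_id))
    return elements


def _build_element(
    chrom: str, strand: str, family: str, cluster: list[RepeatHit]
) -> HervElement:
    parts = tuple(sorted((h.part_name, h.start, h.end) for h in cluster))
    start = min(p[1] for p in parts)
    end = max(p[2] for p in parts)
    element = HervElement(
        locus_id=f"{family}_{chrom}_{start}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        structure=PARTIAL_PROVIRUS,  # placeholder, replaced below
        parts=parts,
        family_id=family,
    )
    return classify_structure(element)


def classify_structure(element: HervElement) -> HervElement:
    """Classify an element's structure and tag its LTR blocks.

    solo_LTR iff only LTR subparts are present; complete_provirus iff two LTR
    blocks flank at least one internal part; anything else is a
    partial_provirus.  Roles follow transcription orientation: on the minus
    strand the genomic order of 5prime/3prime is mirrored.  An LTR block
    surrounded by internal parts on both sides is flagged ambiguous.
    """
    if not element.parts:
        raise ValueError("element has no parts")
    parts = sorted(element.parts, key=lambda p: (p[1], p[2]))
    # group consecutive LTR subparts into blocks, in genome order
    blocks_raw: list[list[tuple[str, int, int]]] = []
    internal_spans: list[tuple[int, int]] = []
    for name, start, end in parts:
        if name in LTR_PART_NAMES:
            if blocks_raw and blocks_raw[-1] and _continues_block(
                blocks_raw[-1][-1][0], name, element.strand
            ):
                blocks_raw[-1].append((name, start, end))
            else:
                blocks_raw.append([(name, start, end)])
        else:
            internal_spans.append((start, end))

    has_internal = bool(internal_spans)
    n_blocks = len(blocks_raw)

    roles: list[str] = []
    ambiguous = False
    if not has_internal:
        structure = SOLO_LTR
        roles = ["solo"] * n_blocks
    else:
        first_internal = min(s for s, _ in internal_spans)
        last_internal = max(e for _, e in internal_spans)
        flank_left = [b for b in blocks_raw if b[-1][2] <= first_internal]
        flank_right = [b for b in blocks_raw if b[0][1] >= last_internal]
        if n_blocks >= 2 and flank_left and flank_right:
            structure = COMPLETE_PROVIRUS
        else:
            structure = PARTIAL_PROVIRUS
        for block in blocks_raw:
            b_start, b_end = block[0][1], block[-1][2]
            left_of_internal = b_end <= first_internal
            right_of_internal = b_start >= last_internal
            if left_of_internal and not right_of_internal:
                roles.append("5prime" if element.strand == "+" else "3prime")
            elif right_of_internal and not left_of_internal:
                roles.append("3prime" if element.strand == "+" else "5prime")
            else:
                # flanked by internal parts on both sides: not resolvable
                roles.append("ambiguous")
                ambiguous = True

    ltr_blocks = tuple(
        LtrBlock(
            role=role,
            start=block[0][1],
            end=block[-1][2],
            part_names=tuple(name for name, _, _ in block),
        )
        for role, block in zip(roles, blocks_raw)
    )
    return replace(
        element, structure=structure, ltr_blocks=ltr_blocks, ambiguous=ambiguous
    )


def _continues_block(prev_part: str, part: str, strand: str) -> bool:
    """Whether ``part`` extends the current LTR run in genome order."""
    order = list(LTR_PART_NAMES) if strand == "+" else list(reversed(LTR_PART_NAMES))
    try:
        return order.index(part) == order.index(prev_part) + 1
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# tabular output


def elements_to_table(elements: Iterable[HervElement]) -> pd.DataFrame:
    rows = []
    for e in elements:
        rows.append(
            {
                "locus_id": e.locus_id,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "family_id": e.family_id,
                "structure": e.structure,
                "ltr_roles": ",".join(e.ltr_roles),
                "ambiguous": e.ambiguous,
                "parts": ";".join(f"{n}:{s}-{t}" for n, s, t in e.parts),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "chrom",
            "start",
            "end",
            "strand",
            "family_id",
            "structure",
            "ltr_roles",
            "ambiguous",
            "parts",
        ],
    )


def elements_from_table(table: pd.DataFrame) -> list[HervElement]:
    """Inverse of :func:`elements_to_table` (structure is re-derived)."""
    elements = []
    for _, row in table.iterrows():
        parts = tuple(
            (chunk.split(":")[0],) + tuple(map(int, chunk.split(":")[1].split("-")))
            for chunk in str(row["parts"]).split(";")
            if chunk
        )
        element = HervElement(
            locus_id=row["locus_id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            structure=row["structure"],
            parts=parts,
            family_id=row["family_id"],
        )
        elements.append(classify_structure(element))
    return elements


def elements_to_bed(elements: Iterable[HervElement]) -> pd.DataFrame:
    """BED6 view of the element table (score column fixed at 0)."""
    rows = [
        (e.chrom, e.start, e.end, e.locus_id, 0, e.strand) for e in elements
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
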