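"""Repeat-aware 25-mer probe design with cross-hybridization control.

Discriminating individual loci of a repeated-element family requires probes
that hybridize at their source locus and nowhere else in the genome.  The
design proceeds in four steps:

1. enumerate every overlapping 25-mer of each functional part;
2. locate all genomic windows (both strands) within a mismatch budget of a
   candidate probe (pigeonhole seed-and-extend, equivalent to a brute-force
   sliding scan);
3. score each off-source alignment with the EDA+ mismatch-penalty model and
   keep only probes whose every off-source site is an improbable hybridizer;
4. assemble at most 10 surviving probes per (locus, part) into a probeset
   with a homogeneous spacing along the part.

The EDA+ model is purely mismatch-based: the penalty of an alignment is the
sum of per-mismatch contributions, where each contribution is a base penalty
for the mismatch type (transition or transversion) scaled by a symmetric
position weight that peaks at the probe center, and where the smaller member
of any two mismatches closer than a proximity span is damped by a factor
lambda <= 1 (clustered mismatches disrupt one shared helix region, so their
effects are sub-additive).  No thermodynamic (nearest-neighbor) term enters
the model.  A hybridization is *probable* when the cumulative penalty stays
below the pass threshold theta.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

PROBE_LENGTH = 25

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A,C,G,T,N -> 0..4)."""
    table = np.full(256, 4, dtype=np.uint8)
    for base, code in _ENCODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class CandidateProbe:
    """A 25-mer candidate with its source location on the genome."""

    sequence: str
    locus_id: str
    part_name: str
    offset: int
    source_chrom: str | None = None
    source_start: int | None = None
    source_strand: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError("probe must be exactly 25 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("probe alphabet is {A,C,G,T}")


def mismatch_class(probe_base: str, target_base: str) -> str:
    return "transition" if (probe_base, target_base) in TRANSITIONS else "transversion"


@dataclass(frozen=True)
class MismatchEvent:
    """One substitution in a probe/target alignment.

    ``position`` counts 1..25 from the 5' end of the probe.
    """

    position: int
    probe_base: str
    target_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= PROBE_LENGTH:
            raise ValueError("mismatch position must lie in 1..25")
        if self.probe_base == self.target_base:
            raise ValueError("probe and target base must differ in a mismatch")

    @property
    def mismatch_class(self) -> str:
        return mismatch_class(self.probe_base, self.target_base)


def default_position_weight(position: int) -> float:
    """Symmetric weight, minimal at the probe ends and maximal at the center.

    w(p) = 0.5 + sin(pi (p - 0.5) / 25) / 2, so w(13) = 1 and w(1) = w(25).
    """
    return 0.5 + math.sin(math.pi * (position - 0.5) / PROBE_LENGTH) / 2.0


@dataclass
class EdaParams:
    """EDA+ scoring weights.

    The committed defaults are the tested contract of this package:
    transversions weigh 1.4 vs 1.0 for transitions, the position weight is
    center-maximal, two mismatches closer than ``proximity_span`` bases have
    the smaller contribution multiplied by ``interval_factor``, and an
    alignment is a probable hybridizer below ``pass_threshold``.
    """

    base_penalty: dict[str, float] = field(
        default_factory=lambda: {"transition": 1.0, "transversion": 1.4}
    )
    position_weight: Callable[[int], float] = default_position_weight
    interval_factor: float = 0.6
    proximity_span: int = 6
    pass_threshold: float = 3.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.base_penalty.values()):
            raise ValueError("base penalties must be positive")
        if not 0 < self.interval_factor <= 1:
            raise ValueError("interval_factor must lie in (0, 1]")
        if self.pass_threshold <= 0:
            raise ValueError("pass_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EdaParams":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in ("base_penalty", "interval_factor", "proximity_span", "pass_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass(frozen=True)
class HybridizationVerdict:
    penalty: float
    probable: bool


def eda_score(
    probe: CandidateProbe | None,
    mismatches: Sequence[MismatchEvent],
    params: EdaParams,
) -> HybridizationVerdict:
    """Cumulative EDA+ penalty of an alignment and its probable/improbable call.

    A perfect match scores 0 and is always probable.  Contributions are
    compared undamped when applying the interval rule; when two adjacent
    mismatches tie, the 5'-most one is damped.  With interval_factor >= 0.5
    the penalty is non-decreasing in the mismatch multiset.
    """
    positions = [m.position for m in mismatches]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate mismatch positions")
    events = sorted(mismatches, key=lambda m: m.position)
    raw = [
        params.base_penalty[m.mismatch_class] * params.position_weight(m.position)
        for m in events
    ]
    multiplier = [1.0] * len(events)
    for i in range(len(events) - 1):
        if events[i + 1].position - events[i].position < params.proximity_span:
            j = i if raw[i] <= raw[i + 1] else i + 1
            multiplier[j] *= params.interval_factor
    penalty = float(sum(r * m for r, m in zip(raw, multiplier)))
    return HybridizationVerdict(penalty=penalty, probable=penalty < params.pass_threshold)


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_candidates(
    part_sequence: str, locus_id: str, part_name: str
) -> tuple[list[CandidateProbe], int]:
    """All overlapping 25-mers of a part; windows containing N are excluded.

    Returns the candidate list and the number of N-containing windows that
    were skipped.
    """
    seq = part_sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("part sequence alphabet is {A,C,G,T,N}")
    candidates: list[CandidateProbe] = []
    skipped = 0
    for offset in range(max(0, len(seq) - PROBE_LENGTH + 1)):
        window = seq[offset : offset + PROBE_LENGTH]
        if "N" in window:
            skipped += 1
            continue
        candidates.append(
            CandidateProbe(
                sequence=window,
                locus_id=locus_id,
                part_name=part_name,
                offset=offset,
            )
        )
    return candidates, skipped


def candidates_for_part(
    genome: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    locus_id: str,
    part_name: str,
) -> tuple[list[CandidateProbe], int]:
    """Enumerate candidates for a genomic part, attaching source coordinates.

    The part sequence is read in transcription orientation (reverse
    complement on the minus strand); the recorded source is the forward-strand
    window the probe matches perfectly.
    """
    seq = genome[chrom][start:end].upper()
    if strand == "-":
        seq = revcomp(seq)
    raw, skipped = enumerate_candidates(seq, locus_id, part_name)
    placed = []
    span = end - start
    for cand in raw:
        if strand == "+":
            genome_start = start + cand.offset
        else:
            genome_start = start + span - cand.offset - PROBE_LENGTH
        placed.append(
            CandidateProbe(
                sequence=cand.sequence,
                locus_id=locus_id,
                part_name=part_name,
                offset=cand.offset,
                source_chrom=chrom,
                source_start=genome_start,
                source_strand=strand,
            )
        )
    return placed, skipped


# ---------------------------------------------------------------------------
# genome screening


@dataclass(frozen=True)
class CrossHybSite:
    chrom: str
    start: int
    strand: str
    mismatches: tuple[MismatchEvent, ...]


class GenomeIndex:
    """Exact k-mer index over a genome for pigeonhole seed lookups.

    Chromosome sequences are kept encoded (A,C,G,T,N -> 0..4); per seed
    length a sorted k-mer code table is built lazily and cached.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.encoded = {c: _encode(s) for c, s in self.sequences.items()}
        self._kmer_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def _kmer_table(self, chrom: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        key = (chrom, k)
        if key not in self._kmer_cache:
            enc = self.encoded[chrom].astype(np.int64)
            n = len(enc) - k + 1
            if n <= 0:
                codes = np.empty(0, dtype=np.int64)
                order = np.empty(0, dtype=np.int64)
            else:
                codes = np.zeros(n, dtype=np.int64)
                valid = np.ones(n, dtype=bool)
                for j in range(k):
                    col = enc[j : j + n]
                    codes = codes * 4 + np.where(col == 4, 0, col)
                    valid &= col != 4
                positions = np.nonzero(valid)[0]
                codes = codes[positions]
                order = np.argsort(codes, kind="stable")
                codes, order = codes[order], positions[order]
            self._kmer_cache[key] = (codes, order)
        return self._kmer_cache[key]

    def seed_positions(self, chrom: str, seed: str) -> np.ndarray:
        """Positions of exact occurrences of ``seed`` on the forward strand."""
        k = len(seed)
        codes, positions = self._kmer_table(chrom, k)
        code = 0
        for base in seed:
            code = code * 4 + _ENCODE[base]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return positions[lo:hi]


def _seed_chunks(sequence: str, n_chunks: int) -> list[tuple[int, str]]:
    """Split a probe into ``n_chunks`` near-equal exact seeds (offset, seq)."""
    base = len(sequence) // n_chunks
    rem = len(sequence) % n_chunks
    chunks = []
    pos = 0
    for i in range(n_chunks):
        size = base + (1 if i < rem else 0)
        chunks.append((pos, sequence[pos : pos + size]))
        pos += size
    return chunks


def find_cross_hyb_sites(
    probe: CandidateProbe | str,
    genome: GenomeIndex | Mapping[str, str],
    max_mismatches: int,
) -> list[CrossHybSite]:
    """Every genomic 25-mer window within ``max_mismatches`` substitutions.

    Both strands are screened; a site on the minus strand is reported by the
    forward-strand coordinates of the window whose reverse complement aligns
    with the probe.  Windows containing N are skipped.  The result is
    identical to a brute-force sliding scan (pigeonhole guarantee: with the
    probe split into ``max_mismatches + 1`` exact seeds, any window within
    the budget matches at least one seed exactly).
    """
    seq = probe.sequence if isinstance(probe, CandidateProbe) else probe.upper()
    if len(seq) != PROBE_LENGTH:
        raise ValueError("probe must be 25 nt")
    if "N" in seq:
        raise ValueError("probe contains N")
    if max_mismatches > 6:
        raise ValueError("max_mismatches must be <= 6")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    probe_enc = _encode(seq)
    sites: list[CrossHybSite] = []
    for strand in ("+", "-"):
        query = seq if strand == "+" else revcomp(seq)
        query_enc = _encode(query)
        for chrom, enc in index.encoded.items():
            n = len(enc)
            if n < PROBE_LENGTH:
                continue
            starts: set[int] = set()
            for offset, chunk in _seed_chunks(query, max_mismatches + 1):
                for pos in index.seed_positions(chrom, chunk):
                    start = int(pos) - offset
                    if 0 <= start <= n - PROBE_LENGTH:
                        starts.add(start)
            for start in sorted(starts):
                window = enc[start : start + PROBE_LENGTH]
                if (window == 4).any():
                    continue
                diff = np.nonzero(window != query_enc)[0]
                if len(diff) > max_mismatches:
                    continue
                if strand == "+":
                    events = tuple(
                        MismatchEvent(
                            position=int(i) + 1,
                            probe_base=seq[int(i)],
                            target_base=_DECODE[int(window[int(i)])],
                        )
                        for i in diff
                    )
                else:
                    # probe position p aligns with window index 25 - p
                    events = tuple(
                        sorted(
                            (
                                MismatchEvent(
                                    position=PROBE_LENGTH - int(i),
                                    probe_base=seq[PROBE_LENGTH - int(i) - 1],
                                    target_base=_DECODE[3 - int(window[int(i)])],
                                )
                                for i in diff
                            ),
                            key=lambda m: m.position,
                        )
                    )
                sites.append(
                    CrossHybSite(chrom=chrom, start=start, strand=strand, mismatches=events)
                )
    return sites


# ---------------------------------------------------------------------------
# specificity screening and probeset assembly


def select_specific_probes(
    candidates: Sequence[CandidateProbe],
    genome: GenomeIndex | Mapping[str, str],
    params: EdaParams,
    max_mismatches: int = 6,
) -> tuple[list[CandidateProbe], dict[str, dict]]:
    """Keep candidates whose only probable hybridization site is their source.

    Every off-source window within the mismatch budget is scored with EDA+;
    a single probable off-source site rejects the probe.  Returns the kept
    probes and a per-probe report of rejection reasons.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    kept: list[CandidateProbe] = []
    report: dict[str, dict] = {}
    for cand in candidates:
        if cand.source_chrom is None or cand.source_start is None:
            raise ValueError("candidate source location is unknown")
        key = f"{cand.locus_id}|{cand.part_name}|{cand.offset}"
        sites = find_cross_hyb_sites(cand, index, max_mismatches)
        offenders = []
        for site in sites:
            is_source = (
                site.chrom == cand.source_chrom
                and site.start == cand.source_start
                and site.strand == cand.source_strand
            )
            if is_source:
                continue
            verdict = eda_score(cand, site.mismatches, params)
            if verdict.probable:
                offenders.append(
                    {
                        "chrom": site.chrom,
                        "start": site.start,
                        "strand": site.strand,
                        "n_mismatches": len(site.mismatches),
                        "penalty": verdict.penalty,
                    }
                )
        if offenders:
            report[key] = {"kept": False, "reason": "cross_hybridizing", "sites": offenders}
        else:
            report[key] = {"kept": True}
            kept.append(cand)
    return kept, report


@dataclass(frozen=True)
class Probeset:
    """Up to 10 specificity-screened probes covering one functional part."""

    locus_id: str
    part_name: str
    probes: tuple[CandidateProbe, ...]
    ltr_role: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.probes) <= 10:
            raise ValueError("a probeset holds 1..10 probes")

    @property
    def probeset_id(self) -> str:
        role = f"@{self.ltr_role}" if self.ltr_role else ""
        return f"{self.locus_id}|{self.part_name}{role}"


def assemble_probeset(
    specific_probes: Sequence[CandidateProbe],
    part_length: int,
    ltr_role: str | None = None,
) -> Probeset | None:
    """Select probes with a homogeneous spread along the functional part.

    With at most 10 probes all are kept.  Otherwise the 10 offsets minimizing
    the sum of squared deviations from the ideal equidistant grid over
    [0, part_length - 25] are chosen (sorted offsets matched to sorted grid
    points; dynamic program over the order-preserving assignments, which
    contains the optimum).  Ties break toward smaller offsets.  An empty
    input yields no probeset.
    """
    if not specific_probes:
        return None
    probes = sorted(specific_probes, key=lambda p: p.offset)
    meta = probes[0]
    if len(probes) <= 10:
        return Probeset(
            locus_id=meta.locus_id,
            part_name=meta.part_name,
            probes=tuple(probes),
            ltr_role=ltr_role,
        )
    offsets = [p.offset for p in probes]
    span = max(part_length - PROBE_LENGTH, 0)
    targets = [i * span / 9.0 for i in range(10)]
    chosen = _grid_select(offsets, targets)
    selected = [probes[i] for i in chosen]
    return Probeset(
        locus_id=meta.locus_id,
        part_name=meta.part_name,
        probes=tuple(selected),
        ltr_role=ltr_role,
    )


def _grid_select(offsets: Sequence[int], targets: Sequence[float]) -> list[int]:
    """Indices of the offsets minimizing sum((offset_i - target_i)^2).

    Offsets are sorted; the optimal subset assigns its sorted members to the
    sorted targets, so a DP over (candidate, slot) with lexicographic
    tie-breaking on the offset tuple is exact and deterministic.
    """
    n, k = len(offsets), len(targets)
    INF = float("inf")
    # best[j] = (cost, offsets-tuple, indices) using first i candidates, j slots filled
    best: list[tuple[float, tuple, tuple]] = [(INF, (), ())] * (k + 1)
    best[0] = (0.0, (), ())
    for i in range(n):
        for j in range(min(i, k - 1), -1, -1):
            cost, offs, idxs = best[j]
            if cost == INF:
                continue
            new_cost = cost + (offsets[i] - targets[j]) ** 2
            cand = (new_cost, offs + (offsets[i],), idxs + (i,))
            if (cand[0], cand[1]) < (best[j + 1][0], best[j + 1][1]):
                best[j + 1] = cand
    return list(best[k][2])


# ---------------------------------------------------------------------------
# whole-element design driver


@dataclass
class DesignReport:
    n_candidates: int = 0
    n_skipped_n_windows: int = 0
    n_specific: int = 0
    probesets: int = 0
    parts_without_probeset: list[str] = field(default_factory=list)
    probe_reports: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_candidates": self.n_candidates,
                "n_skipped_n_windows": self.n_skipped_n_windows,
                "n_specific": self.n_specific,
                "probesets": self.probesets,
                "parts_without_probeset": self.parts_without_probeset,
            },
            indent=2,
        )


def design_for_elements(
    elements,
    genome: Mapping[str, str],
    params: EdaParams | None = None,
    max_mismatches: int = 6,
    parts: Iterable[str] | None = None,
) -> tuple[list[Probeset], DesignReport]:
    """Design probesets for every functional part of a list of elements.

    LTR subparts are designed per LTR block and carry the block role, so a
    complete provirus gets independent U3/U5 probesets for each LTR.  The
    design is deterministic: identical inputs and parameters reproduce
    byte-identical probe tables.
    """
    from .repeat_db import LTR_PART_NAMES

    params = params or EdaParams()
    index = GenomeIndex(genome)
    wanted = set(parts) if parts is not None else None
    report = DesignReport()
    probesets: list[Probeset] = []
    for element in elements:
        jobs: list[tuple[str, int, int, str | None]] = []
        for block in element.ltr_blocks:
            for name in block.part_names:
                span = [
                    (s, e)
                    for n, s, e in element.parts
                    if n == name and block.start <= s and e <= block.end
                ]
                for s, e in span:
                    jobs.append((name, s, e, block.role))
        for name, s, e in element.parts:
            if name not in LTR_PART_NAMES:
                jobs.append((name, s, e, None))
        for name, s, e, role in jobs:
            if wanted is not None and name not in wanted:
                continue
            cands, skipped = candidates_for_part(
                index.sequences,
                element.chrom,
                s,
                e,
                element.strand,
                element.locus_id,
                name,
            )
            report.n_candidates += len(cands)
            report.n_skipped_n_windows += skipped
            specific, probe_report = select_specific_probes(
                cands, index, params, max_mismatches
            )
            report.probe_reports.update(probe_report)
            report.n_specific += len(specific)
            probeset = assemble_probeset(specific, e - s, ltr_role=role)
            if probeset is None:
                report.parts_without_probeset.append(
                    f"{element.locus_id}|{name}" + (f"@{role}" if role else "")
                )
            else:
                probesets.append(probeset)
                report.probesets += 1
    return probesets, report


def probesets_to_table(probesets: Iterable[Probeset]) -> pd.DataFrame:
    rows = []
    for ps in probesets:
        for probe in ps.probes:
            rows.append(
                {
                    "probeset_id": ps.probeset_id,
                    "locus_id": ps.locus_id,
                    "part_name": ps.part_name,
                    "ltr_role": ps.ltr_role or "",
                    "offset": probe.offset,
                    "sequence": probe.sequence,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["probeset_id", "locus_id", "part_name", "ltr_role", "offset", "sequence"],
    )
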