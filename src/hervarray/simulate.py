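"""Seeded synthetic fixtures with machine-readable ground truth.

Every other module of the package is exercisable without downloads through
three generators:

* a genome with implanted, mutated copies of family prototypes at a
  controlled substitution divergence (substitutions only, matching the
  mismatch-only hybridization model);
* a gene annotation table at a controllable density, optionally enforcing a
  sense-gene-free 8 kb upstream zone around designated loci (the geometry
  observed around promoter LTRs);
* a probe-level intensity dataset following the batch model
  Y = mu + X beta + gamma_i + delta_i eps: true set-level locus expression
  times lognormal probe affinities, distorted per (operator, date) batch
  additively and multiplicatively on the log2 scale, on top of an optical
  background shared with the tryptophan control probes.  LTR-function truth
  is realized by drawing U3/U5 levels inside the classifier's unambiguous
  regions (clear of the [50, 100] grey zone).

All draws come from a single ``numpy.random.default_rng(seed)`` stream
consumed in a fixed order, so a fixed seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .probe_design import revcomp
from .repeat_db import Prototype
from .signal_processing import BatchDesign, ProbeSignalMatrix

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe a desk-scale analogue of the published design: a
    handful of solo-LTR loci per family implanted at 10% divergence (half
    the 20% retention cap), a tissue panel of matched normal/tumor pairs
    plus an unpaired placenta-like set, two operators with two
    amplification dates each, and moderate lognormal measurement noise.
    """

    seed: int = 0
    genome_length: int = 200_000
    chrom_name: str = "chr1"
    copies_per_family: Mapping[str, int] = field(default_factory=lambda: {"HVW": 12})
    target_divergence: float = 10.0
    min_implant_gap: int = 2_000
    gene_density: float = 5.0  # genes per 100 kb
    promoter_zone_rule: bool = False
    promoter_zone_bp: int = 8_000
    gene_length_range: tuple[int, int] = (2_000, 12_000)
    # signal dataset
    tissues: tuple[str, ...] = ("colon", "testis", "ovary")
    include_placenta: bool = True
    # four arrays per set spread over the full operator x date grid keeps the
    # covariate unconfounded with every batch factor
    arrays_per_set: int = 4
    operators: tuple[str, ...] = ("op1", "op2")
    dates_per_operator: int = 2
    batch_effects: Mapping[str, tuple[float, float]] | None = None
    batch_gamma_sd: float = 1.0
    batch_delta_range: tuple[float, float] = (0.8, 1.4)
    noise_sd: float = 0.15
    affinity_sd: float = 0.25
    background_mean: float = 40.0
    n_control_probes: int = 30
    # cellular-transcriptome filler: probesets with log-uniform levels shared
    # across sample sets.  They give each array the continuous intensity
    # spectrum of a dense chip, which rank-based normalization relies on.
    n_background_probesets: int = 150
    background_probes_per_set: int = 4
    background_level_log2_range: tuple[float, float] = (2.5, 10.0)
    silent_level_range: tuple[float, float] = (5.0, 35.0)
    active_level_range: tuple[float, float] = (250.0, 1000.0)
    function_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.30,
            "polyA": 0.25,
            "readthrough": 0.10,
            "silent": 0.35,
        }
    )


@dataclass
class ImplantTruth:
    locus_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    realized_divergence: float
    parts: list[tuple[str, int, int]]  # genome coordinates


@dataclass
class GroundTruth:
    implants: list[ImplantTruth] = field(default_factory=list)
    genes: pd.DataFrame | None = None
    designated_promoter_loci: list[str] = field(default_factory=list)
    functions: dict[str, str] = field(default_factory=dict)  # locus -> label
    active_sets: dict[str, list[str]] = field(default_factory=dict)
    expression: pd.DataFrame | None = None  # true set-level levels
    batch_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "implants": [
                {
                    "locus_id": t.locus_id,
                    "family_id": t.family_id,
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "strand": t.strand,
                    "realized_divergence": t.realized_divergence,
                    "parts": t.parts,
                }
                for t in self.implants
            ],
            "designated_promoter_loci": self.designated_promoter_loci,
            "functions": self.functions,
            "active_sets": self.active_sets,
            "batch_params": {k: list(v) for k, v in self.batch_params.items()},
        }
        if self.genes is not None:
            payload["genes"] = self.genes.to_dict(orient="records")
        if self.expression is not None:
            payload["expression"] = {
                "index": list(self.expression.index),
                "columns": list(self.expression.columns),
                "values": self.expression.to_numpy().tolist(),
            }
        return json.dumps(payload, indent=2)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def make_prototype(
    rng: np.random.Generator,
    family_id: str,
    ltr_lengths: tuple[int, int, int] = (260, 70, 250),
    internal_lengths: Mapping[str, int] | None = None,
) -> Prototype:
    """A random solo-LTR (or provirus) prototype with labelled parts."""
    parts: list[tuple[str, int, int]] = []
    pos = 0
    for name, length in zip(("U3", "R", "U5"), ltr_lengths):
        parts.append((name, pos, pos + length))
        pos += length
    if internal_lengths:
        for name, length in internal_lengths.items():
            parts.append((name, pos, pos + length))
            pos += length
    sequence = random_sequence(rng, pos)
    return Prototype(family_id=family_id, sequence=sequence, parts=tuple(parts))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> tuple[str, float]:
    """Substitute each base independently at ``rate``; returns realized rate."""
    arr = np.array(list(sequence))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), float(hit.sum() / len(arr))


def make_genome_and_repeats(
    config: SimConfig,
    prototypes: Sequence[Prototype] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Background genome with non-overlapping mutated prototype implants.

    The truth records each copy's coordinates, strand, per-part genome
    intervals and realized divergence.  Raises if the requested copies
    cannot be placed without overlap.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if prototypes is None:
        prototypes = [
            make_prototype(rng, family) for family in sorted(config.copies_per_family)
        ]
    protos = {p.family_id: p for p in prototypes}
    total_implant = sum(
        len(protos[f].sequence) * n for f, n in config.copies_per_family.items()
    )
    if total_implant > config.genome_length:
        raise ValueError("genome too short for the requested implants")
    genome = bytearray(random_sequence(rng, config.genome_length), "ascii")
    truth = GroundTruth()
    occupied: list[tuple[int, int]] = []
    for family in sorted(config.copies_per_family):
        proto = protos[family]
        length = len(proto.sequence)
        for _ in range(config.copies_per_family[family]):
            placed = False
            for _attempt in range(2000):
                start = int(rng.integers(0, config.genome_length - length + 1))
                end = start + length
                if all(
                    end + config.min_implant_gap <= s or start >= e + config.min_implant_gap
                    for s, e in occupied
                ):
                    placed = True
                    break
            if not placed:
                raise ValueError("cannot place repeat copies without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            mutated, realized = _mutate(
                rng, proto.sequence, config.target_divergence / 100.0
            )
            implant = mutated if strand == "+" else revcomp(mutated)
            genome[start:end] = implant.encode("ascii")
            occupied.append((start, end))
            parts = []
            for name, s, e in proto.parts:
                if strand == "+":
                    parts.append((name, start + s, start + e))
                else:
                    parts.append((name, start + length - e, start + length - s))
            parts.sort(key=lambda p: p[1])
            truth.implants.append(
                ImplantTruth(
                    locus_id=f"{family}_{config.chrom_name}_{start}",
                    family_id=family,
                    chrom=config.chrom_name,
                    start=start,
                    end=end,
                    strand=strand,
                    realized_divergence=100.0 * realized,
                    parts=parts,
                )
            )
    truth.implants.sort(key=lambda t: t.start)
    return {config.chrom_name: genome.decode("ascii")}, truth


def truth_to_repeat_hits(truth: GroundTruth) -> pd.DataFrame:
    """Emit the implants as a masking hit table (1-based, C for minus)."""
    rows = []
    for implant in truth.implants:
        for name, s, e in implant.parts:
            rows.append(
                {
                    "score": 1000,
                    "divergence": round(implant.realized_divergence, 2),
                    "chrom": implant.chrom,
                    "begin": s + 1,
                    "end": e,
                    "strand": "+" if implant.strand == "+" else "C",
                    "family_id": implant.family_id,
                    "part_name": name,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "score",
            "divergence",
            "chrom",
            "begin",
            "end",
            "strand",
            "family_id",
            "part_name",
        ],
    )


def make_gene_annotations(
    config: SimConfig,
    truth: GroundTruth | None = None,
    designated_loci: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Non-overlapping random gene intervals at the requested density.

    The gene count is Poisson(gene_density x genome_length / 100 kb).  With
    ``config.promoter_zone_rule`` the designated loci keep a strand-aware
    zone of ``promoter_zone_bp`` upstream free of sense-orientation genes
    (and free of gene overlap), emulating the environment of promoter LTRs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if config.gene_density < 0:
        raise ValueError("gene density must be >= 0")
    n_genes = int(rng.poisson(config.gene_density * config.genome_length / 1e5))
    if n_genes == 0:
        return pd.DataFrame(columns=["gene_id", "chrom", "tx_start", "tx_end", "strand"])
    mean_len = sum(config.gene_length_range) / 2
    if n_genes * mean_len > 0.8 * config.genome_length:
        raise ValueError("gene density infeasible for this genome length")
    zones: list[tuple[int, int, str]] = []  # (start, end, forbidden strand or '*')
    if config.promoter_zone_rule and truth is not None:
        wanted = set(designated_loci or [t.locus_id for t in truth.implants])
        for implant in truth.implants:
            if implant.locus_id not in wanted:
                continue
            if implant.strand == "+":
                zones.append(
                    (implant.start - config.promoter_zone_bp, implant.start, "+")
                )
            else:
                zones.append((implant.end, implant.end + config.promoter_zone_bp, "-"))
            zones.append((implant.start, implant.end, "*"))
    rows = []
    occupied: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    while placed < n_genes and attempts < 200 * n_genes:
        attempts += 1
        length = int(rng.integers(*config.gene_length_range))
        start = int(rng.integers(0, max(1, config.genome_length - length)))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        if any(start < e and s < end for s, e in occupied):
            continue
        violates = False
        for zs, ze, zstrand in zones:
            if start < ze and zs < end and (zstrand == "*" or strand == zstrand):
                violates = True
                break
        if violates:
            continue
        rows.append(
            {
                "gene_id": f"gene{placed:04d}",
                "chrom": config.chrom_name,
                "tx_start": start,
                "tx_end": end,
                "strand": strand,
            }
        )
        occupied.append((start, end))
        placed += 1
    if placed < n_genes:
        raise ValueError("gene density infeasible for this genome length")
    genes = pd.DataFrame(rows).sort_values("tx_start").reset_index(drop=True)
    return genes


# ---------------------------------------------------------------------------
# probe-level signal dataset


def default_sample_sets(config: SimConfig) -> list[str]:
    sets = []
    for tissue in config.tissues:
        sets.extend([f"{tissue}_normal", f"{tissue}_tumor"])
    if config.include_placenta:
        sets.append("placenta")
    return sets


def _draw_level(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def make_signal_dataset(
    config: SimConfig,
    probesets: Sequence,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ProbeSignalMatrix, BatchDesign, GroundTruth]:
    """Probe intensities + sample sheet implementing the batch model.

    Each locus receives a function label and a set of active tissues; U3/U5
    true levels per sample set fall in the classifier's silent or active
    region according to the label (never the grey zone).  Probe intensity
    on the log2 scale is log2(level) + affinity + gamma_batch +
    delta_batch x N(0, noise_sd), plus a shared optical background that the
    tryptophan controls sample.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    truth = truth if truth is not None else GroundTruth()
    sets = default_sample_sets(config)
    arrays, operators, dates, covars, set_ids, pair_ids = [], [], [], [], [], []
    batch_cycle = [
        (op, f"d{d+1}") for op in config.operators for d in range(config.dates_per_operator)
    ]
    idx = 0
    for s in sets:
        for rep in range(config.arrays_per_set):
            arrays.append(f"{s}_a{rep+1}")
            op, date = batch_cycle[idx % len(batch_cycle)]
            idx += 1
            operators.append(op)
            dates.append(date)
            covars.append(s)
            set_ids.append(s)
            if s.endswith(("_normal", "_tumor")):
                tissue = s.rsplit("_", 1)[0]
                pair_ids.append(f"{tissue}_{rep+1}")
            else:
                pair_ids.append("")
    sheet = pd.DataFrame(
        {
            "operator": operators,
            "amp_date": dates,
            "covariate": covars,
            "sample_set_id": set_ids,
            "pair_id": pair_ids,
        },
        index=pd.Index(arrays, name="array_id"),
    )
    design = BatchDesign(sheet=sheet)

    batch_labels = sorted({f"{o}/{d}" for o, d in zip(operators, dates)})
    if config.batch_effects is not None:
        batch_params = {b: tuple(config.batch_effects[b]) for b in batch_labels}
    else:
        batch_params = {
            b: (
                float(rng.normal(0.0, config.batch_gamma_sd)),
                float(rng.uniform(*config.batch_delta_range)),
            )
            for b in batch_labels
        }
    truth.batch_params = batch_params

    # per-locus function + activity truth
    loci = sorted({ps.locus_id for ps in probesets})
    labels = list(config.function_probs)
    probs = np.array([config.function_probs[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    # balanced tropism: active sample sets are allocated so every tissue
    # carries a comparable number of active loci (keeps array intensity
    # distributions commensurate, as on a dense chip)
    set_load = {s: 0 for s in sets}
    for locus in loci:
        if locus not in truth.functions:
            truth.functions[locus] = str(rng.choice(labels, p=probs))
        if locus not in truth.active_sets:
            if truth.functions[locus] == "silent":
                truth.active_sets[locus] = []
            else:
                n_active = int(rng.integers(1, max(2, len(sets) // 2)))
                shuffled = list(rng.permutation(sets))
                shuffled.sort(key=lambda s: set_load[s])
                chosen = shuffled[:n_active]
                for s in chosen:
                    set_load[s] += 1
                truth.active_sets[locus] = sorted(str(s) for s in chosen)

    lo_s, hi_s = config.silent_level_range
    lo_a, hi_a = config.active_level_range
    levels = {}
    for locus in loci:
        func = truth.functions[locus]
        for s in sets:
            active = s in truth.active_sets[locus]
            if not active or func == "silent":
                u3, u5 = _draw_level(rng, lo_s, hi_s), _draw_level(rng, lo_s, hi_s)
            elif func == "promoter":
                u3, u5 = _draw_level(rng, lo_s, hi_s), _draw_level(rng, lo_a, hi_a)
            elif func == "polyA":
                u3, u5 = _draw_level(rng, lo_a, hi_a), _draw_level(rng, lo_s, hi_s)
            else:  # readthrough
                u3, u5 = _draw_level(rng, lo_a, hi_a), _draw_level(rng, lo_a, hi_a)
            levels[(locus, s)] = {"U3": u3, "U5": u5, "R": max(u3, u5)}

    expr_rows = {}
    for ps in probesets:
        per_set = []
        for s in sets:
            lv = levels[(ps.locus_id, s)]
            per_set.append(lv.get(ps.part_name, lv["R"]))
        expr_rows[ps.probeset_id] = per_set
    # cellular-transcriptome filler spanning the chip's dynamic range
    lo_b, hi_b = config.background_level_log2_range
    for i in range(config.n_background_probesets):
        base = 2.0 ** float(rng.uniform(lo_b, hi_b))
        expr_rows[f"bg:{i:04d}"] = [
            base * 2.0 ** float(rng.normal(0.0, 0.1)) for _ in sets
        ]
    true_expr = pd.DataFrame.from_dict(
        expr_rows, orient="index", columns=sets
    ).sort_index()
    truth.expression = true_expr

    probe_ids, probe_meta_rows = [], []
    affinities = {}
    for ps in probesets:
        for probe in ps.probes:
            pid = f"{ps.probeset_id}:{probe.offset}"
            probe_ids.append(pid)
            probe_meta_rows.append({"probeset_id": ps.probeset_id, "is_control": False})
            affinities[pid] = float(rng.normal(0.0, config.affinity_sd))
    for i in range(config.n_background_probesets):
        for j in range(config.background_probes_per_set):
            pid = f"bg:{i:04d}:{j}"
            probe_ids.append(pid)
            probe_meta_rows.append({"probeset_id": f"bg:{i:04d}", "is_control": False})
            affinities[pid] = float(rng.normal(0.0, config.affinity_sd))
    for i in range(config.n_control_probes):
        pid = f"trp:{i}"
        probe_ids.append(pid)
        probe_meta_rows.append({"probeset_id": "trp_control", "is_control": True})
    probe_meta = pd.DataFrame(probe_meta_rows, index=pd.Index(probe_ids, name="probe_id"))

    backgrounds = {a: max(10.0, float(rng.normal(config.background_mean, 3.0))) for a in arrays}
    values = np.zeros((len(probe_ids), len(arrays)))
    probeset_by_pid = {pid: row["probeset_id"] for pid, row in zip(probe_ids, probe_meta_rows)}
    set_of_array = dict(zip(arrays, set_ids))
    batch_of_array = {
        a: f"{o}/{d}" for a, o, d in zip(arrays, operators, dates)
    }
    for j, array in enumerate(arrays):
        gamma, delta = batch_params[batch_of_array[array]]
        s = set_of_array[array]
        for i, pid in enumerate(probe_ids):
            if probeset_by_pid[pid] == "trp_control":
                values[i, j] = backgrounds[array] * float(
                    np.exp(rng.normal(0.0, 0.1))
                )
            else:
                level = true_expr.loc[probeset_by_pid[pid], s]
                log2_signal = (
                    np.log2(level)
                    + affinities[pid]
                    + gamma
                    + delta * rng.normal(0.0, config.noise_sd)
                )
                values[i, j] = backgrounds[array] + 2.0**log2_signal
    matrix = ProbeSignalMatrix(
        values=pd.DataFrame(values, index=probe_meta.index, columns=arrays),
        probe_meta=probe_meta,
    )
    return matrix, design, truth
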