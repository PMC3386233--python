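"""Rule-based LTR function assignment from U3/U5 signal dichotomy.

An LTR that still initiates transcription produces U5 (and R) transcripts
but no U3 transcript (transcription starts at the U3/R boundary); an LTR
that terminates an upstream transcript by polyadenylation produces U3 but
not U5; a transcribed-through LTR produces both.  Comparing the set-level
signals of independent U3 and U5 probesets therefore classifies each
attributable LTR as promoter, polyA, readthrough or silent:

* negative signal: value < 50; positive: value > 100; the interval
  [50, 100] is an indeterminate grey zone;
* U3-/U5+ -> promoter, U3+/U5- -> polyA, U3+/U5+ -> readthrough,
  U3-/U5- -> silent;
* when a signal falls in the grey zone the function indicated by the larger
  signal is assigned only if the larger signal is positive and the
  larger/smaller ratio exceeds 4 (e.g. U3 = 80, U5 = 321 is a promoter);
  otherwise the call is unknown.

Calls are consolidated across tissues without demotion (a single confident
promoter call makes the locus a promoter locus), and the promoter/polyA
list overlap quantifies operational determinism: an LTR is not expected to
switch between the two functions as the tissue changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

FUNCTION_LABELS = ("promoter", "polyA", "readthrough", "silent", "unknown")


@dataclass
class ClassifierConfig:
    positive_threshold: float = 100.0
    negative_threshold: float = 50.0
    grey_ratio: float = 4.0

    def __post_init__(self) -> None:
        if not self.negative_threshold < self.positive_threshold:
            raise ValueError("negative_threshold must be below positive_threshold")
        if self.grey_ratio <= 1:
            raise ValueError("grey_ratio must exceed 1")


@dataclass(frozen=True)
class LtrSignalPair:
    locus_id: str
    ltr_role: str  # 5prime | 3prime | solo
    u3: float
    u5: float
    sample_set_id: str

    @property
    def ltr_id(self) -> str:
        return f"{self.locus_id}@{self.ltr_role}"


@dataclass(frozen=True)
class FunctionCall:
    label: str
    grey_zone_used: bool


def _zone(value: float, config: ClassifierConfig) -> str:
    if value < config.negative_threshold:
        return "negative"
    if value > config.positive_threshold:
        return "positive"
    return "grey"


def classify_ltr(
    u3: float, u5: float, config: ClassifierConfig | None = None
) -> FunctionCall:
    """Assign a function to one LTR from its U3/U5 set-level signals.

    Total over [0, inf)^2: exactly one label for every pair.  The grey-zone
    ratio rule is conservative: a grey signal is resolved only when the
    *larger* signal is genuinely positive (> 100) and exceeds the smaller
    by more than the grey ratio (a zero smaller signal counts as an
    infinite ratio) -- a promoter or polyA call always rests on a positive
    signal, exactly as in the canonical (U3 = 80, U5 = 321) example.  A
    negative/grey pair is therefore always unknown, and two grey signals
    can never reach the ratio.  ``grey_zone_used`` flags every call that
    involved a grey signal.
    """
    config = config or ClassifierConfig()
    if u3 < 0 or u5 < 0:
        raise ValueError("signals must be non-negative")
    z3, z5 = _zone(u3, config), _zone(u5, config)
    grey = "grey" in (z3, z5)
    if z3 == "negative" and z5 == "negative":
        return FunctionCall("silent", False)
    if z3 == "negative" and z5 == "positive":
        return FunctionCall("promoter", False)
    if z3 == "positive" and z5 == "negative":
        return FunctionCall("polyA", False)
    if z3 == "positive" and z5 == "positive":
        return FunctionCall("readthrough", False)
    # at least one signal is grey
    hi, lo = max(u3, u5), min(u3, u5)
    ratio = math.inf if lo == 0 else hi / lo
    if hi > config.positive_threshold and ratio > config.grey_ratio:
        label = "promoter" if u5 > u3 else "polyA"
        return FunctionCall(label, grey)
    return FunctionCall("unknown", grey)


# ---------------------------------------------------------------------------
# attributable LTRs


def attributable_ltrs(
    elements: Mapping[str, object],
    probesets: Iterable[object],
) -> set[str]:
    """LTR ids whose function can be inferred at all.

    An LTR is attributable iff (i) its element carries a complete U3-R-U5
    block for that LTR on the genome and (ii) both a U3 and a U5 probeset
    exist on the chip for that LTR, so the U3/U5 signal dichotomy is
    measurable.  Ids are ``locus@role``.  Probesets whose ``ltr_role`` is
    unset count for single-LTR-block elements only.
    """
    parts_by_ltr: dict[str, set[str]] = {}
    for ps in probesets:
        locus = ps.locus_id
        role = getattr(ps, "ltr_role", None)
        if role is None:
            element = elements.get(locus)
            if element is None or len(element.ltr_blocks) != 1:
                continue
            role = element.ltr_blocks[0].role
        parts_by_ltr.setdefault(f"{locus}@{role}", set()).add(ps.part_name)
    result = set()
    for locus_id, element in elements.items():
        for block in element.ltr_blocks:
            if not block.is_complete:
                continue
            ltr_id = f"{locus_id}@{block.role}"
            if {"U3", "U5"} <= parts_by_ltr.get(ltr_id, set()):
                result.add(ltr_id)
    return result


# ---------------------------------------------------------------------------
# consolidation across tissues


@dataclass
class ConsolidatedCalls:
    promoter: set[str]
    polya: set[str]
    readthrough: set[str]
    silent_only: set[str]
    overlap: set[str]  # promoter AND polyA somewhere: determinism violations
    overlap_grey: set[str]  # overlap members where a grey-zone call is involved

    @property
    def overlap_count(self) -> int:
        return len(self.overlap)


def consolidate_locus_functions(
    calls: Mapping[str, Sequence[FunctionCall]]
) -> ConsolidatedCalls:
    """Collapse per-tissue calls into locus-level function lists.

    A locus joins the promoter list if it is called promoter in at least
    one sample set (likewise polyA, readthrough); unknown and silent calls
    never veto an assignment.  The promoter/polyA intersection is the
    operational-determinism report, with members involving any grey-zone
    call flagged separately.
    """
    promoter, polya, readthrough, silent_only = set(), set(), set(), set()
    grey_involved: set[str] = set()
    for ltr_id, ltr_calls in calls.items():
        if not ltr_calls:
            raise ValueError(f"no calls for {ltr_id}")
        labels = {c.label for c in ltr_calls}
        if "promoter" in labels:
            promoter.add(ltr_id)
        if "polyA" in labels:
            polya.add(ltr_id)
        if "readthrough" in labels:
            readthrough.add(ltr_id)
        if labels <= {"silent", "unknown"} and "silent" in labels:
            silent_only.add(ltr_id)
        if any(
            c.grey_zone_used and c.label in ("promoter", "polyA") for c in ltr_calls
        ):
            grey_involved.add(ltr_id)
    overlap = promoter & polya
    return ConsolidatedCalls(
        promoter=promoter,
        polya=polya,
        readthrough=readthrough,
        silent_only=silent_only,
        overlap=overlap,
        overlap_grey=overlap & grey_involved,
    )


def compare_call_sets(
    reference: set[str], query: set[str]
) -> dict[str, object]:
    """New characterizations gained by a second dataset vs a reference."""
    new = query - reference
    return {
        "intersection": reference & query,
        "new_characterizations": new,
        "n_reference": len(reference),
        "n_query": len(query),
        "n_intersection": len(reference & query),
        "n_new": len(new),
    }


# ---------------------------------------------------------------------------
# summary report


def function_summary_report(
    counts: Mapping[str, int], attributable_total: int
) -> pd.DataFrame:
    """Counts and integer-truncated percentages per function category.

    Percentages are floor(100 * count / total): truncation, not rounding,
    matches the published convention (326/1513 prints as 21%, 209/1513 as
    13%).  The residual (attributable LTRs in no category) is exposed as an
    explicit ``unassigned`` row.
    """
    if attributable_total <= 0:
        raise ValueError("attributable total must be positive")
    total_counted = sum(counts.values())
    if total_counted > attributable_total:
        raise ValueError("category counts exceed the attributable total")
    rows = []
    for label, count in counts.items():
        if count < 0:
            raise ValueError("negative count")
        rows.append(
            {
                "category": label,
                "count": count,
                "percent": (100 * count) // attributable_total,
            }
        )
    residual = attributable_total - total_counted
    rows.append(
        {
            "category": "unassigned",
            "count": residual,
            "percent": (100 * residual) // attributable_total,
        }
    )
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def pair_signals(expr_linear: pd.DataFrame) -> list[LtrSignalPair]:
    """Build (U3, U5) signal pairs from a comparison-scale expression matrix.

    Rows must follow the probeset id convention ``locus|part`` or
    ``locus|part@role``; only LTRs with both a U3 and a U5 probeset yield a
    pair (one per sample set).
    """
    by_ltr: dict[tuple[str, str], dict[str, pd.Series]] = {}
    for probeset_id in expr_linear.index:
        if "|" not in probeset_id:
            continue
        locus, rest = probeset_id.split("|", 1)
        part, _, role = rest.partition("@")
        if part not in ("U3", "U5"):
            continue
        by_ltr.setdefault((locus, role or "solo"), {})[part] = expr_linear.loc[
            probeset_id
        ]
    pairs = []
    for (locus, role), parts in sorted(by_ltr.items()):
        if "U3" not in parts or "U5" not in parts:
            continue
        for sample_set in expr_linear.columns:
            pairs.append(
                LtrSignalPair(
                    locus_id=locus,
                    ltr_role=role,
                    u3=float(parts["U3"][sample_set]),
                    u5=float(parts["U5"][sample_set]),
                    sample_set_id=str(sample_set),
                )
            )
    return pairs


def classify_signal_pairs(
    pairs: Sequence[LtrSignalPair], config: ClassifierConfig | None = None
) -> dict[str, dict[str, FunctionCall]]:
    """Per-(LTR, sample set) function calls keyed by LTR id."""
    calls: dict[str, dict[str, FunctionCall]] = {}
    for pair in pairs:
        calls.setdefault(pair.ltr_id, {})[pair.sample_set_id] = classify_ltr(
            pair.u3, pair.u5, config
        )
    return calls


def calls_to_table(
    calls: Mapping[str, Mapping[str, FunctionCall]]
) -> pd.DataFrame:
    """Per-(LTR, sample set) call table for serialization."""
    rows = []
    for ltr_id, per_set in calls.items():
        for sample_set, call in per_set.items():
            rows.append(
                {
                    "ltr_id": ltr_id,
                    "sample_set_id": sample_set,
                    "label": call.label,
                    "grey_zone_used": call.grey_zone_used,
                }
            )
    return pd.DataFrame(
        rows, columns=["ltr_id", "sample_set_id", "label", "grey_zone_used"]
    )
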