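"""Locus-level transcriptome analysis of the repeat-element expression matrix.

Works on the *comparison scale*: the anti-logged (2**x) set-level summarized
expression values.  All published thresholds (activity cutoff 100, the 2^6
detection filter) are applied on this single declared scale so no log/linear
confusion can arise.

Provides activity calls per element, expression-profile partitioning
(k-means with a minimum cluster size of 6), permutation-based SAM
differential expression with FDR correction, repertoire extrapolation with
chip-content correction factors, and relative-expression computations for
qPCR confirmation assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

ACTIVITY_THRESHOLD = 100.0
DETECTION_FILTER = 2.0**6
MIN_CLUSTER_SIZE = 6
DEFAULT_FDR_CUTOFF = 0.20


def to_comparison_scale(expr_log2: pd.DataFrame) -> pd.DataFrame:
    """Map log2 summarized values onto the linear comparison scale."""
    return 2.0**expr_log2


# ---------------------------------------------------------------------------
# activity


@dataclass
class ActivityResult:
    probeset_active: pd.DataFrame  # probesets x sample sets, bool
    element_active: pd.Series  # per locus, bool (active in >= 1 set)
    counts: pd.DataFrame | None  # family x structure counts of active elements
    unmapped_probesets: list[str]


def call_active_elements(
    expr: pd.DataFrame,
    probeset_map: Mapping[str, str],
    elements: Mapping[str, object] | None = None,
    threshold: float = ACTIVITY_THRESHOLD,
) -> ActivityResult:
    """Element activity from set-level expression on the comparison scale.

    A probeset is active in a sample set iff its value is strictly greater
    than the threshold (a value of exactly 100 is inactive); an element is
    active iff any of its probesets is active in any set, and each element
    counts once however many of its probesets fire.  When ``elements`` maps
    locus ids to objects with ``family_id``/``structure`` attributes, active
    elements are tallied per family x structure.
    """
    unmapped = [p for p in expr.index if p not in probeset_map]
    if unmapped:
        warnings.warn(f"{len(unmapped)} probesets without element mapping excluded")
    mapped = expr.loc[[p for p in expr.index if p in probeset_map]]
    active = mapped > threshold
    locus = pd.Series({p: probeset_map[p] for p in mapped.index}, name="locus_id")
    element_active = active.any(axis=1).groupby(locus).any()
    counts = None
    if elements is not None:
        rows = []
        for locus_id, is_active in element_active.items():
            if not is_active or locus_id not in elements:
                continue
            e = elements[locus_id]
            rows.append({"family_id": e.family_id, "structure": e.structure})
        counts = (
            pd.DataFrame(rows, columns=["family_id", "structure"])
            .value_counts()
            .unstack(fill_value=0)
            if rows
            else pd.DataFrame()
        )
    return ActivityResult(
        probeset_active=active,
        element_active=element_active,
        counts=counts,
        unmapped_probesets=unmapped,
    )


# ---------------------------------------------------------------------------
# expression profiles


@dataclass
class ExpressionProfile:
    profile_id: int
    members: list[str]
    tissue_signature: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def partition_profiles(
    active_expr: pd.DataFrame,
    k: int | None = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    random_state: int = 0,
    k_range: Iterable[int] = range(2, 16),
) -> tuple[list[ExpressionProfile], list[str]]:
    """Partition active probesets into expression profiles.

    Euclidean k-means on the set-level rows; ``k`` is either given or chosen
    by a silhouette scan over ``k_range``.  Clusters smaller than the
    minimum size (6) dissolve into the unclassified pool.  Each retained
    profile is annotated with its dominant sample sets: those whose centroid
    value exceeds the midpoint between the centroid's min and max.
    """
    n = active_expr.shape[0]
    if n < min_cluster_size:
        return [], list(active_expr.index)
    X = active_expr.to_numpy(dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k is None:
        best_k, best_score = None, -np.inf
        for kk in k_range:
            if kk >= n or kk > n_distinct:
                break
            labels = KMeans(n_clusters=kk, n_init=10, random_state=random_state).fit_predict(X)
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(X, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k if best_k is not None else 1
    if k < 2:
        labels = np.zeros(n, dtype=int)
    else:
        labels = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(X)
    profiles: list[ExpressionProfile] = []
    unclassified: list[str] = []
    next_id = 1
    for label in sorted(set(labels)):
        members = [active_expr.index[i] for i in np.nonzero(labels == label)[0]]
        if len(members) < min_cluster_size:
            unclassified.extend(members)
            continue
        centroid = active_expr.loc[members].mean(axis=0)
        cut = (centroid.min() + centroid.max()) / 2.0
        signature = [str(c) for c in centroid.index[centroid > cut]]
        profiles.append(
            ExpressionProfile(
                profile_id=next_id, members=members, tissue_signature=signature
            )
        )
        next_id += 1
    return profiles, unclassified


# ---------------------------------------------------------------------------
# SAM differential expression


@dataclass
class SamResult:
    table: pd.DataFrame  # index probeset, columns d, q, called
    filtered_out: list[str]
    s0: float


def _sam_statistic(
    values: np.ndarray, group_mask: np.ndarray, s0: float
) -> np.ndarray:
    """Unpaired two-class SAM statistic for each row."""
    a = values[:, ~group_mask]
    b = values[:, group_mask]
    n1, n2 = a.shape[1], b.shape[1]
    diff = b.mean(axis=1) - a.mean(axis=1)
    pooled = ((a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1))
              / (n1 + n2 - 2))
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return diff / (s + s0)


def _paired_statistic(diffs: np.ndarray, s0: float) -> np.ndarray:
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1) / np.sqrt(n)
    return mean / (s + s0)


def _tune_s0(numer_s: np.ndarray, stat_fn) -> float:
    """Pick s0 minimizing the coefficient of variation of d across s-strata."""
    best_s0, best_cv = 0.0, np.inf
    for alpha in np.arange(0, 1.01, 0.05):
        s0 = float(np.quantile(numer_s, alpha))
        d = stat_fn(s0)
        # stratify genes by s into ~10 groups, spread of d per group
        edges = np.quantile(numer_s, np.linspace(0, 1, 11))
        strata = np.clip(np.searchsorted(edges, numer_s, side="right") - 1, 0, 9)
        mads = []
        for g in range(10):
            vals = d[strata == g]
            if len(vals) >= 2:
                mads.append(stats.median_abs_deviation(vals, scale="normal"))
        if len(mads) < 2:
            continue
        mads = np.asarray(mads)
        cv = mads.std(ddof=1) / mads.mean() if mads.mean() > 0 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def sam_fdr(
    expr: pd.DataFrame,
    group_labels: pd.Series,
    paired: pd.Series | None = None,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    n_permutations: int = 1000,
    seed: int = 0,
    detection_filter: float = DETECTION_FILTER,
) -> SamResult:
    """Permutation SAM with FDR correction between two sample groups.

    ``expr`` holds comparison-scale values (samples in columns); probesets
    whose values stay below 2^6 in every sample are removed before testing.
    The statistic is d = (mean difference)/(s + s0) on log2 values, with s0
    tuned to minimize the coefficient of variation of d across s strata.
    The null is built by label permutation (paired sign flips when
    ``paired`` marks matched samples); q-values are permutation exceedance
    ratios scaled by an estimated null proportion and monotonized; calls are
    made at q <= the FDR cutoff.
    """
    group_labels = group_labels.loc[expr.columns]
    # deterministic orientation: the lexicographically larger label is the
    # test group (d > 0 means higher expression there)
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    if (group_labels.value_counts() < 2).any():
        raise ValueError("each group needs >= 2 samples")
    keep = (expr >= detection_filter).any(axis=1)
    filtered_out = list(expr.index[~keep])
    data = np.log2(expr.loc[keep].to_numpy(dtype=float))
    index = expr.index[keep]
    rng = np.random.default_rng(seed)

    if paired is not None:
        paired = paired.loc[expr.columns]
        mask = group_labels == groups[1]
        pair_ids = paired.unique()
        diff_cols = []
        for pid in pair_ids:
            cols = np.nonzero((paired == pid).to_numpy())[0]
            b = [c for c in cols if mask.iloc[c]]
            a = [c for c in cols if not mask.iloc[c]]
            if len(a) != 1 or len(b) != 1:
                raise ValueError(f"pair {pid} is not a matched 1:1 pair")
            diff_cols.append(data[:, b[0]] - data[:, a[0]])
        diffs = np.column_stack(diff_cols)
        n_pairs = diffs.shape[1]
        s_obs = diffs.std(axis=1, ddof=1) / np.sqrt(n_pairs)
        s0 = _tune_s0(s_obs, lambda s0: _paired_statistic(diffs, s0))
        d_obs = _paired_statistic(diffs, s0)
        d_perm = np.empty((n_permutations, len(d_obs)))
        for p in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n_pairs)
            d_perm[p] = _paired_statistic(diffs * signs[None, :], s0)
    else:
        mask = (group_labels == groups[1]).to_numpy()
        a = data[:, ~mask]
        b = data[:, mask]
        n1, n2 = a.shape[1], b.shape[1]
        pooled = ((a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1))
                  / (n1 + n2 - 2))
        s_obs = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        s0 = _tune_s0(s_obs, lambda s0: _sam_statistic(data, mask, s0))
        d_obs = _sam_statistic(data, mask, s0)
        d_perm = np.empty((n_permutations, len(d_obs)))
        for p in range(n_permutations):
            perm_mask = np.zeros(len(mask), dtype=bool)
            perm_mask[rng.choice(len(mask), size=mask.sum(), replace=False)] = True
            d_perm[p] = _sam_statistic(data, perm_mask, s0)

    q = _permutation_q_values(d_obs, d_perm)
    table = pd.DataFrame(
        {"d": d_obs, "q": q, "called": q <= fdr_cutoff}, index=index
    )
    return SamResult(table=table, filtered_out=filtered_out, s0=s0)


def _permutation_q_values(d_obs: np.ndarray, d_perm: np.ndarray) -> np.ndarray:
    """FDR q-values from permutation exceedances of |d|.

    For each cutoff c = |d_i|: the expected null count of |d*| >= c (mean
    over permutations, scaled by the estimated null proportion pi0) divided
    by the observed count, monotonized over decreasing cutoffs and capped
    at 1.
    """
    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(d_perm)
    n = len(abs_obs)
    # Storey-style pi0 from the central 50% of the permutation distribution
    lo, hi = np.quantile(d_perm, [0.25, 0.75])
    pi0 = min(1.0, ((d_obs >= lo) & (d_obs <= hi)).sum() / (0.5 * n))
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    perm_sorted = np.sort(abs_perm.ravel())
    exceed_null = (
        len(perm_sorted) - np.searchsorted(perm_sorted, sorted_abs, side="left")
    ) / d_perm.shape[0]
    exceed_obs = np.arange(1, n + 1)
    fdr = np.minimum(1.0, pi0 * exceed_null / exceed_obs)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = fdr
    return q


def tissue_specific_sets(
    dep_lists: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Members appearing in exactly one tissue's differential list."""
    counts: dict[str, int] = {}
    for members in dep_lists.values():
        for m in members:
            counts[m] = counts.get(m, 0) + 1
    return {
        tissue: {m for m in members if counts[m] == 1}
        for tissue, members in dep_lists.items()
    }


# ---------------------------------------------------------------------------
# repertoire extrapolation


def extrapolate_repertoire(
    transcriptome_counts: pd.DataFrame,
    chip_counts: pd.DataFrame,
    genome_counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct transcriptome counts for chip content and renormalize.

    The chip holds only the loci for which specific probes could be
    designed, so raw transcriptome counts under-represent families whose
    loci were hard to discriminate.  Each cell is scaled by genome/chip;
    proportions are then renormalized to sum to one over the table.
    """
    t = transcriptome_counts.astype(float)
    c = chip_counts.astype(float)
    g = genome_counts.astype(float)
    bad = (c == 0) & (t > 0)
    if bad.any().any():
        raise ValueError("chip count of 0 with nonzero transcriptome count")
    factor = g.where(c != 0, 0.0) / c.replace(0, np.nan)
    corrected = (t * factor).fillna(0.0)
    total = corrected.to_numpy().sum()
    proportions = corrected / total if total > 0 else corrected
    return corrected, proportions


# ---------------------------------------------------------------------------
# qPCR relative expression


def relative_expression(ct: pd.Series, efficiency: float) -> pd.Series:
    """RLE = Eff^(Ct_min - Ct) across the samples of one PCR system."""
    if not 1 < efficiency <= 2:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    return efficiency ** (ct.min() - ct)


def qpcr_relative_expression(
    ct_table: pd.DataFrame,
    efficiencies: pd.Series,
    housekeeping_ids: Sequence[str],
) -> pd.DataFrame:
    """Housekeeping-normalized relative expression for each PCR system.

    RLE = Eff^(Ct_min - Ct) per system; each sample's values are divided by
    the geometric mean of its housekeeping-system RLEs.
    """
    missing = [h for h in housekeeping_ids if h not in ct_table.index]
    if missing:
        raise ValueError(f"housekeeping systems missing from Ct table: {missing}")
    if ct_table.loc[list(housekeeping_ids)].isna().any().any():
        raise ValueError("missing housekeeping Ct value")
    rle = pd.DataFrame(
        {
            system: relative_expression(ct_table.loc[system], float(efficiencies[system]))
            for system in ct_table.index
        }
    ).T
    hk = rle.loc[list(housekeeping_ids)]
    norm = np.exp(np.log(hk).mean(axis=0))  # geometric mean per sample
    return rle / norm


def fc_u5_u3(
    eff_u3: float, ct_u3: float, eff_u5: float, ct_u5: float
) -> tuple[float, bool]:
    """U5-over-U3 fold change; values above 1 indicate promoter activity.

    Fc_U5/U3 = Eff_U3^Ct_U3 / Eff_U5^Ct_U5 (a higher Ct means less
    template, hence U3 in the numerator).
    """
    ratio = (eff_u3**ct_u3) / (eff_u5**ct_u5)
    return ratio, ratio > 1.0
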