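"""Rank-order classification of mutated positions: rheostat, toggle or neutral.

A position in one homolog is scored from all its substitutions' repression
values.  Rank-ordered outcomes fall into a handful of archetypes:

* ``N`` / ``n`` — neutral: every substitution stays within 2-fold (``N``) or
  within ~5-fold (``n``) of the parent protein.
* ``T`` — toggle: biphasic outcomes, one group of substitutions near the
  parent level, the other indistinguishable from the no-repressor MIN level,
  with nothing in between.
* ``3`` — three discrete states instead of a continuum.
* ``R`` / ``r`` — rheostat: progressive changes spanning more than two orders
  of magnitude (``R``) or between ~5-fold and two orders (``r``).
* ``x`` — no substitution shows measurable repression.
* ``#`` — too few substitutions to call a behavior.
* hybrids — ``R+T``/``r+T`` (a rheostatic subset plus a subset that abolishes
  repression), ``N+R``/``N+r`` (a mostly-neutral position with a rheostatic
  minority), ``n/r`` (between neutral and rheostat, ~5–9-fold span).

Two distinguishability rules anchor everything.  A *change* between two
measurements requires BOTH a >2-fold activity difference AND non-overlapping
standard-deviation intervals.  A variant is *at MIN* when it is not
distinguishable, by that same rule, from the DEL (no repressor) control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import (
    HomologContext,
    PositionProfile,
    ValidationError,
)

CODE_RHEOSTAT = "R"
CODE_RHEOSTAT_MINOR = "r"
CODE_TOGGLE = "T"
CODE_NEUTRAL = "N"
CODE_NEUTRAL_MINOR = "n"
CODE_THREE_STATE = "3"
CODE_INSUFFICIENT = "#"
CODE_NO_REPRESSION = "x"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the decision procedure (all spans in log10 units)."""

    min_substitutions: int = 5      # fewer scored substitutions -> "#"
    neutral_fold: float = 2.0       # the assay's equivalence band
    n_fold: float = 5.0             # outer band for "n" (between 2- and ~5-fold)
    rheostat_span: float = 2.0      # "R" needs > 2 orders of magnitude
    r_span_min: float = math.log10(5.0)   # "r" starts beyond the ~5-fold band
    nr_span_max: float = 0.95       # "n/r" window: ~5-9-fold span
    cluster_gap: float = 0.7        # log10 gap that separates discrete states
    three_state_width: float = 0.3  # max internal span of a discrete state
    gap_fraction: float = 0.62      # progressivity: largest gap <= this * span
    min_subset: int = 3             # "+T" hybrids need >= this many at MIN


@dataclass(frozen=True)
class FoldChange:
    """Parent / variant activity ratio: >1 = enhanced repression, <1 = diminished."""

    variant_aa: str
    value: float
    changed: bool
    at_min: bool


@dataclass
class BehaviorCall:
    """A position's behavior code with its supporting evidence."""

    code: str
    span_log10: float
    n_substitutions: int
    n_at_min: int = 0
    n_neutral: int = 0
    clusters: list[tuple[int, float, float]] = field(default_factory=list)
    largest_gap: float = 0.0


def is_changed(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """The dual change criterion between two (mean, sd) measurements.

    True iff the means differ strictly more than 2-fold AND the intervals
    mean +/- sd do not overlap.  Symmetric; false on identical inputs.
    """
    (ma, sa), (mb, sb) = a, b
    if sa < 0 or sb < 0:
        raise ValidationError("standard deviations must be non-negative")
    lo, hi = sorted((ma, mb))
    if lo <= 0:
        ratio_ok = hi > 0
    else:
        ratio_ok = hi / lo > 2.0
    disjoint = (ma + sa < mb - sb) or (mb + sb < ma - sa)
    return bool(ratio_ok and disjoint)


def clamp_activities(values: Iterable[float], floor: float | None = None) -> list[float]:
    """Replace zero activities by half the smallest positive value.

    The assay bottoms out rather than reading exactly zero; ratios must exist.
    """
    vals = list(values)
    positive = [v for v in vals if v > 0]
    if floor is None:
        if not positive:
            raise ValidationError("all activities are zero; cannot form ratios")
        floor = min(positive) / 2.0
    return [v if v > 0 else floor for v in vals]


def fold_change(
    parent: tuple[float, float],
    variant: tuple[float, float],
    variant_aa: str = "?",
    del_control: float | None = None,
    floor: float | None = None,
) -> FoldChange:
    """Normalize one variant against its parent protein.

    ``value`` is parent_mean / variant_mean, so values above 1 mean the
    substitution repressed more tightly than the parent.  ``changed`` applies
    the dual change criterion against the parent; ``at_min`` (if a DEL control
    is supplied) marks variants indistinguishable from the no-repressor level.
    """
    pm, ps = parent
    vm, vs = variant
    pm, vm = clamp_activities([pm, vm], floor=floor) if min(pm, vm) <= 0 else (pm, vm)
    if pm <= 0 or vm <= 0:
        raise ValidationError("activities must be positive after clamping")
    at_min = False
    if del_control is not None:
        at_min = not is_changed((vm, vs), (del_control, 0.0))
    return FoldChange(
        variant_aa=variant_aa,
        value=pm / vm,
        changed=is_changed((pm, ps), (vm, vs)),
        at_min=at_min,
    )


def profile_fold_changes(profile: PositionProfile) -> list[FoldChange]:
    """Fold changes for every scored substitution of a profile, with a
    dataset-level zero clamp shared across the profile."""
    ms = profile.scored()
    hom = profile.homolog
    positive = [v for v in
                [hom.parent_activity, hom.del_control] + [m.mean_activity for m in ms]
                if v > 0]
    floor = min(positive) / 2.0 if positive else None
    parent = clamp_activities([hom.parent_activity], floor=floor)[0]
    return [
        fold_change(
            (parent, hom.parent_sd),
            (m.mean_activity, m.sd_activity),
            variant_aa=m.substituted_aa,
            del_control=hom.del_control,
            floor=floor,
        )
        for m in ms
    ]


def _split_clusters(sorted_logs: Sequence[float], gap: float) -> list[tuple[int, int]]:
    """Split sorted log10 activities at gaps >= ``gap``; returns index ranges."""
    bounds = []
    start = 0
    for i in range(1, len(sorted_logs)):
        if sorted_logs[i] - sorted_logs[i - 1] >= gap:
            bounds.append((start, i))
            start = i
    bounds.append((start, len(sorted_logs)))
    return bounds


def _span(values: Sequence[float]) -> float:
    return max(values) - min(values) if len(values) > 1 else 0.0


def classify_position(
    profile: PositionProfile, cfg: ClassifierConfig = ClassifierConfig()
) -> BehaviorCall:
    """Assign a behavior code to one (homolog, position).

    Deterministic gate order: minimum-count -> all-at-MIN ("x") -> neutral
    ("N"/"n") -> discrete clusters ("T"/"3") -> progressive span ("R") ->
    hybrids ("R+T"/"r+T", "N+R"/"N+r", "n/r") -> span ("r") -> fallback.
    Invariant under measurement re-ordering and under common rescaling of all
    activities in the profile.
    """
    ms = profile.scored()
    n = len(ms)
    if n < cfg.min_substitutions:
        return BehaviorCall(CODE_INSUFFICIENT, 0.0, n)

    fcs = profile_fold_changes(profile)
    hom = profile.homolog
    positive = [v for v in
                [hom.parent_activity, hom.del_control] + [m.mean_activity for m in ms]
                if v > 0]
    floor = min(positive) / 2.0
    acts = clamp_activities([m.mean_activity for m in ms], floor=floor)
    logs = np.log10(np.sort(acts))
    gaps = np.diff(logs)
    span = float(logs[-1] - logs[0])
    largest_gap = float(gaps.max()) if len(gaps) else 0.0

    n_at_min = sum(fc.at_min for fc in fcs)
    neutral_lo, neutral_hi = 1.0 / cfg.neutral_fold, cfg.neutral_fold
    n_neutral = sum(neutral_lo <= fc.value <= neutral_hi for fc in fcs)

    bounds = _split_clusters(logs, cfg.cluster_gap)
    clusters = [(hi - lo, float(logs[lo]), float(logs[hi - 1])) for lo, hi in bounds]

    call = BehaviorCall(
        code="?", span_log10=span, n_substitutions=n, n_at_min=n_at_min,
        n_neutral=n_neutral, clusters=clusters, largest_gap=largest_gap,
    )

    # x: weak or no measurable repression for any substitution
    if n_at_min == n:
        call.code = CODE_NO_REPRESSION
        return call

    # neutral bands
    if all(neutral_lo <= fc.value <= neutral_hi for fc in fcs):
        call.code = CODE_NEUTRAL
        return call
    if all(1.0 / cfg.n_fold <= fc.value <= cfg.n_fold for fc in fcs):
        call.code = CODE_NEUTRAL_MINOR
        return call

    # discrete states: toggle (parent-level + MIN, nothing between)
    sorted_idx = np.argsort(acts)
    fc_sorted = [fcs[i] for i in sorted_idx]
    if len(bounds) == 2:
        lo_fcs = fc_sorted[bounds[0][0]:bounds[0][1]]
        hi_fcs = fc_sorted[bounds[1][0]:bounds[1][1]]
        lo_neutral = all(neutral_lo <= fc.value <= neutral_hi for fc in lo_fcs)
        hi_min = all(fc.at_min for fc in hi_fcs)
        if lo_neutral and hi_min:
            call.code = CODE_TOGGLE
            return call
    # three discrete states: tight levels, empty interiors
    if len(bounds) == 3 and all(
        _span(logs[lo:hi]) <= cfg.three_state_width for lo, hi in bounds
    ):
        call.code = CODE_THREE_STATE
        return call

    # a subset of >= min_subset substitutions at MIN is its own (abolished)
    # state; MIN values are censored at the assay floor and are excluded from
    # the progressive-span measurement of the remainder
    rest = sorted(math.log10(a) for a, fc in zip(acts, fcs) if not fc.at_min)
    if n_at_min >= cfg.min_subset:
        rest_span = _span(rest)
        rest_gaps = np.diff(rest)
        rest_prog = (rest_gaps.max() <= cfg.gap_fraction * rest_span
                     if len(rest_gaps) and rest_span > 0 else True)
        if rest_span > cfg.rheostat_span and rest_prog:
            call.code = CODE_RHEOSTAT + "+T"
            return call
        if rest_span > cfg.r_span_min:
            call.code = CODE_RHEOSTAT_MINOR + "+T"
            return call

    # progressive rheostat spanning > 2 orders of magnitude
    progressive = largest_gap <= cfg.gap_fraction * span if span > 0 else True
    if span > cfg.rheostat_span and progressive:
        call.code = CODE_RHEOSTAT
        return call
    # mostly neutral with a rheostatic minority reaching beyond the ~5-fold band
    if n_neutral >= math.ceil(n / 2) and n_neutral < n and span > cfg.r_span_min:
        call.code = (CODE_NEUTRAL + "+R" if span > cfg.rheostat_span
                     else CODE_NEUTRAL + "+r")
        return call
    if cfg.r_span_min < span <= cfg.nr_span_max:
        call.code = CODE_NEUTRAL_MINOR + "/r"
        return call

    # rheostat character short of two orders of magnitude
    if cfg.r_span_min < span <= cfg.rheostat_span:
        call.code = CODE_RHEOSTAT_MINOR
        return call
    if span > cfg.rheostat_span:
        # wide but gap-dominated with no hybrid structure: still rheostatic
        call.code = CODE_RHEOSTAT
        return call
    call.code = CODE_NEUTRAL_MINOR
    return call


def classify_dataset(
    variants: pd.DataFrame,
    contexts: Mapping[str, HomologContext],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Classify every (homolog, position) in a variant frame.

    Returns one row per cell with the behavior code and its evidence.
    """
    from .variants import profiles_from_frame

    rows = []
    for profile in profiles_from_frame(variants, contexts):
        call = classify_position(profile, cfg)
        rows.append(
            {
                "homolog": profile.homolog.homolog_id,
                "position": profile.position,
                "code": call.code,
                "span_log10": round(call.span_log10, 4),
                "n_substitutions": call.n_substitutions,
                "n_at_min": call.n_at_min,
                "n_neutral": call.n_neutral,
                "n_clusters": len(call.clusters),
                "largest_gap_log10": round(call.largest_gap, 4),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enhancement statistics


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EnhancementRow:
    position: str
    total_variants: int
    enhanced: int
    pct_enhanced: int | None
    parents_mutated: int
    parents_enhanced: int


def enhancement_percent(enhanced: int, total_variants: int, parents_mutated: int) -> int | None:
    """Percent of substitutions enhancing repression beyond the fold threshold:
    enhanced / (total variants - parent proteins mutated), rounded half-up.
    Each parent protein counts as one of the amino acids in the total."""
    denom = total_variants - parents_mutated
    if denom <= 0:
        return None
    return round_half_up(100.0 * enhanced / denom)


def enhancement_table(
    variants: pd.DataFrame,
    contexts: Mapping[str, HomologContext],
    fold_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-position counts of substitutions that enhance repression.

    A substitution enhances when its fold change against its own parent
    exceeds ``fold_threshold`` (tighter repression).  Totals count each
    mutated parent protein once, as the amino acid it already carries.
    """
    from .variants import profiles_from_frame

    records: dict[str, dict] = {}
    for profile in profiles_from_frame(variants, contexts):
        pos = profile.position
        rec = records.setdefault(
            pos,
            {"n_subs": 0, "enhanced": 0, "parents": 0, "parents_enhanced": 0},
        )
        fcs = profile_fold_changes(profile)
        if not fcs:
            continue
        rec["n_subs"] += len(fcs)
        rec["parents"] += 1
        n_enh = sum(fc.value > fold_threshold for fc in fcs)
        rec["enhanced"] += n_enh
        rec["parents_enhanced"] += int(n_enh > 0)

    from .variants import position_sort_key

    rows = []
    for pos in sorted(records, key=position_sort_key):
        rec = records[pos]
        total = rec["n_subs"] + rec["parents"]
        pct = enhancement_percent(rec["enhanced"], total, rec["parents"])
        rows.append(
            {
                "position": pos,
                "total_variants": total,
                "enhanced": rec["enhanced"],
                "pct_enhanced": pct,
                "parents_mutated": rec["parents"],
                "parents_enhanced": rec["parents_enhanced"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allosteric response


def allosteric_change_flags(
    variants: pd.DataFrame,
    contexts: Mapping[str, HomologContext],
    parent_inactive: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Flag substitutions whose response to effector differs from the parent's.

    Variants normally track their parent in one of two ways: they induce
    fully to the DEL (no repressor) level in the inactive condition, or they
    maintain the parent's magnitude of response rho = inactive/active.  A
    variant is flagged as allostery-altered only when NEITHER holds under the
    change criterion: its inactive-condition activity is distinguishable from
    DEL and from active*rho (sd propagated through the scaling).

    ``parent_inactive`` optionally supplies each parent's own (mean, sd) in
    the inactive condition; by default parents induce fully to DEL.  Missing
    conditions yield an undetermined (NA) flag, never a false.
    """
    inactive_of = {"minus_effector": "plus_effector", "plus_effector": "minus_effector"}
    rows = []
    for (hom, pos, aa), group in variants[~variants["excluded"]].groupby(
        ["homolog", "position", "sub_aa"], sort=False
    ):
        ctx = contexts[hom]
        active = ctx.active_condition
        inactive = inactive_of[active]
        by_cond = {row["condition"]: row for _, row in group.iterrows()}
        if active not in by_cond or inactive not in by_cond:
            flag = pd.NA
        else:
            va = by_cond[active]
            vi = by_cond[inactive]
            vim = (float(vi["mean_miller"]), float(vi["sd_miller"]))
            del_ = (ctx.del_control, 0.0)
            pim, pis = parent_inactive.get(hom, del_) if parent_inactive else del_
            induces = not is_changed(vim, del_)
            rho = pim / max(ctx.parent_activity, 1e-12)
            expected = (float(va["mean_miller"]) * rho, float(va["sd_miller"]) * rho)
            maintains = not is_changed(vim, expected)
            flag = not (induces or maintains)
        rows.append({"homolog": hom, "position": pos, "sub_aa": aa,
                     "altered_allostery": flag})
    return pd.DataFrame(rows)
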