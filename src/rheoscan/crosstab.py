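"""Cross-tabulation of substitution outcomes against natural amino-acid
frequencies, plus physico-chemical scale screens.

For each (position, amino acid) cell the outcomes across all homologs are
compared with the amino acid's frequency in the motif-restricted MSA:

* ``A``  — absent from the MSA yet tolerated (repression near or better than
  parent) in two or more homologs.
* ``P1`` — present in the MSA yet, in at least one homolog whose parent
  represses below the growth threshold, the substitution pushed activity
  above that threshold (a biologically catastrophic loss).
* ``P2`` — present in the MSA yet the substitution abolished repression to
  the MIN (no repressor) level in at least one such homolog.
* ``D``  — disparate outcomes among homologs (fold changes spanning two
  orders of magnitude, or enhancing in one homolog while at MIN in another).
* ``L``  — absent from the MSA; tolerated in the designated reference
  homolog only (the family's usual single representative).
* ``X``  — the amino acid is a parent (starting) residue; excluded from the
  tallies above.

Codes are not mutually exclusive except A versus P1/P2 (absence versus
presence in the MSA); cells may carry composites such as ``P2D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classify import clamp_activities, is_changed, profile_fold_changes
from .variants import (
    AMINO_ACIDS,
    AminoAcidScale,
    HomologContext,
    PositionProfile,
    position_sort_key,
    profiles_from_frame,
)
from .msa import ColumnFrequencies

CODE_PARENT = "X"
CODE_ABSENT_TOLERATED = "A"
CODE_PRESENT_DISRUPTIVE = "P1"
CODE_PRESENT_ABOLISHING = "P2"
CODE_DISPARATE = "D"
CODE_REFERENCE_ONLY = "L"
CODE_INSUFFICIENT = "-"


@dataclass(frozen=True)
class CrosstabConfig:
    tolerated_fold: float = 0.5      # "near or better than parent": fold >= 0.5
    disparity_span: float = 2.0      # log10 fold-change span that counts as disparate
    min_homologs: int = 2            # fewer carriers -> insufficient
    absent_floor: float = 0.0        # raw MSA frequency <= this counts as absent
    reference_homolog: str | None = None  # default: first homolog of the dataset


@dataclass(frozen=True)
class ScaleScreenResult:
    homolog: str
    position: str
    scale_name: str
    rank_correlation: float | None
    n: int


def assign_outcome_codes(
    variants: pd.DataFrame,
    contexts: Mapping[str, HomologContext],
    msa_freqs: Mapping[str, ColumnFrequencies],
    cfg: CrosstabConfig = CrosstabConfig(),
) -> pd.DataFrame:
    """Assign outcome codes to every (position, amino acid) cell.

    ``msa_freqs`` maps each scanned position to its motif-subset column
    frequencies; a scanned position missing from it raises a KeyError naming
    the gap.  Returns one row per cell with the full code set (sorted,
    concatenated, e.g. ``"P2D"``) plus the per-rule booleans.
    """
    profiles = profiles_from_frame(variants, contexts)
    positions = sorted({p.position for p in profiles}, key=position_sort_key)
    missing = [p for p in positions if p not in msa_freqs]
    if missing:
        raise KeyError(f"positions absent from MSA profile: {missing}")

    order = list(dict.fromkeys(variants["homolog"]))
    reference = cfg.reference_homolog or (order[0] if order else None)

    # collect per-cell observations: (position, aa) -> homolog -> record
    obs: dict[tuple[str, str], dict[str, dict]] = {}
    parents: dict[tuple[str, str], set[str]] = {}
    for profile in profiles:
        ctx = profile.homolog
        pos = profile.position
        ms = profile.scored()
        if ms:
            wt = ms[0].wildtype_aa
            parents.setdefault((pos, wt), set()).add(ctx.homolog_id)
        for m, fc in zip(ms, profile_fold_changes(profile)):
            obs.setdefault((pos, m.substituted_aa), {})[ctx.homolog_id] = {
                "fold": fc.value,
                "at_min": fc.at_min,
                "changed": fc.changed,
                "mean": m.mean_activity,
                "parent_tight": ctx.parent_activity < ctx.growth_threshold,
                "above_threshold": m.mean_activity > ctx.growth_threshold,
            }

    rows = []
    for pos in positions:
        for aa in AMINO_ACIDS:
            cell = obs.get((pos, aa), {})
            codes: list[str] = []
            is_parent = (pos, aa) in parents
            if is_parent:
                codes.append(CODE_PARENT)
            f = msa_freqs[pos].frequency(aa)
            absent = f <= cfg.absent_floor
            if len(cell) < cfg.min_homologs:
                if not is_parent:
                    codes.append(CODE_INSUFFICIENT)
                if cell or is_parent:
                    rows.append(_cell_row(pos, aa, f, cell, codes))
                continue
            folds = [r["fold"] for r in cell.values()]
            tolerated_in = [h for h, r in cell.items()
                            if r["fold"] >= cfg.tolerated_fold]
            if absent and len(tolerated_in) >= 2:
                codes.append(CODE_ABSENT_TOLERATED)
            if not absent and any(
                r["parent_tight"] and r["above_threshold"] for r in cell.values()
            ):
                codes.append(CODE_PRESENT_DISRUPTIVE)
            if not absent and any(
                r["parent_tight"] and r["at_min"] for r in cell.values()
            ):
                codes.append(CODE_PRESENT_ABOLISHING)
            log_folds = np.log10(folds)
            enhancing = any(r["fold"] > 2 and r["changed"] for r in cell.values())
            anyone_min = any(r["at_min"] for r in cell.values())
            if (log_folds.max() - log_folds.min() >= cfg.disparity_span) or (
                enhancing and anyone_min
            ):
                codes.append(CODE_DISPARATE)
            if absent and reference in cell:
                others = [h for h in cell if h != reference]
                if cell[reference]["fold"] >= cfg.tolerated_fold and others and all(
                    cell[h]["fold"] < cfg.tolerated_fold for h in others
                ):
                    codes.append(CODE_REFERENCE_ONLY)
            rows.append(_cell_row(pos, aa, f, cell, codes))
    return pd.DataFrame(rows)


_CODE_ORDER = {c: i for i, c in enumerate(["X", "A", "P1", "P2", "L", "D", "-"])}


def _cell_row(pos, aa, freq, cell, codes):
    codes = sorted(set(codes), key=_CODE_ORDER.get)
    return {
        "position": pos,
        "aa": aa,
        "msa_frequency": freq,
        "n_homologs": len(cell),
        "codes": "".join(codes),
        "is_parent": "X" in codes,
        "absent_tolerated": "A" in codes,
        "present_disruptive": "P1" in codes,
        "present_abolishing": "P2" in codes,
        "disparate": "D" in codes,
        "reference_only": "L" in codes,
        "insufficient": "-" in codes,
    }


# ---------------------------------------------------------------------------
# physico-chemical scale screen


def scale_screen(
    profile: PositionProfile, scale: AminoAcidScale, min_n: int = 4
) -> ScaleScreenResult:
    """Rank correlation between a physico-chemical scale and log10 activity
    over one profile's substitutions.

    Spearman's tie-corrected statistic on log10 of (zero-clamped) activities;
    undefined (None) when fewer than ``min_n`` substitutions carry scale
    values or the scale is constant over the observed amino acids.
    """
    ms = [m for m in profile.scored() if m.substituted_aa in scale.values]
    n = len(ms)
    if n < min_n:
        return ScaleScreenResult(profile.homolog.homolog_id, profile.position,
                                 scale.name, None, n)
    xs = [scale.values[m.substituted_aa] for m in ms]
    if len(set(xs)) == 1:
        return ScaleScreenResult(profile.homolog.homolog_id, profile.position,
                                 scale.name, None, n)
    ys = np.log10(clamp_activities([m.mean_activity for m in ms]))
    rho = spearmanr(xs, ys).statistic
    rho = None if (rho is None or math.isnan(rho)) else float(rho)
    return ScaleScreenResult(profile.homolog.homolog_id, profile.position,
                             scale.name, rho, n)


def scale_screen_table(
    variants: pd.DataFrame,
    contexts: Mapping[str, HomologContext],
    scales: Mapping[str, AminoAcidScale],
    min_n: int = 4,
) -> pd.DataFrame:
    """Scale screen over every (homolog, position) cell and every scale."""
    rows = []
    for profile in profiles_from_frame(variants, contexts):
        for scale in scales.values():
            res = scale_screen(profile, scale, min_n=min_n)
            rows.append({
                "homolog": res.homolog,
                "position": res.position,
                "scale_name": res.scale_name,
                "rank_correlation": res.rank_correlation,
                "n": res.n,
            })
    return pd.DataFrame(rows)


def scale_screen_summary(
    screen: pd.DataFrame, strong_threshold: float = 0.8
) -> pd.DataFrame:
    """Family-wide summary: per scale, the fraction of (homolog, position)
    cells whose |rank correlation| reaches ``strong_threshold``."""
    rows = []
    for name, group in screen.groupby("scale_name"):
        defined = group["rank_correlation"].dropna()
        frac = float((defined.abs() >= strong_threshold).mean()) if len(defined) else float("nan")
        rows.append({
            "scale_name": name,
            "n_cells": len(group),
            "n_defined": len(defined),
            "frac_strong": frac,
        })
    return pd.DataFrame(rows)
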