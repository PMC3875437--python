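"""Synthetic variant datasets and alignments with known ground truth.

The generator emulates the shape of a parallel scanning-mutagenesis study of
a repressor family: a panel of parent proteins with repression values spanning
0.06-58 Miller units, a no-repressor DEL control, 8-12 substitutions per
nonconserved position, replicate measurements with multiplicative (lognormal)
noise, and both effector conditions.  Every position carries a planted
behavior class, so classification accuracy can be measured exactly:

* ``R``/``r`` — true activities stratified log-uniform across a planted
  log10 span centred on the parent (one draw per equal stratum, shuffled),
  which makes the ladder progressive for every seed.
* ``T`` — a fixed fraction of substitutions at the DEL level, the rest at
  the parent level, nothing between.
* ``3`` — three discrete levels: parent, the geometric midpoint, DEL.
* ``N``/``n`` — lognormal effects truncated inside the 2-fold (``N``) or
  5-fold (``n``) band around the parent.
* ``x`` — every substitution at the DEL level.

A companion alignment generator plants a conserved motif in a configurable
fraction of sequences and a low-diversity subfamily inside the motif
carriers, giving the nested sequence sets (family > motif subset >
subfamily) over which entropy tiering is tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .variants import (
    AMINO_ACIDS,
    ALPHABET21,
    MINUS,
    PLUS,
    HomologContext,
    ValidationError,
    build_reference_alignment,
)

RHEOSTAT_CLASSES = {"R", "r"}
ALL_CLASSES = {"R", "r", "T", "N", "n", "x", "3"}


@dataclass(frozen=True)
class HomologSpec:
    homolog_id: str
    parent_activity: float
    parent_sd: float
    del_control: float
    active_condition: str = MINUS

    def context(self, growth_threshold: float = 13.0) -> HomologContext:
        return HomologContext(
            homolog_id=self.homolog_id,
            parent_activity=self.parent_activity,
            parent_sd=self.parent_sd,
            del_control=self.del_control,
            active_condition=self.active_condition,
            growth_threshold=growth_threshold,
        )


@dataclass(frozen=True)
class PositionSpec:
    label: str
    true_class: str
    span_log10: float = 3.0        # rheostat span (R > 2; r uses min(span, 1.5))
    abolished_fraction: float = 0.5  # toggle: fraction of substitutions at DEL


@dataclass(frozen=True)
class MsaConfig:
    n_sequences: int = 500
    motif_fraction: float = 0.6
    concentration: float = 0.5       # Dirichlet concentration, family columns
    subfamily_fraction: float = 0.15  # of all sequences, drawn from motif carriers
    subfamily_concentration: float = 0.05
    conserved_positions: Mapping[str, str] = field(
        default_factory=lambda: dict(reference.YPAL_MOTIF)
    )
    first_position: int = 45
    n_columns: int = 18


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    homologs: tuple[HomologSpec, ...] = ()
    positions: tuple[PositionSpec, ...] = ()
    substitutions_per_position: int = 10
    noise_cv: float = 0.2
    n_replicates: int = 4
    n_allosteric: int = 30
    n_excluded: int = 10
    met_bias: bool = False
    growth_threshold: float = 13.0
    msa: MsaConfig = MsaConfig()

    def validate(self) -> None:
        if not self.homologs or not self.positions:
            raise ValidationError("config needs at least one homolog and position")
        for h in self.homologs:
            if h.parent_activity <= 0 or h.del_control <= 0:
                raise ValidationError(f"{h.homolog_id}: activities must be positive")
        for p in self.positions:
            if p.true_class not in ALL_CLASSES:
                raise ValidationError(f"unknown class {p.true_class!r}")
            if p.true_class == "R" and p.span_log10 <= 2:
                raise ValidationError("class R requires span_log10 > 2")
        if self.noise_cv < 0 or self.n_replicates < 1:
            raise ValidationError("bad noise configuration")
        if not 0 <= self.msa.motif_fraction <= 1:
            raise ValidationError("motif_fraction must be in [0, 1]")

    def contexts(self) -> dict[str, HomologContext]:
        return {h.homolog_id: h.context(self.growth_threshold) for h in self.homologs}


#: Planted benchmark classes for the 12 scanned positions.
DEFAULT_POSITION_CLASSES = {
    "46": "R", "48": "R", "50": "T", "51": "R", "52": "R", "54": "x",
    "55": "N", "58": "R", "59": "N", "60": "N", "61": "T", "62": "R",
}

#: No-repressor control level, Miller units.  Fully induced lacZ reporter
#: activity is of order 10^3 Miller units.
DEFAULT_DEL = 4000.0

#: Parents the study design keeps: weak repressors are replaced by their
#: tighter point-mutant versions (changes in an already-weak repressor are
#: undetectable), so the panel spans 0.06-58 Miller units.
_BENCHMARK_HOMOLOGS = (
    "LacI-11", "LLhR", "LLhF", "LLhG", "LLhG/E62K", "LGhG", "LLhS",
    "LLhS/R51S", "LLhS/D62N", "LLhS/R51S/D62N", "LLhP", "LPhP57cs",
    "LLhT/V52A", "LLhA/Q55A",
)


def default_config(seed: int = 0, noise_cv: float = 0.2) -> SimulationConfig:
    """The benchmark study conditions: 14 homologs x 12 positions x 10
    substitutions, replicate noise cv 0.2, 4 replicates, ~30 planted
    allostery-altering variants and ~10 excluded ones."""
    homologs = tuple(
        HomologSpec(
            homolog_id=h,
            parent_activity=reference.PARENT_REPRESSION[h][0],
            parent_sd=reference.PARENT_REPRESSION[h][1],
            del_control=DEFAULT_DEL,
            active_condition=reference.active_condition(h),
        )
        for h in _BENCHMARK_HOMOLOGS
    )
    positions = tuple(
        PositionSpec(label=pos, true_class=cls)
        for pos, cls in DEFAULT_POSITION_CLASSES.items()
    )
    return SimulationConfig(seed=seed, homologs=homologs, positions=positions,
                            noise_cv=noise_cv)


# ---------------------------------------------------------------------------
# variant dataset


def _true_values(
    rng: np.random.Generator, spec: PositionSpec, parent: float, del_: float, k: int
) -> np.ndarray:
    """True (noise-free) activities for one (homolog, position) cell."""
    cls = spec.true_class
    if cls in ("R", "r"):
        span = spec.span_log10 if cls == "R" else min(spec.span_log10, 1.5)
        lo = math.log10(parent) - span / 2.0
        edges = lo + span * np.arange(k + 1) / k
        vals = 10 ** (edges[:-1] + rng.random(k) * span / k)
        vals = np.clip(vals, 1e-6, del_)
        return rng.permutation(vals)
    if cls == "T":
        n_abol = int(round(spec.abolished_fraction * k))
        n_abol = min(max(n_abol, 1), k - 1)
        vals = np.full(k, float(parent))
        vals[rng.choice(k, size=n_abol, replace=False)] = del_
        return vals
    if cls == "3":
        mid = math.sqrt(parent * del_)
        levels = [parent, mid, del_]
        counts = [k // 3] * 3
        for i in range(k - sum(counts)):
            counts[i] += 1
        vals = np.repeat(levels, counts).astype(float)
        return rng.permutation(vals)
    if cls in ("N", "n"):
        band = math.log10(2.0) if cls == "N" else math.log10(5.0)
        sigma = 0.1 if cls == "N" else 0.35
        offsets = np.clip(rng.normal(0.0, sigma, size=k), -band, band)
        if cls == "n":
            # guarantee the cell leaves the 2-fold band without leaving 5-fold
            i = int(rng.integers(k))
            offsets[i] = math.copysign(
                rng.uniform(math.log10(2.0) + 0.05, band), offsets[i] or 1.0
            )
        return parent * 10 ** offsets
    if cls == "x":
        return np.full(k, del_)
    raise ValidationError(f"unknown class {cls!r}")


def _measure(rng: np.random.Generator, true: float, cv: float, n_reps: int):
    """Replicate-level lognormal noise: returns (mean, sd) over replicates."""
    if cv == 0:
        return float(true), 0.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    reps = true * np.exp(rng.normal(0.0, sigma, size=n_reps) - sigma * sigma / 2.0)
    return float(reps.mean()), float(reps.std(ddof=1))


def _sample_substitutions(rng: np.random.Generator, wt: str, k: int, met_bias: bool):
    pool = [a for a in AMINO_ACIDS if a != wt]
    if met_bias:
        w = np.array([0.3 if a == "M" else 1.0 for a in pool])
        w = w / w.sum()
    else:
        w = None
    return list(rng.choice(pool, size=k, replace=False, p=w))


def simulate_dataset(cfg: SimulationConfig):
    """Generate a variant table, its ground truth, and homolog contexts.

    Returns ``(variants, truth, contexts)``: a variant frame in the standard
    table schema (both effector conditions per variant), a truth frame with
    one row per substitution carrying the planted cell class, the true
    activity and the allostery flag, and the homolog context map.  Fixed
    seed implies identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    contexts = cfg.contexts()
    k = cfg.substitutions_per_position

    cells = []   # (hom, pos, wt, [aa], [true])
    for h in cfg.homologs:
        for p in cfg.positions:
            wt = str(rng.choice(list(AMINO_ACIDS)))
            aas = _sample_substitutions(rng, wt, k, cfg.met_bias)
            true = _true_values(rng, p, h.parent_activity, h.del_control, k)
            cells.append((h, p, wt, aas, true))

    # plant allostery-altering substitutions among variants far enough from
    # the MIN level to be detectable
    eligible = []
    for ci, (h, p, wt, aas, true) in enumerate(cells):
        for vi, t in enumerate(true):
            if t <= h.del_control / 4.0:
                eligible.append((ci, vi))
    n_alt = min(cfg.n_allosteric, len(eligible))
    altered = set()
    if n_alt:
        idx = rng.choice(len(eligible), size=n_alt, replace=False)
        altered = {eligible[i] for i in idx}

    inactive_of = {MINUS: PLUS, PLUS: MINUS}
    var_rows, truth_rows = [], []
    for ci, (h, p, wt, aas, true) in enumerate(cells):
        for vi, (aa, t) in enumerate(zip(aas, true)):
            is_alt = (ci, vi) in altered
            active_val = float(t)
            inactive_val = active_val if is_alt else h.del_control
            for cond, val in (
                (h.active_condition, active_val),
                (inactive_of[h.active_condition], inactive_val),
            ):
                mean, sd = _measure(rng, val, cfg.noise_cv, cfg.n_replicates)
                var_rows.append({
                    "homolog": h.homolog_id, "position": p.label, "wt_aa": wt,
                    "sub_aa": aa, "condition": cond, "mean_miller": mean,
                    "sd_miller": sd, "n_reps": cfg.n_replicates,
                    "excluded": False,
                })
            truth_rows.append({
                "homolog": h.homolog_id, "position": p.label, "sub_aa": aa,
                "true_class": p.true_class, "true_activity": active_val,
                "altered_allostery": is_alt,
            })

    # extra rows emulating variants with no activity in either pull-down
    # assay: kept in the sheet, flagged excluded, dropped from analyses
    taken: set[tuple[int, str]] = set()
    for _ in range(cfg.n_excluded):
        ci = int(rng.integers(len(cells)))
        h, p, wt, aas, _true = cells[ci]
        unused = [a for a in AMINO_ACIDS
                  if a != wt and a not in aas and (ci, a) not in taken]
        if not unused:
            continue
        aa = str(rng.choice(unused))
        taken.add((ci, aa))
        for cond in (h.active_condition, inactive_of[h.active_condition]):
            mean, sd = _measure(rng, h.del_control, cfg.noise_cv, cfg.n_replicates)
            var_rows.append({
                "homolog": h.homolog_id, "position": p.label, "wt_aa": wt,
                "sub_aa": aa, "condition": cond, "mean_miller": mean,
                "sd_miller": sd, "n_reps": cfg.n_replicates, "excluded": True,
            })

    variants = pd.DataFrame(var_rows)
    truth = pd.DataFrame(truth_rows)
    return variants, truth, contexts


# ---------------------------------------------------------------------------
# alignment generator


def simulate_msa(cfg: SimulationConfig):
    """Generate an aligned FASTA-style family with a planted motif subset and
    a low-diversity subfamily nested inside it.

    Returns ``(alignment, truth)``: a ReferenceAlignment whose reference
    ("REF", gapless, a subfamily member) numbers columns from
    ``msa.first_position``, and a truth frame with per-sequence motif and
    subfamily membership.
    """
    cfg.validate()
    m = cfg.msa
    rng = np.random.default_rng(cfg.seed + 9973)
    n, L = m.n_sequences, m.n_columns
    first = m.first_position
    labels = [str(first + i) for i in range(L)]
    conserved_cols = {
        labels.index(str(pos)): aa for pos, aa in m.conserved_positions.items()
        if str(pos) in labels
    }

    symbols = np.array(list(ALPHABET21))
    alpha = np.full(21, m.concentration)
    theta_motif = rng.dirichlet(alpha, size=L)
    theta_plain = rng.dirichlet(alpha, size=L)
    theta_sub = rng.dirichlet(np.full(21, m.subfamily_concentration), size=L)

    has_motif = rng.random(n) < m.motif_fraction
    carriers = np.flatnonzero(has_motif)
    n_sub = min(int(round(m.subfamily_fraction * n)), len(carriers))
    in_subfamily = np.zeros(n, dtype=bool)
    if n_sub:
        in_subfamily[rng.choice(carriers, size=n_sub, replace=False)] = True

    rows = np.empty((n, L), dtype="<U1")
    for j in range(L):
        for group, theta in (
            (~has_motif, theta_plain[j]),
            (has_motif & ~in_subfamily, theta_motif[j]),
            (in_subfamily, theta_sub[j]),
        ):
            idx = np.flatnonzero(group)
            if len(idx):
                rows[idx, j] = symbols[rng.choice(21, size=len(idx), p=theta)]
        if j in conserved_cols:
            rows[has_motif, j] = conserved_cols[j]

    # gapless reference: a motif-carrying subfamily consensus
    ref = np.array([symbols[np.argmax(theta_sub[j][:20])] for j in range(L)])
    for j, aa in conserved_cols.items():
        ref[j] = aa

    ids = ["REF"] + [f"seq{i:04d}" for i in range(n)]
    seqs = ["".join(ref)] + ["".join(r) for r in rows]
    aln = build_reference_alignment(ids, seqs, "REF", reference_offset=first)
    truth = pd.DataFrame({
        "id": ids,
        "has_motif": [True] + list(has_motif),
        "in_subfamily": [True] + list(in_subfamily),
    })
    return aln, truth


# ---------------------------------------------------------------------------
# recovery


def recovery_report(classified: pd.DataFrame, truth: pd.DataFrame):
    """Confusion matrix and accuracy of behavior calls against planted truth.

    ``classified`` needs columns (homolog, position, code); ``truth`` needs
    (homolog, position, true_class), extra rows per substitution are
    deduplicated.  Key mismatches raise with the orphan list.
    """
    pred = classified[["homolog", "position", "code"]].copy()
    tr = truth[["homolog", "position", "true_class"]].drop_duplicates()
    merged = pred.merge(tr, on=["homolog", "position"], how="outer", indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        keys = [f"{r['homolog']}/{r['position']}" for _, r in orphans.iterrows()]
        raise ValidationError(f"keys without counterpart: {keys}")
    confusion = pd.crosstab(merged["true_class"], merged["code"])
    correct = (merged["code"] == merged["true_class"]).sum()
    accuracy = correct / len(merged)
    recall = {
        cls: float((grp["code"] == cls).mean())
        for cls, grp in merged.groupby("true_class")
    }
    return confusion, float(accuracy), recall
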