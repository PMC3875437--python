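"""Domain types and file I/O for variant activity tables, alignments and scales.

Activity is measured in Miller units from a beta-galactosidase reporter:
LOWER values mean TIGHTER repression of the operon.  Every variant row carries
a mean, a standard deviation over independent colonies, and a replicate count,
under one effector condition.  A homolog's context supplies the un-mutated
parent activity, the no-repressor "DEL" control (the MIN level any variant can
reach), which condition is the repression readout, and the growth threshold
below which repression changes alter growth on lactose minimal medium.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET21 = tuple(AMINO_ACIDS) + (GAP,)

MINUS = "minus_effector"
PLUS = "plus_effector"
CONDITIONS = (MINUS, PLUS)

_CONDITION_ALIASES = {
    "minus": MINUS, "-": MINUS, "minus_effector": MINUS, "no_effector": MINUS,
    "plus": PLUS, "+": PLUS, "plus_effector": PLUS, "with_effector": PLUS,
}

#: required columns of a variant table (TSV/CSV)
VARIANT_COLUMNS = (
    "homolog", "position", "wt_aa", "sub_aa", "condition",
    "mean_miller", "sd_miller", "n_reps",
)


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


def normalize_condition(value: str) -> str:
    key = str(value).strip().lower()
    try:
        return _CONDITION_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown effector condition {value!r}") from None


def position_sort_key(label) -> tuple[int, str]:
    """Order reference-position labels numerically, insertion suffixes after.

    Labels are opaque: an integer part plus an optional suffix such as "61a".
    No arithmetic is ever done on them.
    """
    m = re.match(r"^(\d+)([A-Za-z]*)$", str(label).strip())
    if not m:
        raise ValidationError(f"unparseable position label {label!r}")
    return int(m.group(1)), m.group(2).lower()


@dataclass(frozen=True)
class RepressionMeasurement:
    """One variant's assayed activity under one effector condition."""

    homolog_id: str
    position: str
    wildtype_aa: str
    substituted_aa: str
    condition: str
    mean_activity: float
    sd_activity: float
    n_replicates: int
    excluded: bool = False

    def __post_init__(self):
        if self.mean_activity < 0 or self.sd_activity < 0:
            raise ValidationError(
                f"negative activity for {self.homolog_id} {self.position}"
                f"{self.substituted_aa}"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for aa in (self.wildtype_aa, self.substituted_aa):
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"unknown amino-acid letter {aa!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"bad condition {self.condition!r}")


@dataclass(frozen=True)
class HomologContext:
    """Parent activity, DEL control and readout condition for one homolog."""

    homolog_id: str
    parent_activity: float
    parent_sd: float
    del_control: float
    active_condition: str = MINUS
    growth_threshold: float = 13.0

    def __post_init__(self):
        if self.growth_threshold <= 0:
            raise ValidationError("growth_threshold must be positive")
        if self.active_condition not in CONDITIONS:
            raise ValidationError(f"bad condition {self.active_condition!r}")
        if self.parent_activity > 0 and self.del_control <= self.parent_activity:
            raise ValidationError(
                f"{self.homolog_id}: DEL control ({self.del_control}) must "
                f"exceed parent activity ({self.parent_activity})"
            )


@dataclass
class PositionProfile:
    """All substitution outcomes for one (homolog, position), both conditions."""

    homolog: HomologContext
    position: str
    measurements: list[RepressionMeasurement] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for m in self.measurements:
            key = (m.substituted_aa, m.condition)
            if key in seen:
                raise ValidationError(
                    f"duplicate ({m.substituted_aa}, {m.condition}) in profile "
                    f"{self.homolog.homolog_id}/{self.position}; merge clones first"
                )
            seen.add(key)

    def scored(self, condition: str | None = None) -> list[RepressionMeasurement]:
        """Non-excluded measurements, defaulting to the repression readout."""
        cond = condition or self.homolog.active_condition
        return [m for m in self.measurements
                if m.condition == cond and not m.excluded]


@dataclass(frozen=True)
class AminoAcidScale:
    """A named physico-chemical scale: one-letter amino acid -> value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        bad = set(self.values) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(f"scale {self.name}: non-canonical keys {bad}")

    @property
    def missing(self) -> frozenset[str]:
        return frozenset(AMINO_ACIDS) - set(self.values)


@dataclass
class ReferenceAlignment:
    """An aligned sequence set with reference-based column numbering.

    ``column_map`` sends a reference position label (the family's conventional
    1-based numbering, offset applied) to a 0-based alignment column.  Columns
    are positional: subsetting the membership never renumbers them.
    """

    ids: list[str]
    sequences: list[str]
    reference_id: str
    column_map: dict[str, int]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError("ragged alignment: sequences differ in length")
        cols = list(self.column_map.values())
        if len(set(cols)) != len(cols):
            raise ValidationError("column_map is not injective")
        order = sorted(self.column_map, key=position_sort_key)
        if [self.column_map[p] for p in order] != sorted(cols):
            raise ValidationError("column_map does not respect position order")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def column(self, position) -> str:
        try:
            col = self.column_map[str(position)]
        except KeyError:
            raise KeyError(f"position {position!r} not mapped in alignment") from None
        return "".join(seq[col] for seq in self.sequences)

    def subset(self, keep_ids: Iterable[str]) -> "ReferenceAlignment":
        keep = set(keep_ids)
        ids, seqs = [], []
        for i, s in zip(self.ids, self.sequences):
            if i in keep:
                ids.append(i)
                seqs.append(s)
        ref = self.reference_id if self.reference_id in keep else ""
        return ReferenceAlignment(ids, seqs, ref, dict(self.column_map))


# ---------------------------------------------------------------------------
# variant tables


def _merge_clones(group: pd.DataFrame, warnings: list[str]) -> pd.Series:
    """Merge repeat clones of one (homolog, position, aa, condition).

    Separate clones of the same variant agreed within about 2-fold in the
    assay, so repeats are merged to a single value: geometric mean of the
    means, pooled standard deviation, summed replicates.  Pairs differing by
    more than 2-fold are flagged for review but still merged.
    """
    if len(group) == 1:
        return group.iloc[0]
    means = group["mean_miller"].to_numpy(float)
    positive = means[means > 0]
    ratio = positive.max() / positive.min() if len(positive) else 1.0
    if ratio > 2 or len(positive) < len(means):
        row = group.iloc[0]
        warnings.append(
            f"clones differ >2-fold for {row['homolog']} {row['position']}"
            f"{row['sub_aa']} ({row['condition']}): {sorted(means)}"
        )
    gm = float(np.exp(np.mean(np.log(np.maximum(means, 1e-300))))) if np.all(
        means > 0) else float(means.mean())
    n = group["n_reps"].to_numpy(int)
    s = group["sd_miller"].to_numpy(float)
    dof = np.maximum(n - 1, 0)
    pooled = math.sqrt(float((dof * s**2).sum() / dof.sum())) if dof.sum() else float(s.mean())
    out = group.iloc[0].copy()
    out["mean_miller"] = gm
    out["sd_miller"] = pooled
    out["n_reps"] = int(n.sum())
    out["excluded"] = bool(group["excluded"].any())
    return out


def read_variant_table(
    path,
    contexts: Mapping[str, HomologContext] | None = None,
    sep: str | None = None,
    warnings: list[str] | None = None,
) -> pd.DataFrame:
    """Read a variant activity table (CSV or TSV) into a validated frame.

    Repeat clones of the same (homolog, position, substitution, condition)
    are merged by geometric mean / pooled sd; pairs differing >2-fold are
    reported through ``warnings``.  Rows flagged ``excluded`` are kept in the
    frame (they stay in the data sheet) but carry the flag for downstream
    stages to drop.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"position": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table missing column(s): {', '.join(missing)}")
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    df["condition"] = df["condition"].map(normalize_condition)
    df["position"] = df["position"].astype(str)
    for idx, row in df.iterrows():
        if row["mean_miller"] < 0 or row["sd_miller"] < 0:
            raise ValidationError(f"row {idx}: negative activity value")
        for aa in (row["wt_aa"], row["sub_aa"]):
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"row {idx}: unknown amino-acid letter {aa!r}")
    if warnings is None:
        warnings = []
    key = ["homolog", "position", "sub_aa", "condition"]
    if len(df) and df.duplicated(key).any():
        rows = [_merge_clones(g, warnings) for _, g in df.groupby(key, sort=False)]
        df = pd.DataFrame(rows).reset_index(drop=True)
    if len(df):
        df = df[list(VARIANT_COLUMNS) + ["excluded"]]
    if contexts is not None:
        unknown = set(df["homolog"]) - set(contexts)
        if unknown:
            raise ValidationError(f"homologs without context: {sorted(unknown)}")
    return df


def read_contexts(path, sep: str | None = None) -> dict[str, HomologContext]:
    """Read a homolog-context table (columns: homolog, parent_miller,
    parent_sd, del_control, active_condition, growth_threshold)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = ["homolog", "parent_miller", "parent_sd", "del_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"context table missing column(s): {', '.join(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row["homolog"]] = HomologContext(
            homolog_id=row["homolog"],
            parent_activity=float(row["parent_miller"]),
            parent_sd=float(row["parent_sd"]),
            del_control=float(row["del_control"]),
            active_condition=normalize_condition(row.get("active_condition", MINUS)),
            growth_threshold=float(row.get("growth_threshold", 13.0)),
        )
    return out


def contexts_to_frame(contexts: Mapping[str, HomologContext]) -> pd.DataFrame:
    rows = [
        {
            "homolog": c.homolog_id,
            "parent_miller": c.parent_activity,
            "parent_sd": c.parent_sd,
            "del_control": c.del_control,
            "active_condition": c.active_condition,
            "growth_threshold": c.growth_threshold,
        }
        for c in contexts.values()
    ]
    return pd.DataFrame(rows)


def profiles_from_frame(
    df: pd.DataFrame, contexts: Mapping[str, HomologContext]
) -> list[PositionProfile]:
    """Group a variant frame into per-(homolog, position) profiles."""
    profiles = []
    for (hom, pos), group in df.groupby(["homolog", "position"], sort=False):
        ms = [
            RepressionMeasurement(
                homolog_id=hom,
                position=str(pos),
                wildtype_aa=row["wt_aa"],
                substituted_aa=row["sub_aa"],
                condition=row["condition"],
                mean_activity=float(row["mean_miller"]),
                sd_activity=float(row["sd_miller"]),
                n_replicates=int(row["n_reps"]),
                excluded=bool(row["excluded"]),
            )
            for _, row in group.iterrows()
        ]
        profiles.append(PositionProfile(contexts[hom], str(pos), ms))
    return profiles


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path, reference_id: str, reference_offset: int = 1) -> ReferenceAlignment:
    """Read an aligned FASTA and number columns from the reference sequence.

    The reference's non-gap characters are numbered consecutively starting at
    ``reference_offset``; those labels key ``column_map``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no sequences in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if len({len(s) for s in seqs}) > 1:
        raise ValidationError("ragged alignment: sequences differ in length")
    if reference_id not in ids:
        raise KeyError(f"reference {reference_id!r} not found in alignment")
    return build_reference_alignment(ids, seqs, reference_id, reference_offset)


def build_reference_alignment(
    ids: Sequence[str], seqs: Sequence[str], reference_id: str,
    reference_offset: int = 1,
) -> ReferenceAlignment:
    ref_seq = seqs[list(ids).index(reference_id)]
    column_map: dict[str, int] = {}
    pos = reference_offset
    for col, ch in enumerate(ref_seq):
        if ch != GAP:
            column_map[str(pos)] = col
            pos += 1
    return ReferenceAlignment(list(ids), list(seqs), reference_id, column_map)


def write_alignment(aln: ReferenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.sequences):
            fh.write(f">{i}\n{s}\n")


# ---------------------------------------------------------------------------
# scales and reports


def read_scales(path, sep: str | None = None) -> dict[str, AminoAcidScale]:
    """Read physico-chemical scales from a long-format CSV
    (columns: scale_name, aa, value)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("scale_name", "aa", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"scales table missing column(s): {', '.join(missing)}")
    scales = {}
    for name, group in df.groupby("scale_name"):
        scales[name] = AminoAcidScale(
            name=name,
            values={row["aa"]: float(row["value"]) for _, row in group.iterrows()},
        )
    return scales


def builtin_scales() -> dict[str, AminoAcidScale]:
    """Physico-chemical scales shipped with the package.

    Currently the Kyte-Doolittle hydropathy index (via biopython); users
    supply further scales (helix propensity, side-chain area, ...) as a CSV
    through :func:`read_scales`.
    """
    from Bio.SeqUtils.ProtParamData import kd

    return {"hydropathy_kd": AminoAcidScale("hydropathy_kd", dict(kd))}


def write_report(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a result table as TSV; reading it back recovers the values."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"position": str})


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)
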