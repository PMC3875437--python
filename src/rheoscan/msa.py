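"""Column frequencies, gap-inclusive sequence entropy, and motif subsetting.

Conservation of an alignment column is quantified by Shannon entropy over a
21-symbol alphabet (20 amino acids plus the gap character):

    H = -sum_i f_i ln f_i     (nats)

so H = 0 is perfect conservation and H = ln 21 ~ 3.04 is maximal diversity.
A motif (for the LacI/GalR linker, the YPAL residues Tyr47/Pro49/Ala53/Leu56)
defines a subfamily of the alignment; restricting the sequence set before
computing entropies is what separates functional toggles (near-zero entropy
in the motif subset) from rheostats (entropy >= ~0.6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from .variants import ALPHABET21, AMINO_ACIDS, GAP, ReferenceAlignment, position_sort_key

logger = logging.getLogger(__name__)

MAX_ENTROPY = math.log(21)

TOGGLE_CANDIDATE = "toggle_candidate"
RHEOSTAT_CANDIDATE = "rheostat_candidate"
INTERMEDIATE = "intermediate"


@dataclass
class ColumnFrequencies:
    """Relative symbol frequencies of one alignment column (21 symbols)."""

    position: str
    freqs: dict[str, float]
    n_sequences: int

    def __post_init__(self):
        total = sum(self.freqs.values())
        if self.n_sequences > 0 and abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {total}, not 1")

    def frequency(self, symbol: str) -> float:
        return self.freqs.get(symbol, 0.0)


@dataclass(frozen=True)
class MotifSpec:
    """Required amino acids at reference positions, e.g. 47:Y 49:P 53:A 56:L."""

    constraints: Mapping[str, str]

    def __post_init__(self):
        if not self.constraints:
            raise ValueError("motif must constrain at least one position")

    @classmethod
    def parse(cls, text: str) -> "MotifSpec":
        """Parse a compact motif string like ``"47:Y,49:P,53:A,56:L"``."""
        constraints = {}
        for item in text.split(","):
            pos, _, aa = item.strip().partition(":")
            if not aa or aa.upper() not in AMINO_ACIDS:
                raise ValueError(f"bad motif constraint {item!r}")
            constraints[pos.strip()] = aa.upper()
        return cls(constraints)


def column_frequencies(aln: ReferenceAlignment, position) -> ColumnFrequencies:
    """Symbol frequencies over the 21-letter alphabet for one reference position.

    Ambiguity codes and any non-canonical character are counted as gap (the
    alphabet admits only the 20 amino acids and the gap symbol); a warning is
    logged when that happens.
    """
    column = aln.column(position)
    counts = {s: 0 for s in ALPHABET21}
    oddballs = 0
    for ch in column.upper():
        if ch in counts and ch != GAP:
            counts[ch] += 1
        else:
            if ch != GAP and ch != ".":
                oddballs += 1
            counts[GAP] += 1
    if oddballs:
        logger.warning(
            "position %s: %d non-canonical letter(s) counted as gap",
            position, oddballs,
        )
    n = len(column)
    freqs = {s: c / n for s, c in counts.items()} if n else {s: 0.0 for s in counts}
    return ColumnFrequencies(position=str(position), freqs=freqs, n_sequences=n)


def sequence_entropy(freqs: ColumnFrequencies) -> float:
    """Gap-inclusive Shannon entropy of a column, in nats (0 .. ln 21)."""
    p = np.array([freqs.freqs.get(s, 0.0) for s in ALPHABET21], dtype=float)
    return float(_shannon(p))  # natural log; 0*ln(0) treated as 0


def entropy_table(aln: ReferenceAlignment, positions=None, set_name: str = "") -> pd.Series:
    """Entropies for a set of reference positions (all mapped ones by default)."""
    if positions is None:
        positions = sorted(aln.column_map, key=position_sort_key)
    values = {
        str(p): sequence_entropy(column_frequencies(aln, p)) for p in positions
    }
    return pd.Series(values, name=set_name or "entropy")


def subset_by_motif(aln: ReferenceAlignment, motif: MotifSpec) -> ReferenceAlignment:
    """Keep exactly the sequences matching every motif constraint.

    Matching is exact-letter and case-insensitive; a gap at a motif position
    is a mismatch.  Columns keep their numbering (the column map is
    positional), and the reference sequence is retained only if it matches.
    """
    for pos in motif.constraints:
        if str(pos) not in aln.column_map:
            raise KeyError(f"motif position {pos!r} not mapped in alignment")
    keep = []
    for sid, seq in zip(aln.ids, aln.sequences):
        if all(seq[aln.column_map[str(p)]].upper() == aa
               for p, aa in motif.constraints.items()):
            keep.append(sid)
    if not keep:
        logger.warning("motif %s matched no sequences", dict(motif.constraints))
    return aln.subset(keep)


def tier_separation(
    entropies: Mapping[str, float] | pd.Series,
    toggle_cut: float = 0.1,
    rheostat_cut: float = 0.6,
) -> pd.Series:
    """Separate toggle from rheostat candidates by motif-subset entropy.

    H < toggle_cut labels a toggle candidate; H >= rheostat_cut a rheostat
    candidate; anything between is intermediate.  Ties follow the inequality
    directions: H exactly at rheostat_cut is a rheostat candidate, H exactly
    at toggle_cut is intermediate.
    """
    labels = {}
    for pos, h in dict(entropies).items():
        if h < toggle_cut:
            labels[str(pos)] = TOGGLE_CANDIDATE
        elif h >= rheostat_cut:
            labels[str(pos)] = RHEOSTAT_CANDIDATE
        else:
            labels[str(pos)] = INTERMEDIATE
    return pd.Series(labels, name="tier")


def entropy_report(
    aln: ReferenceAlignment,
    motif: MotifSpec | None = None,
    subfamily_ids=None,
    positions=None,
    toggle_cut: float = 0.1,
    rheostat_cut: float = 0.6,
) -> pd.DataFrame:
    """Per-position entropies for the full set, the motif subset and an
    optional subfamily, with the tier label computed on the motif subset
    (or on the full set when no motif is given)."""
    if positions is None:
        positions = sorted(aln.column_map, key=position_sort_key)
    out = pd.DataFrame({"position": [str(p) for p in positions]})
    out["H_all"] = entropy_table(aln, positions).to_numpy()
    tier_basis = out["H_all"]
    if motif is not None:
        sub = subset_by_motif(aln, motif)
        out["H_motif"] = entropy_table(sub, positions).to_numpy()
        tier_basis = out["H_motif"]
    if subfamily_ids is not None:
        fam = aln.subset(subfamily_ids)
        out["H_subfamily"] = entropy_table(fam, positions).to_numpy()
    out["tier"] = tier_separation(
        pd.Series(tier_basis.to_numpy(), index=out["position"]),
        toggle_cut, rheostat_cut,
    ).to_numpy()
    return out
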