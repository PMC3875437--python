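"""Published reference values for the LacI/GalR linker scanning family.

These are the printed summary numbers of the LacI/GalR parallel-mutagenesis
study of linker positions 45-62: parent-protein repression values for the
LXhX chimera panel, gap-inclusive sequence entropies of each linker position
computed over three nested alignments (the whole family, the YPAL-motif
subset, and the LacI ortholog subfamily), and the per-position enhancement
counts.  They serve as fixed inputs for tier separation, as generator
defaults, and as ground truth for checking the enhancement-percentage
formula; they are not recomputed by this package (building the underlying
alignments requires a database search that is out of scope).
"""

from __future__ import annotations

from .variants import MINUS, PLUS

#: Parent repression in Miller units (mean, sd) for the chimera panel.
#: Lower = tighter repression.  PurR-based chimeras are co-repressible: their
#: repression readout is the plus-effector condition.
PARENT_REPRESSION: dict[str, tuple[float, float]] = {
    "LacI-11": (0.12, 0.06),
    "LLhR": (0.06, 0.06),
    "LLhF": (1.9, 0.3),
    "LLhG": (15.0, 4.0),
    "LLhG/E62K": (0.7, 0.2),
    "LGhG": (13.0, 11.0),
    "LLhS": (6.0, 4.0),
    "LLhS/R51S": (58.0, 20.0),
    "LLhS/D62N": (3.0, 1.0),
    "LLhS/R51S/D62N": (0.06, 0.03),
    "LLhP": (3.9, 2.2),
    "LPhP57cs": (37.0, 5.0),
    "LGhP": (320.0, 130.0),
    "LLhT": (120.0, 16.0),
    "LLhT/V52A": (0.5, 0.1),
    "LLhA": (78.0, 10.0),
    "LLhA/Q55A": (0.2, 0.04),
}

#: Chimeras whose repression readout is measured WITH effector (co-repressible,
#: PurR regulatory domain); all others are read out without effector.
COREPRESSIBLE = frozenset({"LLhP", "LPhP57cs", "LGhP"})


def active_condition(homolog: str) -> str:
    return PLUS if homolog in COREPRESSIBLE else MINUS


#: Growth threshold in Miller units: repression tighter than this is the
#: regime where any further change alters growth on lactose minimal medium.
GROWTH_THRESHOLD = 13.0

#: The twelve nonconserved linker positions mutated across the panel.
MUTATED_POSITIONS = ("46", "48", "50", "51", "52", "54", "55",
                     "58", "59", "60", "61", "62")

#: The conserved YPAL motif of the linker.
YPAL_MOTIF = {"47": "Y", "49": "P", "53": "A", "56": "L"}

#: Sequence entropies (nats, 21-symbol alphabet) of linker positions 45-62
#: over the whole family alignment, the YPAL-motif subset, and the LacI
#: ortholog subfamily.
LINKER_ENTROPY = {
    #        all,  YPAL, subfamily
    "45": (1.20, 1.01, 0.00),
    "46": (1.56, 1.62, 0.86),
    "47": (0.24, 0.07, 0.00),
    "48": (2.25, 1.99, 0.93),
    "49": (0.70, 0.00, 0.00),
    "50": (1.20, 0.60, 0.00),
    "51": (2.15, 1.92, 0.07),
    "52": (2.24, 1.80, 0.93),
    "53": (0.91, 0.00, 0.00),
    "54": (1.37, 0.82, 0.00),
    "55": (2.21, 1.67, 0.37),
    "56": (0.96, 0.00, 0.00),
    "57": (1.98, 1.70, 0.36),
    "58": (2.37, 2.26, 0.20),
    "59": (2.14, 1.66, 0.20),
    "60": (2.28, 2.16, 1.28),
    "61": (1.68, 1.03, 1.07),
    "62": (2.30, 2.18, 1.47),
}


def entropy_column(which: str) -> dict[str, float]:
    """One entropy column: ``"all"``, ``"ypal"`` or ``"subfamily"``."""
    idx = {"all": 0, "ypal": 1, "subfamily": 2}[which]
    return {pos: vals[idx] for pos, vals in LINKER_ENTROPY.items()}


#: Per-position enhancement counts: total variants (parents counted once),
#: substitutions enhancing repression >10-fold, parent proteins mutated,
#: parent proteins with at least one enhancing substitution, and the printed
#: rounded percentage.
ENHANCEMENT_COUNTS = {
    #        total, enhanced, parents, parents_enh, pct
    "46": (114, 4, 13, 2, 4),
    "48": (102, 1, 14, 1, 1),
    "50": (96, 0, 14, 0, 0),
    "51": (100, 10, 13, 5, 11),
    "52": (113, 7, 14, 7, 7),
    "54": (117, 1, 13, 1, 1),
    "55": (113, 9, 14, 5, 9),
    "58": (95, 5, 13, 3, 6),
    "59": (101, 1, 14, 1, 1),
    "60": (107, 3, 14, 3, 3),
    "61": (92, 2, 14, 1, 3),
    "62": (126, 21, 13, 6, 19),
}
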