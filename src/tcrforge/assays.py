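"""Small assay arithmetic: specific killing, peptide scans, normalizations.

These are the defined formulas used to post-process functional readouts:
the flow-cytometry specific-killing equation, alanine/serine scanning of
peptide epitopes, background subtraction of irrelevant-peptide responses,
and fold-change normalization to a reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AMINO_ACIDS


@dataclass(frozen=True)
class Peptide:
    """An MHC-class-I-sized peptide (8-11 residues)."""

    sequence: str

    def __post_init__(self):
        if not 8 <= len(self.sequence) <= 11:
            raise ValueError(f"peptide length {len(self.sequence)} outside 8-11")
        if not set(self.sequence) <= set(AMINO_ACIDS):
            raise ValueError(f"peptide {self.sequence!r} contains invalid characters")

    def __str__(self) -> str:
        return self.sequence


@dataclass(frozen=True)
class KillingAssayInput:
    """Relevant/irrelevant target ratios with and without effector T cells."""

    ratio_with_t_cells: float
    ratio_without_t_cells: float

    def __post_init__(self):
        if self.ratio_with_t_cells < 0:
            raise ValueError("ratio with T cells must be non-negative")
        if self.ratio_without_t_cells <= 0:
            raise ValueError("ratio without T cells must be positive")


def specific_killing(input: KillingAssayInput) -> float:
    """% specific killing = 100 - (ratio with T cells / ratio without) x 100.

    The value may be negative (targets gained relative to control); it is
    reported as-is.
    """
    return 100.0 - (input.ratio_with_t_cells / input.ratio_without_t_cells) * 100.0


def alanine_scan(peptide: Peptide | str) -> list[Peptide]:
    """Single-position alanine scan with the serine rule.

    Each native residue is replaced with alanine; where the native residue
    is already alanine it is replaced with serine instead.  One variant
    per position, in position order.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    seq = peptide.sequence
    variants = []
    for i, native in enumerate(seq):
        substitute = "S" if native == "A" else "A"
        variants.append(Peptide(seq[:i] + substitute + seq[i + 1 :]))
    return variants


def net_response(cognate: float, irrelevant: float, *, floor: bool = True) -> float:
    """Background-subtracted response: cognate minus irrelevant stimulation.

    Floored at zero by default (figure-legend convention); pass
    ``floor=False`` for the raw difference.
    """
    diff = cognate - irrelevant
    return max(0.0, diff) if floor else diff


def fold_change(value: float, reference: float) -> float:
    """Value expressed as a fold change over a positive reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return value / reference
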