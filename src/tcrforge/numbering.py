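"""IMGT unique numbering of TCR V domains and the framework position mask.

The IMGT unique numbering scheme places every V-domain residue at a fixed
1-128 coordinate so that positions are comparable across genes and chains.
Region boundaries are fixed: FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65,
FR3 66-104, CDR3 105-117, FR4 118-128.  Conserved anchors are the 1st-CYS
at 23, the conserved tryptophan at 41, and the 2nd-CYS at 104.

Numbering here is template-based: clonotypes arrive with a V-gene call, so
the germline supplies positions 1-104 (with its gap pattern) and the
junctional CDR3 is spliced into 105-117 using the IMGT center-out rule.
Profile/HMM numbering of unannotated sequences is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io import (
    AMINO_ACIDS,
    CHAINS,
    GermlineGene,
    GermlineSet,
    read_gapped_fasta,
)

logger = logging.getLogger(__name__)

#: (region, first position, last position), inclusive, in scheme order.
REGION_BOUNDS = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
    ("FR4", 118, 128),
)

FIRST_CYS, CONSERVED_TRP, SECOND_CYS = 23, 41, 104
CDR3_START, CDR3_END = 105, 117
MAX_CDR3_LENGTH = CDR3_END - CDR3_START + 1  # 13; insertions (111.1 etc.) unsupported
MIN_CDR3_LENGTH = 5

#: Framework gap pattern of the packaged reference convention.  Five FR
#: positions per chain are unoccupied in every reference gene, so each
#: chain's FR1-FR3 mask holds 82 - 5 = 77 positions.
DEFAULT_FRAMEWORK_GAPS = {
    "alpha": (10, 73, 81, 82, 83),
    "beta": (73, 81, 82, 83, 84),
}

_REFERENCE_FASTA = "germline_reference_synthetic.fasta"


def region_of(position: int) -> str:
    """Region label for an IMGT position (total on 1-128)."""
    for region, lo, hi in REGION_BOUNDS:
        if lo <= position <= hi:
            return region
    raise ValueError(f"position {position} outside IMGT range 1-128")


@dataclass
class NumberedDomain:
    """A V domain indexed by IMGT position, with region labels."""

    chain: str
    residues: dict[int, str]
    source_gene: str
    anchor_warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}")
        for pos, aa in self.residues.items():
            if not 1 <= pos <= 128:
                raise ValueError(f"position {pos} outside IMGT range 1-128")
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {aa!r} at position {pos}")

    @property
    def regions(self) -> dict[int, str]:
        return {pos: region_of(pos) for pos in self.residues}

    def cdr_positions(self) -> list[int]:
        return sorted(p for p in self.residues if region_of(p).startswith("CDR"))


@dataclass(frozen=True)
class FrameworkMask:
    """Ordered set of IMGT positions counted as framework for one chain.

    FR4 is excluded: it is J-encoded and the statistics compare V-domain
    frameworks (77 positions per chain under the packaged convention).
    """

    chain: str
    positions: tuple[int, ...]

    def __post_init__(self):
        for p in self.positions:
            if region_of(p).startswith("CDR") or region_of(p) == "FR4":
                raise ValueError(f"position {p} ({region_of(p)}) is not FR1-FR3")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("mask positions must be strictly ascending")

    def __contains__(self, position: int) -> bool:
        return position in set(self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def cdr3_position_map(length: int) -> list[int]:
    """IMGT positions occupied by a CDR3 of the given length.

    Center-out rule: ceil(L/2) residues fill 105 upward, floor(L/2) fill
    117 downward, leaving the gap (if any) in the middle of the loop.
    """
    if not MIN_CDR3_LENGTH <= length <= MAX_CDR3_LENGTH:
        raise ValueError(
            f"CDR3 length {length} outside supported range "
            f"{MIN_CDR3_LENGTH}-{MAX_CDR3_LENGTH} (IMGT insertions unsupported)"
        )
    n_front = (length + 1) // 2
    n_back = length // 2
    return list(range(CDR3_START, CDR3_START + n_front)) + list(
        range(CDR3_END - n_back + 1, CDR3_END + 1)
    )


def number_v_domain(gene: GermlineGene, cdr3_aa: str) -> NumberedDomain:
    """Place a clonotype's residues at their IMGT coordinates.

    V-segment residues come from the gene's gapped sequence; the CDR3 is
    spliced into 105-117.  A missing anchor cysteine is recorded as a
    warning flag rather than a rejection.
    """
    residues: dict[int, str] = {}
    for pos in range(1, len(gene.gapped_seq) + 1):
        aa = gene.residue(pos)
        if aa is not None:
            residues[pos] = aa
    positions = cdr3_position_map(len(cdr3_aa))
    for pos, aa in zip(positions, cdr3_aa):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"CDR3 residue {aa!r} is not an amino acid")
        residues[pos] = aa
    warnings = []
    for anchor, label in ((FIRST_CYS, "1st-CYS C23"), (SECOND_CYS, "2nd-CYS C104")):
        if residues.get(anchor) != "C":
            warnings.append(f"missing anchor {label} in {gene.name}")
    if warnings:
        logger.warning("%s: %s", gene.name, "; ".join(warnings))
    return NumberedDomain(
        chain=gene.chain,
        residues=residues,
        source_gene=gene.name,
        anchor_warnings=warnings,
    )


def residue_at(domain: NumberedDomain, position: int) -> str | None:
    """Residue at an IMGT position, or None where the domain has a gap."""
    if not 1 <= position <= 128:
        raise ValueError(f"position {position} outside IMGT range 1-128")
    return domain.residues.get(position)


def build_framework_mask(germline_set: GermlineSet, chain: str) -> FrameworkMask:
    """Union of occupied FR1-FR3 positions across a chain's germline genes."""
    genes = germline_set.by_chain(chain)
    if not genes:
        raise ValueError(f"germline set contains no {chain}-chain genes")
    occupied: set[int] = set()
    for gene in genes:
        for pos in range(1, len(gene.gapped_seq) + 1):
            if gene.residue(pos) is not None and region_of(pos) in ("FR1", "FR2", "FR3"):
                occupied.add(pos)
    return FrameworkMask(chain=chain, positions=tuple(sorted(occupied)))


def validate_anchors(gene: GermlineGene) -> list[str]:
    """Check the conserved C23 / W41 / C104 anchors of a germline V segment."""
    problems = []
    for pos, expected, label in (
        (FIRST_CYS, "C", "1st-CYS"),
        (CONSERVED_TRP, "W", "CONSERVED-TRP"),
        (SECOND_CYS, "C", "2nd-CYS"),
    ):
        if gene.residue(pos) != expected:
            problems.append(f"{gene.name}: expected {label} {expected}{pos}, found {gene.residue(pos)}")
    return problems


def load_reference_germlines() -> GermlineSet:
    """Load the packaged reference germline set.

    The packaged set is a synthetic stand-in for the IMGT reference
    directory: fabricated sequences carrying the documented residue
    identities of each covered gene at their IMGT positions, with anchors
    and the packaged gap convention.
    """
    with resources.as_file(
        resources.files("tcrforge.data").joinpath(_REFERENCE_FASTA)
    ) as p:
        return read_gapped_fasta(Path(p))


def write_mask_tsv(mask: FrameworkMask, path: str | Path) -> None:
    lines = ["chain\timgt_position"] + [f"{mask.chain}\t{p}" for p in mask.positions]
    Path(path).write_text("\n".join(lines) + "\n")
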