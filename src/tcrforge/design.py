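"""Framework substitution plans for TCR alpha/beta pairs.

Plans are ordered edit lists (chain, IMGT position, from, to) restricted to
framework positions, applied atomically with a from-residue audit check so
that a stale plan can never silently corrupt a sequence.  The canonical
plans are the LRY triple (L96a + R9b + Y10b, the minimal stabilizing set)
and full conversions between the weak and dominant identities of the
curated 14-residue candidate set.  CDR loops are never touched, so antigen
specificity is preserved by construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources
from pathlib import Path

from .candidates import CandidateResidue
from .io import AMINO_ACIDS, GermlineSet
from .numbering import NumberedDomain, number_v_domain, region_of, residue_at

logger = logging.getLogger(__name__)

#: The minimal stabilizing substitution set: target residues at the V-C
#: interface positions alpha-96, beta-9 and beta-10.
LRY_TARGETS = (("alpha", 96, "L"), ("beta", 9, "R"), ("beta", 10, "Y"))

_CLASSES_TSV = "biochemical_classes.tsv"


@dataclass(frozen=True)
class Edit:
    chain: str
    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self):
        if region_of(self.position) not in ("FR1", "FR2", "FR3"):
            raise ValueError(
                f"edit at position {self.position} ({region_of(self.position)}) "
                "is outside the FR1-FR3 framework"
            )
        if self.from_aa == self.to_aa:
            raise ValueError(f"edit at {self.position} does not change the residue")
        for aa in (self.from_aa, self.to_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {aa!r}")

    def __str__(self) -> str:
        greek = {"alpha": "a", "beta": "b"}[self.chain]
        return f"{self.from_aa}{self.position}{greek}{self.to_aa}"


@dataclass(frozen=True)
class SubstitutionPlan:
    edits: tuple[Edit, ...]
    label: str

    def __post_init__(self):
        positions = [(e.chain, e.position) for e in self.edits]
        if len(positions) != len(set(positions)):
            raise ValueError("plan edits must target unique positions per chain")

    def __len__(self) -> int:
        return len(self.edits)


@dataclass(frozen=True)
class TCRPair:
    """A named TCR with numbered alpha and beta V domains."""

    name: str
    alpha: NumberedDomain
    beta: NumberedDomain
    edit_log: tuple[str, ...] = ()

    def __post_init__(self):
        if self.alpha.chain != "alpha" or self.beta.chain != "beta":
            raise ValueError("TCRPair requires one alpha and one beta domain")

    def domain(self, chain: str) -> NumberedDomain:
        return self.alpha if chain == "alpha" else self.beta


def build_tcr_pair(
    name: str,
    alpha_gene: str,
    beta_gene: str,
    cdr3_alpha: str,
    cdr3_beta: str,
    germline_set: GermlineSet | None = None,
) -> TCRPair:
    """Number a TCR pair from germline gene calls and CDR3 sequences."""
    if germline_set is None:
        from .numbering import load_reference_germlines

        germline_set = load_reference_germlines()
    return TCRPair(
        name=name,
        alpha=number_v_domain(germline_set.resolve(alpha_gene), cdr3_alpha),
        beta=number_v_domain(germline_set.resolve(beta_gene), cdr3_beta),
    )


def build_lry_plan(tcr: TCRPair) -> SubstitutionPlan:
    """Plan the LRY stabilization (alpha96->L, beta9->R, beta10->Y).

    Positions already carrying the target residue need no edit; a gapped
    required position is an error naming it.
    """
    edits = []
    for chain, position, target in LRY_TARGETS:
        current = residue_at(tcr.domain(chain), position)
        if current is None:
            raise ValueError(f"{tcr.name}: required position {position} ({chain}) is gapped")
        if current != target:
            edits.append(Edit(chain=chain, position=position, from_aa=current, to_aa=target))
    return SubstitutionPlan(edits=tuple(edits), label="LRY")


def build_conversion_plan(
    tcr: TCRPair,
    candidates: list[CandidateResidue],
    direction: str,
) -> SubstitutionPlan:
    """Convert a TCR between the weak and dominant candidate identities.

    For ``to_dominant``, every candidate position currently carrying the
    weak identity is edited to the dominant identity (and vice versa for
    ``to_weak``).  Positions matching neither identity, or gapped in this
    TCR, are skipped with a warning.
    """
    if direction not in ("to_dominant", "to_weak"):
        raise ValueError("direction must be 'to_dominant' or 'to_weak'")
    edits = []
    for cand in sorted(candidates, key=lambda c: (c.chain, c.position)):
        current = residue_at(tcr.domain(cand.chain), cand.position)
        expect, target = (
            (cand.weak_aa, cand.dominant_aa)
            if direction == "to_dominant"
            else (cand.dominant_aa, cand.weak_aa)
        )
        if current is None:
            logger.warning("%s: candidate position %s%d gapped, skipped", tcr.name, cand.chain, cand.position)
            continue
        if current == target:
            continue
        if current != expect:
            logger.warning(
                "%s: %s%d carries %s, matching neither identity (%s/%s); skipped",
                tcr.name, cand.chain, cand.position, current, cand.dominant_aa, cand.weak_aa,
            )
            continue
        edits.append(Edit(chain=cand.chain, position=cand.position, from_aa=current, to_aa=target))
    label = "weak->dom" if direction == "to_dominant" else "dom->weak"
    return SubstitutionPlan(edits=tuple(edits), label=label)


def apply_plan(tcr: TCRPair, plan: SubstitutionPlan) -> TCRPair:
    """Apply a plan atomically, returning a new TCR pair.

    Every edit's from-residue must match the current sequence; otherwise
    nothing is applied.  CDR residues are untouched by construction (edits
    are framework-only).
    """
    for e in plan.edits:
        current = residue_at(tcr.domain(e.chain), e.position)
        if current != e.from_aa:
            raise ValueError(
                f"{tcr.name}: plan {plan.label!r} expects {e.from_aa} at "
                f"{e.chain}{e.position} but found {current}"
            )
    new_residues = {"alpha": dict(tcr.alpha.residues), "beta": dict(tcr.beta.residues)}
    for e in plan.edits:
        new_residues[e.chain][e.position] = e.to_aa
    return TCRPair(
        name=tcr.name,
        alpha=NumberedDomain(
            chain="alpha", residues=new_residues["alpha"], source_gene=tcr.alpha.source_gene
        ),
        beta=NumberedDomain(
            chain="beta", residues=new_residues["beta"], source_gene=tcr.beta.source_gene
        ),
        edit_log=tcr.edit_log + tuple(f"{plan.label}:{e}" for e in plan.edits),
    )


# ---------------------------------------------------------------------------
# biochemical-equivalence expansion


def load_biochemical_classes() -> dict[str, str]:
    """Packaged residue classes (class name -> member residues, in order)."""
    from .candidates import _read_tsv

    return {r["class"]: r["members"] for r in _read_tsv(_CLASSES_TSV)}


def class_of(aa: str, classes: dict[str, str] | None = None) -> str:
    """Primary biochemical class of a residue: first class containing it."""
    classes = classes or load_biochemical_classes()
    for name, members in classes.items():
        if aa in members:
            return name
    raise KeyError(f"residue {aa!r} not covered by the class table")


def equivalence_variants(
    plan: SubstitutionPlan,
    classes: dict[str, str] | None = None,
    *,
    positions: set[tuple[str, int]] | None = None,
    cap: int = 256,
) -> list[SubstitutionPlan]:
    """Expand a plan into biochemically equivalent alternatives.

    Each edit's target is replaced by every member of its biochemical
    class (skipping members equal to the from-residue); the Cartesian
    product over edits is returned, capped.  ``positions`` restricts the
    expansion to a subset of edited positions, leaving other edits fixed.
    """
    classes = classes or load_biochemical_classes()
    alternatives = []
    for e in plan.edits:
        if positions is not None and (e.chain, e.position) not in positions:
            alternatives.append([e.to_aa])
            continue
        members = classes[class_of(e.to_aa, classes)]
        alternatives.append([aa for aa in members if aa != e.from_aa])
    total = 1
    for alt in alternatives:
        total *= len(alt)
    if total > cap:
        raise ValueError(f"equivalence expansion would produce {total} plans (cap {cap})")
    variants = []
    for combo in itertools.product(*alternatives):
        edits = tuple(
            dc_replace(e, to_aa=aa) for e, aa in zip(plan.edits, combo)
        )
        label = plan.label if combo == tuple(e.to_aa for e in plan.edits) else (
            plan.label + "~" + "".join(combo)
        )
        variants.append(SubstitutionPlan(edits=edits, label=label))
    return variants


# ---------------------------------------------------------------------------
# sequence output


def domain_to_gapped(domain: NumberedDomain) -> str:
    """Gapped IMGT string over positions 1-117 (V frame + CDR3)."""
    return "".join(domain.residues.get(p, ".") for p in range(1, 118))


def domain_to_ungapped(domain: NumberedDomain) -> str:
    return "".join(domain.residues[p] for p in sorted(domain.residues))


def write_tcr_fasta(pairs: list[TCRPair], path: str | Path, *, gapped: bool = True) -> None:
    render = domain_to_gapped if gapped else domain_to_ungapped
    lines = []
    for tcr in pairs:
        log = ",".join(tcr.edit_log) if tcr.edit_log else "wild-type"
        for chain in ("alpha", "beta"):
            lines.append(f">{tcr.name}|{chain}|{log}")
            lines.append(render(tcr.domain(chain)))
    Path(path).write_text("\n".join(lines) + "\n")
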