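"""Nomination of candidate framework residues from enrichment results.

Statistically enriched (position, amino acid) pairs are intersected with a
packaged structural-category annotation (solvent-exposed, hydrophobic
core, Va-Vb interface, V-C interface) to yield candidate residues for
engineering.  Category assignment requires 3D structural analysis, which
is out of scope here; the annotation is static, user-replaceable package
data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .enrichment import EnrichmentResult
from .io import AMINO_ACIDS, CHAINS, FormatError

logger = logging.getLogger(__name__)

CATEGORY_LABELS = {
    1: "solvent-exposed",
    2: "hydrophobic core",
    3: "Va-Vb interface",
    4: "V-C interface",
}

_CANDIDATES_TSV = "curated_candidates.tsv"
_CATEGORIES_TSV = "structural_categories.tsv"


@dataclass(frozen=True)
class CandidateResidue:
    """A framework position with dominant/weak identities and a category."""

    chain: str
    position: int
    dominant_aa: str
    weak_aa: str
    category: int
    evidence: object = "curated"

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}")
        if self.category not in CATEGORY_LABELS:
            raise ValueError(f"category must be in {sorted(CATEGORY_LABELS)}")
        if self.dominant_aa == self.weak_aa:
            raise ValueError("dominant and weak identities must differ")
        for aa in (self.dominant_aa, self.weak_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {aa!r}")


def _read_tsv(name: str) -> list[dict[str, str]]:
    with resources.as_file(resources.files("tcrforge.data").joinpath(name)) as p:
        lines = [
            ln for ln in Path(p).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_curated_candidates() -> list[CandidateResidue]:
    """The curated 14-residue candidate set shipped with the package."""
    rows = _read_tsv(_CANDIDATES_TSV)
    candidates = [
        CandidateResidue(
            chain=r["chain"],
            position=int(r["imgt_position"]),
            dominant_aa=r["dominant_aa"],
            weak_aa=r["weak_aa"],
            category=int(r["category_code"]),
            evidence=r.get("evidence", "curated"),
        )
        for r in rows
    ]
    if len(candidates) != 14:
        raise FormatError(f"curated candidate table must hold 14 residues, found {len(candidates)}")
    if {c.category for c in candidates} != set(CATEGORY_LABELS):
        raise FormatError("curated candidates must span all four structural categories")
    return candidates


def load_structural_categories() -> dict[tuple[str, int], int]:
    """Packaged (chain, IMGT position) -> structural category annotation."""
    return {
        (r["chain"], int(r["imgt_position"])): int(r["category_code"])
        for r in _read_tsv(_CATEGORIES_TSV)
    }


def _weak_identity(result: EnrichmentResult, siblings: list[EnrichmentResult]) -> str | None:
    """Most plausible weak-arm identity at a position: the other amino acid
    with the largest weak-arm count (preferring weak-enriched siblings)."""
    best, best_rank = None, None
    for s in siblings:
        if s.amino_acid == result.amino_acid:
            continue
        rank = (s.direction == "weak-enriched", s.pooled_table().c)
        if best_rank is None or rank > best_rank:
            best, best_rank = s.amino_acid, rank
    return best


def select_candidates(
    results: list[EnrichmentResult],
    alpha_level: float,
    categories: set[int] | None = None,
    annotations: dict[tuple[str, int], int] | None = None,
) -> list[CandidateResidue]:
    """Select dominant-enriched framework residues at annotated positions.

    A result qualifies when it was tested, its selection p-value (adjusted
    where available) is below ``alpha_level``, its direction is
    dominant-enriched, and its position carries a structural-category
    annotation in the requested set.  Ties are broken by smaller p, then
    larger |log odds ratio|, then lower position.
    """
    if annotations is None:
        annotations = load_structural_categories()
    if categories is None:
        categories = set(CATEGORY_LABELS)
    if not annotations:
        logger.warning("no annotated positions; candidate list empty")
        return []
    by_position: dict[tuple[str, int], list[EnrichmentResult]] = {}
    for r in results:
        by_position.setdefault((r.chain, r.position), []).append(r)
    selected: list[tuple[tuple, CandidateResidue]] = []
    for r in results:
        if not r.tested or r.direction != "dominant-enriched":
            continue
        p = r.p_selection
        if p is None or not p < alpha_level:
            continue
        category = annotations.get((r.chain, r.position))
        if category is None or category not in categories:
            continue
        weak_aa = _weak_identity(r, by_position[(r.chain, r.position)])
        if weak_aa is None:
            continue  # monomorphic position cannot define a weak identity
        log_or = abs(math.log(r.odds_ratio)) if r.odds_ratio > 0 else math.inf
        sort_key = (p, -log_or, r.position)
        selected.append(
            (
                sort_key,
                CandidateResidue(
                    chain=r.chain,
                    position=r.position,
                    dominant_aa=r.amino_acid,
                    weak_aa=weak_aa,
                    category=category,
                    evidence=r,
                ),
            )
        )
    selected.sort(key=lambda kv: kv[0])
    return [c for _, c in selected]


def write_candidates_tsv(candidates: list[CandidateResidue], path: str | Path) -> None:
    lines = ["chain\timgt_position\tdominant_aa\tweak_aa\tcategory_code\tevidence"]
    for c in candidates:
        ev = c.evidence if isinstance(c.evidence, str) else "enrichment"
        lines.append(
            f"{c.chain}\t{c.position}\t{c.dominant_aa}\t{c.weak_aa}\t{c.category}\t{ev}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
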