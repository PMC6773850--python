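"""Readers and writers for clonotype tables, gapped germline FASTA and reports.

The clonotype dialect is a plain UTF-8 TSV in the style of Decombinator
summary output: one row per distinct TCR chain rearrangement with donor,
expression phenotype, V/J gene calls, CDR3 amino-acid sequence and an
optional abundance.  Lines starting with ``#`` are comments.  Unknown
columns are preserved verbatim as opaque annotations so that round-trips
are lossless on the validated field set.

Germline V segments are exchanged as IMGT-gapped amino-acid FASTA: every
record spans IMGT positions 1-104 with ``.`` marking unoccupied positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "."

#: IMGT V-segment frame: positions 1..104 (FR1 through the 2nd-CYS anchor).
V_FRAME_LENGTH = 104

PHENOTYPES = ("dominant", "weak")
CHAINS = ("alpha", "beta")

V_GENE_PATTERN = re.compile(r"^TR[AB]V\d+(-\d+)?(\*\d+)?$")

#: Canonical clonotype-table column order.
CLONOTYPE_COLUMNS = (
    "donor_id",
    "phenotype",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3_aa",
    "abundance",
    "fw_variants",
)


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


def strip_allele(gene: str) -> str:
    """Drop an IMGT allele suffix (``*01``), keeping the gene-level name."""
    return gene.split("*", 1)[0]


@dataclass(frozen=True)
class Clonotype:
    """One annotated TCR chain observation.

    ``framework_overrides`` maps IMGT positions to residues that replace the
    germline identity of ``v_gene`` at that position (allelic/framework
    variation carried by the sequenced clone).  It is serialized in the
    ``fw_variants`` column as ``;``-joined ``POS:AA`` pairs.
    """

    donor_id: str
    phenotype: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    abundance: int = 1
    framework_overrides: Mapping[int, str] = field(default_factory=dict)
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}: {self.phenotype!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}: {self.chain!r}")
        if not V_GENE_PATTERN.match(self.v_gene):
            raise ValueError(f"v_gene {self.v_gene!r} does not follow IMGT nomenclature")
        if not set(self.cdr3_aa) <= set(AMINO_ACIDS):
            raise ValueError(f"cdr3_aa {self.cdr3_aa!r} contains non-amino-acid characters")
        if self.abundance < 1:
            raise ValueError("abundance must be a positive count")
        object.__setattr__(self, "framework_overrides", dict(self.framework_overrides))
        object.__setattr__(self, "annotations", dict(self.annotations))

    @property
    def key(self) -> tuple:
        """Identity of the rearrangement, ignoring donor and phenotype."""
        return (self.chain, self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass(frozen=True)
class GermlineGene:
    """An IMGT-gapped germline V segment (positions 1-104)."""

    name: str
    chain: str
    gapped_seq: str

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}: {self.chain!r}")
        if len(self.gapped_seq) != V_FRAME_LENGTH:
            raise ValueError(
                f"gene {self.name}: gapped sequence length {len(self.gapped_seq)} != {V_FRAME_LENGTH}"
            )
        bad = set(self.gapped_seq) - set(AMINO_ACIDS + GAP)
        if bad:
            raise ValueError(f"gene {self.name}: illegal characters {sorted(bad)}")

    def residue(self, position: int) -> str | None:
        """Residue at a 1-based IMGT position within the V frame, or None for a gap."""
        if not 1 <= position <= V_FRAME_LENGTH:
            raise ValueError(f"position {position} outside V frame 1-{V_FRAME_LENGTH}")
        aa = self.gapped_seq[position - 1]
        return None if aa == GAP else aa


@dataclass
class GermlineSet:
    genes: dict[str, GermlineGene]

    def __post_init__(self):
        for name, gene in self.genes.items():
            if name != gene.name:
                raise ValueError(f"germline set key {name!r} != gene name {gene.name!r}")

    def by_chain(self, chain: str) -> list[GermlineGene]:
        return [g for g in self.genes.values() if g.chain == chain]

    def resolve(self, v_gene: str) -> GermlineGene:
        """Look up a gene, tolerating an allele suffix on the query."""
        name = strip_allele(v_gene)
        try:
            return self.genes[name]
        except KeyError:
            raise KeyError(f"V gene {v_gene!r} not present in germline set") from None


@dataclass
class RepertoireLibrary:
    """A collection of clonotypes spanning donors and the two phenotypes."""

    clonotypes: list[Clonotype]

    @property
    def donors(self) -> set[str]:
        return {c.donor_id for c in self.clonotypes}

    @property
    def phenotypes(self) -> set[str]:
        return {c.phenotype for c in self.clonotypes}

    def subset(self, **field_values) -> "RepertoireLibrary":
        keep = [
            c
            for c in self.clonotypes
            if all(getattr(c, k) == v for k, v in field_values.items())
        ]
        return RepertoireLibrary(keep)

    def __len__(self) -> int:
        return len(self.clonotypes)


# ---------------------------------------------------------------------------
# clonotype tables


def _format_overrides(ov: Mapping[int, str]) -> str:
    return ";".join(f"{pos}:{aa}" for pos, aa in sorted(ov.items()))


def _parse_overrides(text: str, row: int) -> dict[int, str]:
    out: dict[int, str] = {}
    text = text.strip()
    if not text:
        return out
    for item in text.split(";"):
        try:
            pos_s, aa = item.split(":")
            pos = int(pos_s)
        except ValueError:
            raise FormatError(f"row {row}: malformed fw_variants entry {item!r}") from None
        if aa not in AMINO_ACIDS:
            raise FormatError(f"row {row}: fw_variants residue {aa!r} is not an amino acid")
        out[pos] = aa
    return out


def read_clonotype_table(path: str | Path) -> RepertoireLibrary:
    """Read a clonotype TSV into a validated :class:`RepertoireLibrary`.

    Duplicate (donor, phenotype, chain, v_gene, cdr3) rows are merged by
    summing abundances, with a warning.  Row order never affects downstream
    results.  An empty table (header only) is accepted and flagged.
    """
    path = Path(path)
    lines = [
        (i + 1, ln.rstrip("\n"))
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: no header row")
    header = lines[0][1].split("\t")
    required = {"donor_id", "phenotype", "chain", "v_gene", "cdr3_aa"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    known = set(CLONOTYPE_COLUMNS)

    merged: dict[tuple, Clonotype] = {}
    for row_no, line in lines[1:]:
        values = line.split("\t")
        if len(values) != len(header):
            raise FormatError(f"row {row_no}: expected {len(header)} fields, got {len(values)}")
        rec = dict(zip(header, values))
        extras = {k: v for k, v in rec.items() if k not in known}
        try:
            clonotype = Clonotype(
                donor_id=rec["donor_id"],
                phenotype=rec["phenotype"],
                chain=rec["chain"],
                v_gene=rec["v_gene"],
                j_gene=rec.get("j_gene", ""),
                cdr3_aa=rec["cdr3_aa"],
                abundance=int(rec["abundance"]) if rec.get("abundance", "").strip() else 1,
                framework_overrides=_parse_overrides(rec.get("fw_variants", ""), row_no),
                annotations=extras,
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"row {row_no}: {exc}") from None
        key = (
            clonotype.donor_id,
            clonotype.phenotype,
            clonotype.chain,
            clonotype.v_gene,
            clonotype.cdr3_aa,
        )
        if key in merged:
            prev = merged[key]
            logger.warning("duplicate clonotype row %d merged (abundances summed)", row_no)
            merged[key] = Clonotype(
                donor_id=prev.donor_id,
                phenotype=prev.phenotype,
                chain=prev.chain,
                v_gene=prev.v_gene,
                j_gene=prev.j_gene,
                cdr3_aa=prev.cdr3_aa,
                abundance=prev.abundance + clonotype.abundance,
                framework_overrides=prev.framework_overrides,
                annotations=prev.annotations,
            )
        else:
            merged[key] = clonotype
    if not merged:
        logger.warning("%s: empty clonotype table (header only)", path)
    # deterministic order, independent of input row order
    clonotypes = sorted(
        merged.values(),
        key=lambda c: (c.donor_id, c.phenotype, c.chain, c.v_gene, c.cdr3_aa),
    )
    return RepertoireLibrary(clonotypes)


def write_clonotype_table(library: RepertoireLibrary, path: str | Path) -> None:
    path = Path(path)
    rows = ["\t".join(CLONOTYPE_COLUMNS)]
    ordered = sorted(
        library.clonotypes,
        key=lambda c: (c.donor_id, c.phenotype, c.chain, c.v_gene, c.cdr3_aa),
    )
    for c in ordered:
        rows.append(
            "\t".join(
                [
                    c.donor_id,
                    c.phenotype,
                    c.chain,
                    c.v_gene,
                    c.j_gene,
                    c.cdr3_aa,
                    str(c.abundance),
                    _format_overrides(c.framework_overrides),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# gapped germline FASTA


def _chain_of(name: str) -> str:
    if name.startswith("TRAV"):
        return "alpha"
    if name.startswith("TRBV"):
        return "beta"
    raise FormatError(f"cannot infer chain from gene name {name!r}")


def read_gapped_fasta(path: str | Path) -> GermlineSet:
    """Read IMGT-gapped amino-acid FASTA into a :class:`GermlineSet`.

    ``-`` gaps are tolerated and normalized to ``.`` with a warning; a
    record of the wrong frame length is rejected naming the gene.
    """
    genes: dict[str, GermlineGene] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id.split("|")[0]
        seq = str(record.seq)
        if "-" in seq:
            logger.warning("gene %s: '-' gap characters normalized to '.'", name)
            seq = seq.replace("-", ".")
        if len(seq) != V_FRAME_LENGTH:
            raise FormatError(
                f"gene {name}: sequence length {len(seq)} != expected frame length {V_FRAME_LENGTH}"
            )
        gene = GermlineGene(name=name, chain=_chain_of(name), gapped_seq=seq)
        if name in genes:
            raise FormatError(f"duplicate gene name {name}")
        genes[name] = gene
    return GermlineSet(genes)


def write_gapped_fasta(germline_set: GermlineSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.gapped_seq), id=g.name, description=g.chain)
        for g in sorted(germline_set.genes.values(), key=lambda g: g.name)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# enrichment reports

REPORT_COLUMNS = (
    "chain",
    "imgt_position",
    "amino_acid",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "per_donor_p",
    "cmh_p",
    "p_adjusted",
    "direction",
    "tested",
    "family_size",
    "category",
)


def write_enrichment_report(results: Iterable, path: str | Path) -> None:
    """Write enrichment results as a TSV, stably sorted by (chain, position, aa).

    Pooled 2x2 counts are reported in the a/b/c/d columns; per-donor Fisher
    p-values are serialized as ``donor=p`` pairs joined by ``;``.
    """
    path = Path(path)
    rows = ["\t".join(REPORT_COLUMNS)]
    for r in sorted(results, key=lambda r: (r.chain, r.position, r.amino_acid)):
        pooled = r.pooled_table()
        if r.per_donor_p:
            per_donor = ";".join(
                f"{donor}={p:.6g}" for donor, p in sorted(r.per_donor_p.items())
            )
        elif r.pooled_p is not None:
            per_donor = f"pooled={r.pooled_p:.6g}"
        else:
            per_donor = ""
        rows.append(
            "\t".join(
                [
                    r.chain,
                    str(r.position),
                    r.amino_acid,
                    str(pooled.a),
                    str(pooled.b),
                    str(pooled.c),
                    str(pooled.d),
                    f"{r.odds_ratio:.6g}",
                    per_donor,
                    "" if r.cmh_p is None else f"{r.cmh_p:.6g}",
                    "" if r.p_adjusted is None else f"{r.p_adjusted:.6g}",
                    r.direction,
                    "yes" if r.tested else "no",
                    str(r.family_size),
                    "" if r.category is None else str(r.category),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")
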