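"""Synthetic paired dominant/weak clonotype libraries with planted effects.

The generator emulates a sorted-library experiment: for each
donor, transduced T cells are sorted into a *dominant* arm (endogenous TCR
co-expressed with the introduced receptor) and a *weak* arm (endogenous TCR
out-competed), and each arm is sequenced into a table of distinct
clonotypes.  Ground truth is planted at the residue level: a planted effect
``(chain, position, aa, odds_ratio)`` makes the amino acid occur at
phenotype-specific frequencies whose odds ratio equals the configured
value, independent of the V gene carrying it, so a correct enrichment
analysis must recover exactly the planted positions.

Residue variation relative to the germline is carried on each clonotype row
as framework overrides; no new germline genes are invented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .io import (
    AMINO_ACIDS,
    CHAINS,
    PHENOTYPES,
    V_FRAME_LENGTH,
    Clonotype,
    GermlineGene,
    GermlineSet,
    RepertoireLibrary,
)
from .numbering import DEFAULT_FRAMEWORK_GAPS, REGION_BOUNDS, build_framework_mask

_ALPHA_J = tuple(f"TRAJ{i}" for i in (3, 6, 9, 12, 23, 28, 33, 40, 45, 49))
_BETA_J = ("TRBJ1-1", "TRBJ1-2", "TRBJ1-5", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7")

#: Residues tried, in order, when a fallback distinct from both the planted
#: amino acid and the germline identity is needed.
_FALLBACK_ORDER = "PSAGTVLINDE"


@dataclass(frozen=True)
class PlantedEffect:
    """A positional residue enrichment planted between the two phenotypes.

    ``baseline_freq`` is the frequency of ``amino_acid`` in the weak arm;
    the dominant-arm frequency is derived so that the odds ratio of
    carrying the residue (dominant vs weak) equals ``odds_ratio``.
    """

    chain: str
    imgt_position: int
    amino_acid: str
    odds_ratio: float
    baseline_freq: float = 0.25
    donor_multipliers: dict[str, float] | None = None

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}")
        if self.amino_acid not in AMINO_ACIDS:
            raise ValueError(f"amino_acid {self.amino_acid!r} invalid")
        if not self.odds_ratio > 0:
            raise ValueError("planted odds ratio must be > 0")
        if not 0 < self.baseline_freq < 1:
            raise ValueError("baseline_freq must lie in (0, 1)")

    def frequency(self, phenotype: str, donor_id: str | None = None) -> float:
        odds = self.baseline_freq / (1.0 - self.baseline_freq)
        if phenotype == "dominant":
            r = self.odds_ratio
            if self.donor_multipliers and donor_id in self.donor_multipliers:
                r *= self.donor_multipliers[donor_id]
            odds *= r
        return odds / (1.0 + odds)


@dataclass
class SyntheticConfig:
    n_donors: int = 3
    n_clonotypes_per_phenotype: int = 442
    v_gene_pool: dict[str, list[str]] | None = None
    v_usage_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    background_variation: list[PlantedEffect] = field(default_factory=list)
    cdr3_length_range: tuple[int, int] = (8, 13)
    chain_split: float = 0.5
    seed: int = 1
    germline_set: GermlineSet | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("planted_effects", "background_variation"):
            raw[key] = [PlantedEffect(**e) for e in raw.get(key, [])]
        if "cdr3_length_range" in raw:
            raw["cdr3_length_range"] = tuple(raw["cdr3_length_range"])
        return cls(**raw)


def split_evenly(total: int, parts: int) -> list[int]:
    """Split a count over parts, larger shares first (e.g. 442/3 -> 148,147,147)."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _fallback_residue(gene: GermlineGene, position: int, avoid: str) -> str:
    germ = gene.residue(position)
    if germ is not None and germ != avoid:
        return germ
    for aa in _FALLBACK_ORDER:
        if aa != avoid and aa != germ:
            return aa
    raise AssertionError("unreachable")


def _validate(config: SyntheticConfig, germline_set: GermlineSet) -> dict[str, object]:
    if config.n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if config.n_clonotypes_per_phenotype < 1:
        raise ValueError("zero clonotypes requested")
    masks = {chain: build_framework_mask(germline_set, chain) for chain in CHAINS}
    seen: set[tuple[str, int]] = set()
    for eff in list(config.planted_effects) + list(config.background_variation):
        if eff.imgt_position not in masks[eff.chain]:
            raise ValueError(
                f"planted position {eff.imgt_position} ({eff.chain}) is outside the framework mask"
            )
        key = (eff.chain, eff.imgt_position)
        if key in seen:
            raise ValueError(f"multiple effects configured at {eff.chain} position {eff.imgt_position}")
        seen.add(key)
    pool = config.v_gene_pool or {
        chain: sorted(g.name for g in germline_set.by_chain(chain)) for chain in CHAINS
    }
    for chain in CHAINS:
        for name in pool[chain]:
            germline_set.resolve(name)  # raises if missing
    for phenotype in PHENOTYPES:
        weights = config.v_usage_weights.get(phenotype, {})
        if any(w < 0 for w in weights.values()):
            raise ValueError("usage weights must be non-negative")
        for chain in CHAINS:
            chain_w = [weights.get(name, 1.0) for name in pool[chain]]
            if not any(w > 0 for w in chain_w):
                raise ValueError(f"no positive usage weight for {phenotype}/{chain}")
    return {"masks": masks, "pool": pool}


def _sample_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def generate_library(config: SyntheticConfig, seed: int | None = None) -> RepertoireLibrary:
    """Generate a dominant/weak clonotype library with planted ground truth.

    Clonotypes are globally distinct on (chain, v_gene, j_gene, cdr3);
    CDR3s are resampled on collision.  Identical (config, seed) pairs give
    identical libraries.
    """
    germline_set = config.germline_set
    if germline_set is None:
        from .numbering import load_reference_germlines

        germline_set = load_reference_germlines()
    ctx = _validate(config, germline_set)
    pool: dict[str, list[str]] = ctx["pool"]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.cdr3_length_range

    donors = [f"donor{i + 1}" for i in range(config.n_donors)]
    per_donor = split_evenly(config.n_clonotypes_per_phenotype, config.n_donors)
    seen_keys: set[tuple] = set()
    clonotypes: list[Clonotype] = []

    for phenotype in PHENOTYPES:
        weights = config.v_usage_weights.get(phenotype, {})
        probs = {}
        for chain in CHAINS:
            w = np.array([weights.get(name, 1.0) for name in pool[chain]], float)
            probs[chain] = w / w.sum()
        for donor, n_donor in zip(donors, per_donor):
            n_alpha = int(round(n_donor * config.chain_split))
            for chain, n_chain in (("alpha", n_alpha), ("beta", n_donor - n_alpha)):
                gene_names = pool[chain]
                j_pool = _ALPHA_J if chain == "alpha" else _BETA_J
                gene_idx = rng.choice(len(gene_names), size=n_chain, p=probs[chain])
                j_idx = rng.integers(0, len(j_pool), size=n_chain)
                effects = [
                    e
                    for e in list(config.planted_effects) + list(config.background_variation)
                    if e.chain == chain
                ]
                draws = [
                    rng.random(n_chain) < e.frequency(phenotype, donor) for e in effects
                ]
                for i in range(n_chain):
                    gene = germline_set.genes[gene_names[int(gene_idx[i])]]
                    overrides: dict[int, str] = {}
                    for k, e in enumerate(effects):
                        pos = e.imgt_position
                        germ = gene.residue(pos)
                        if germ is None:
                            continue  # residue-level variation cannot ungap a position
                        aa = e.amino_acid if draws[k][i] else _fallback_residue(gene, pos, e.amino_acid)
                        if aa != germ:
                            overrides[pos] = aa
                    while True:
                        cdr3 = _sample_cdr3(rng, lo, hi)
                        key = (chain, gene.name, j_pool[int(j_idx[i])], cdr3)
                        if key not in seen_keys:
                            seen_keys.add(key)
                            break
                    clonotypes.append(
                        Clonotype(
                            donor_id=donor,
                            phenotype=phenotype,
                            chain=chain,
                            v_gene=gene.name,
                            j_gene=key[2],
                            cdr3_aa=cdr3,
                            abundance=1,
                            framework_overrides=overrides,
                        )
                    )
    return RepertoireLibrary(clonotypes)


def null_config(config: SyntheticConfig | None = None, **kwargs) -> SyntheticConfig:
    """A copy of a config with every effect removed and usage equalized.

    Under the null every residue frequency is identical between phenotypes,
    so any downstream discovery is a false positive.
    """
    base = config or default_sanger_config()
    cfg = replace(base, planted_effects=[], v_usage_weights={}, **kwargs)
    return cfg


def default_sanger_config() -> SyntheticConfig:
    """Packaged default emulating a pooled Sanger-sequenced library.

    Three donors contribute 442 distinct clonotypes per phenotype in total
    (an 884-clonotype pooled library, half per expression arm).  Usage
    weights skew the genes characteristically enriched in each arm, and modest
    residue-level effects are planted at documented candidate positions.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("tcrforge.data").joinpath("default_sanger.yaml")
    ) as p:
        return SyntheticConfig.from_yaml(p)


# ---------------------------------------------------------------------------
# fabricated germline sets for tests


def generate_germline_set(n_genes_per_chain: int, seed: int) -> GermlineSet:
    """Fabricate a valid IMGT-gapped germline set (test fixture material).

    Each gene carries the C23/W41/C104 anchors and the packaged framework
    gap convention; CDR1/CDR2 lengths vary gene to gene.  Names use a
    synthetic IMGT-style series (TRAV6xx / TRBV6xx) disjoint from the
    packaged reference genes.
    """
    if n_genes_per_chain < 1:
        raise ValueError("n_genes_per_chain must be >= 1")
    rng = np.random.default_rng(seed)
    cdr_bounds = {name: (lo, hi) for name, lo, hi in REGION_BOUNDS if name in ("CDR1", "CDR2")}
    genes: dict[str, GermlineGene] = {}
    for chain, prefix in (("alpha", "TRAV"), ("beta", "TRBV")):
        gaps = set(DEFAULT_FRAMEWORK_GAPS[chain])
        for i in range(n_genes_per_chain):
            name = f"{prefix}{600 + i}"
            cdr_occ: set[int] = set()
            for lo_b, hi_b in cdr_bounds.values():
                length = int(rng.integers(4, hi_b - lo_b + 2))
                front = (length + 1) // 2
                back = length // 2
                cdr_occ |= set(range(lo_b, lo_b + front)) | set(range(hi_b - back + 1, hi_b + 1))
            seq = []
            for pos in range(1, V_FRAME_LENGTH + 1):
                in_cdr = any(lo_b <= pos <= hi_b for lo_b, hi_b in cdr_bounds.values())
                if pos in gaps or (in_cdr and pos not in cdr_occ):
                    seq.append(".")
                elif pos == 23 or pos == 104:
                    seq.append("C")
                elif pos == 41:
                    seq.append("W")
                else:
                    seq.append(AMINO_ACIDS[int(rng.integers(0, 20))])
            genes[name] = GermlineGene(name=name, chain=chain, gapped_seq="".join(seq))
    return GermlineSet(genes)
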