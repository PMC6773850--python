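"""Positional amino-acid enrichment between dominant and weak libraries.

For every framework IMGT position and amino acid A, counts of A versus all
other residues (~A) are tabulated per donor and phenotype into 2x2
contingency tables.  Two analysis modes mirror the two sequencing designs:

* ``sanger`` — donors pooled into a single table per (position, A); the
  two-sided Fisher exact test (hypergeometric point-probability ordering)
  is applied without multiplicity correction.
* ``ngs`` — per-donor Fisher tests plus the Cochran-Mantel-Haenszel score
  test across donors, Bonferroni-adjusted over the per-chain family of
  (position, amino acid) pairs with nonzero pooled count.

Counting is clonotype-weighted: each distinct clonotype contributes once,
since the libraries are collections of distinct rearrangements (abundance
weighting is available but off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io import AMINO_ACIDS, CHAINS, GermlineSet, RepertoireLibrary
from .numbering import FrameworkMask, build_framework_mask

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CODE = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of residue A vs not-A in the dominant and weak arms.

    a = A & dominant, b = ~A & dominant, c = A & weak, d = ~A & weak.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when any margin is zero, leaving the test undefined."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def _hypergeom_pmf(k: np.ndarray, n: int, n_success: int, n_draw: int) -> np.ndarray:
    """Hypergeometric pmf over a support vector, via log-gamma binomials."""
    logc = (
        _logcomb(n_success, k)
        + _logcomb(n - n_success, n_draw - k)
        - _logcomb(n, n_draw)
    )
    return np.exp(logc)


def _logcomb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by hypergeometric point-probability ordering.

    p sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (within 1e-12
    relative tolerance, guarding against floating-point ties).  A table
    with any zero margin is degenerate and returns p = 1.
    """
    if t.degenerate:
        return 1.0
    n, r1, c1 = t.n, t.a + t.b, t.a + t.c
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, n, c1, r1)
    p_obs = pmf[t.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, max(p, float(p_obs)))


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample odds ratio (a*d)/(b*c), Haldane-Anscombe +0.5 when any cell is 0."""
    if t.degenerate:
        raise ValueError("odds ratio undefined for a table with a zero margin")
    if min(t.a, t.b, t.c, t.d) == 0:
        return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    return (t.a * t.d) / (t.b * t.c)


def cmh_test(tables: dict[str, ContingencyTable2x2]) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel score test across strata (no continuity correction).

    statistic = (sum_k a_k - sum_k E_k)^2 / sum_k Var_k with hypergeometric
    mean and variance per stratum; p from chi-square with 1 df.  With a
    single stratum this equals the Mantel-Haenszel score chi-square of that
    table.  If every stratum is degenerate the test returns (0.0, 1.0).
    """
    if not tables:
        raise ValueError("cmh_test requires at least one stratum")
    num = 0.0
    var = 0.0
    for t in tables.values():
        if t.n == 0 or t.degenerate:
            continue
        n = t.n
        r1, r2 = t.a + t.b, t.c + t.d
        c1, c2 = t.a + t.c, t.b + t.d
        num += t.a - r1 * c1 / n
        if n > 1:
            var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if var == 0.0:
        return 0.0, 1.0
    statistic = num * num / var
    return statistic, float(stats.chi2.sf(statistic, df=1))


def bonferroni(p_values: list[float], family_size: int) -> list[float]:
    """Bonferroni adjustment: min(1, family_size * p), order-preserving."""
    if family_size < len(p_values):
        raise ValueError("family_size must be at least the number of p-values")
    return [min(1.0, family_size * p) for p in p_values]


# ---------------------------------------------------------------------------
# tallying


@dataclass
class PositionTally:
    """Per-(donor, position, amino acid) counts for one chain.

    ``counts`` has shape (n_donors, 2, n_positions, 21): phenotype axis is
    (dominant, weak); the last amino-acid slot is the gap code, excluded
    from tables (a gapped position contributes nothing).
    """

    chain: str
    donors: tuple[str, ...]
    positions: tuple[int, ...]
    counts: np.ndarray

    def table(self, donor: str, position: int, amino_acid: str) -> ContingencyTable2x2:
        di = self.donors.index(donor)
        pi = self.positions.index(position)
        ai = _AA_INDEX[amino_acid]
        dom = self.counts[di, 0, pi, :_GAP_CODE]
        weak = self.counts[di, 1, pi, :_GAP_CODE]
        a = int(dom[ai])
        c = int(weak[ai])
        return ContingencyTable2x2(a=a, b=int(dom.sum()) - a, c=c, d=int(weak.sum()) - c)

    def pooled_table(self, position: int, amino_acid: str) -> ContingencyTable2x2:
        pi = self.positions.index(position)
        ai = _AA_INDEX[amino_acid]
        dom = self.counts[:, 0, pi, :_GAP_CODE].sum(axis=0)
        weak = self.counts[:, 1, pi, :_GAP_CODE].sum(axis=0)
        a = int(dom[ai])
        c = int(weak[ai])
        return ContingencyTable2x2(a=a, b=int(dom.sum()) - a, c=c, d=int(weak.sum()) - c)


def tally_position_aa(
    library: RepertoireLibrary,
    germline_set: GermlineSet,
    mask: FrameworkMask | dict[str, FrameworkMask],
    *,
    weight_by_abundance: bool = False,
) -> dict[str, PositionTally]:
    """Count residues per (donor, masked position, amino acid) and phenotype.

    Each clonotype's residues come from its V-gene germline with the
    clonotype's framework overrides applied; positions gapped in the
    germline contribute nothing.  Returns one tally per chain present.
    """
    masks: dict[str, FrameworkMask]
    if isinstance(mask, FrameworkMask):
        masks = {mask.chain: mask}
    else:
        masks = dict(mask)

    unresolved = [
        v for v in {c.v_gene for c in library.clonotypes}
        if _try_resolve(germline_set, v) is None
    ]
    if unresolved:
        raise KeyError(f"V genes not resolvable in germline set: {sorted(unresolved)}")

    donors = tuple(sorted(library.donors))
    donor_index = {d: i for i, d in enumerate(donors)}
    out: dict[str, PositionTally] = {}
    for chain, chain_mask in masks.items():
        clonos = [c for c in library.clonotypes if c.chain == chain]
        positions = chain_mask.positions
        pos_index = {p: i for i, p in enumerate(positions)}
        n_pos = len(positions)
        counts = np.zeros((len(donors), 2, n_pos, 21), dtype=float)
        if clonos:
            gene_names = sorted({c.v_gene for c in clonos})
            gene_codes = {}
            for name in gene_names:
                gene = germline_set.resolve(name)
                codes = np.full(n_pos, _GAP_CODE, dtype=np.int64)
                for p, i in pos_index.items():
                    aa = gene.residue(p)
                    if aa is not None:
                        codes[i] = _AA_INDEX[aa]
                gene_codes[name] = codes
            rows = np.stack([gene_codes[c.v_gene] for c in clonos])
            for i, c in enumerate(clonos):
                for p, aa in c.framework_overrides.items():
                    j = pos_index.get(p)
                    if j is not None and rows[i, j] != _GAP_CODE:
                        rows[i, j] = _AA_INDEX[aa]
            d_idx = np.array([donor_index[c.donor_id] for c in clonos])
            ph_idx = np.array([0 if c.phenotype == "dominant" else 1 for c in clonos])
            w = np.array(
                [c.abundance if weight_by_abundance else 1 for c in clonos], dtype=float
            )
            pos_grid = np.arange(n_pos)
            flat_dim = n_pos * 21
            for di in range(len(donors)):
                for ph in range(2):
                    sel = (d_idx == di) & (ph_idx == ph)
                    if not sel.any():
                        continue
                    flat = (pos_grid[None, :] * 21 + rows[sel]).ravel()
                    wts = np.repeat(w[sel], n_pos)
                    counts[di, ph] += np.bincount(
                        flat, weights=wts, minlength=flat_dim
                    ).reshape(n_pos, 21)
        out[chain] = PositionTally(chain=chain, donors=donors, positions=positions, counts=counts)
    return out


def _try_resolve(germline_set: GermlineSet, v_gene: str):
    try:
        return germline_set.resolve(v_gene)
    except KeyError:
        return None


# ---------------------------------------------------------------------------
# enrichment results


@dataclass
class EnrichmentResult:
    """Outcome of the enrichment test for one (chain, position, amino acid)."""

    chain: str
    position: int
    amino_acid: str
    per_donor_tables: dict[str, ContingencyTable2x2]
    per_donor_p: dict[str, float]
    odds_ratio: float
    cmh_statistic: float | None
    cmh_p: float | None
    pooled_p: float | None
    p_adjusted: float | None
    direction: str
    tested: bool
    degenerate: bool
    family_size: int
    category: int | None = None

    def pooled_table(self) -> ContingencyTable2x2:
        a = sum(t.a for t in self.per_donor_tables.values())
        b = sum(t.b for t in self.per_donor_tables.values())
        c = sum(t.c for t in self.per_donor_tables.values())
        d = sum(t.d for t in self.per_donor_tables.values())
        return ContingencyTable2x2(a, b, c, d)

    @property
    def p_selection(self) -> float | None:
        """The p-value a discovery threshold applies to (adjusted if present)."""
        return self.p_adjusted if self.p_adjusted is not None else self.pooled_p


def _direction(t: ContingencyTable2x2) -> str:
    if t.degenerate:
        return "none"
    ratio = odds_ratio(t)
    if ratio > 1.0:
        return "dominant-enriched"
    if ratio < 1.0:
        return "weak-enriched"
    return "none"


def run_enrichment(
    library: RepertoireLibrary,
    germline_set: GermlineSet,
    mode: str = "ngs",
    *,
    min_count: int = 5,
    weight_by_abundance: bool = False,
) -> list[EnrichmentResult]:
    """Full enrichment analysis of a dominant/weak library.

    ``sanger``: donors pooled, Fisher only, no multiplicity correction.
    ``ngs``: per-donor Fisher + CMH across donors + Bonferroni over the
    per-chain family of (position, aa) pairs with nonzero pooled count.
    Pairs with pooled residue count below ``min_count`` are reported but
    flagged untested.  Results are sorted by (chain, position, amino acid).
    """
    if mode not in ("sanger", "ngs"):
        raise ValueError(f"mode must be 'sanger' or 'ngs', got {mode!r}")
    if library.phenotypes != {"dominant", "weak"}:
        raise ValueError("library must contain both dominant and weak clonotypes")
    masks = {
        chain: build_framework_mask(germline_set, chain)
        for chain in CHAINS
        if any(c.chain == chain for c in library.clonotypes)
    }
    tallies = tally_position_aa(
        library, germline_set, masks, weight_by_abundance=weight_by_abundance
    )
    results: list[EnrichmentResult] = []
    for chain in sorted(tallies):
        tally = tallies[chain]
        pooled_counts = tally.counts[:, :, :, :_GAP_CODE].sum(axis=(0, 1))
        nonzero = [
            (pos, AMINO_ACIDS[ai])
            for pi, pos in enumerate(tally.positions)
            for ai in range(20)
            if pooled_counts[pi, ai] > 0
        ]
        family_size = len(nonzero)
        chain_results = []
        for pos, aa in nonzero:
            pooled = tally.pooled_table(pos, aa)
            per_donor_tables = {d: tally.table(d, pos, aa) for d in tally.donors}
            degenerate = pooled.degenerate
            tested = (pooled.a + pooled.c) >= min_count and not degenerate
            ratio = math.nan if degenerate else odds_ratio(pooled)
            if mode == "sanger":
                per_donor_p = {}
                cmh_stat = cmh_p = p_adj = None
                pooled_p = fisher_exact_2x2(pooled)
            else:
                per_donor_p = {
                    d: fisher_exact_2x2(t) for d, t in per_donor_tables.items()
                }
                cmh_stat, cmh_p = cmh_test(per_donor_tables)
                pooled_p = None
                p_adj = None  # filled after the family loop
            chain_results.append(
                EnrichmentResult(
                    chain=chain,
                    position=pos,
                    amino_acid=aa,
                    per_donor_tables=per_donor_tables,
                    per_donor_p=per_donor_p,
                    odds_ratio=ratio,
                    cmh_statistic=cmh_stat,
                    cmh_p=cmh_p,
                    pooled_p=pooled_p,
                    p_adjusted=p_adj,
                    direction=_direction(pooled),
                    tested=tested,
                    degenerate=degenerate,
                    family_size=family_size,
                )
            )
        if mode == "ngs":
            raw = [r.cmh_p for r in chain_results]
            adjusted = bonferroni(raw, family_size)
            for r, p in zip(chain_results, adjusted):
                r.p_adjusted = p
        results.extend(chain_results)
    results.sort(key=lambda r: (r.chain, r.position, r.amino_acid))
    return results


def read_enrichment_report(path) -> list[EnrichmentResult]:
    """Read a report TSV back into results (pooled counts as one stratum).

    Per-donor tables are not serialized in the report, so the pooled a/b/c/d
    counts are restored under a single ``pooled`` stratum; everything a
    downstream selection needs (p-values, direction, tested flag, category)
    round-trips exactly.
    """
    from pathlib import Path

    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    results = []
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        table = ContingencyTable2x2(
            a=int(rec["a"]), b=int(rec["b"]), c=int(rec["c"]), d=int(rec["d"])
        )
        per_donor_p = {}
        pooled_p = None
        if rec.get("per_donor_p"):
            for item in rec["per_donor_p"].split(";"):
                donor, p = item.split("=")
                per_donor_p[donor] = float(p)
        if not rec.get("cmh_p") and "pooled" in per_donor_p:
            pooled_p = per_donor_p.pop("pooled")
        results.append(
            EnrichmentResult(
                chain=rec["chain"],
                position=int(rec["imgt_position"]),
                amino_acid=rec["amino_acid"],
                per_donor_tables={"pooled": table},
                per_donor_p=per_donor_p,
                odds_ratio=float(rec["odds_ratio"]),
                cmh_statistic=None,
                cmh_p=float(rec["cmh_p"]) if rec.get("cmh_p") else None,
                pooled_p=pooled_p,
                p_adjusted=float(rec["p_adjusted"]) if rec.get("p_adjusted") else None,
                direction=rec["direction"],
                tested=rec["tested"] == "yes",
                degenerate=table.degenerate,
                family_size=int(rec["family_size"]),
                category=int(rec["category"]) if rec.get("category") else None,
            )
        )
    return results


# ---------------------------------------------------------------------------
# V-gene usage comparison


@dataclass
class UsageComparison:
    gene: str
    chain: str
    per_donor_freq_dominant: list[float]
    per_donor_freq_weak: list[float]
    t_statistic: float | None
    p: float | None
    skipped: bool = False


def compare_v_usage(library: RepertoireLibrary, *, welch: bool = False) -> list[UsageComparison]:
    """Per-gene usage frequencies by donor/phenotype with an unpaired t-test.

    Frequencies are clonotype-weighted proportions of each chain's
    repertoire.  With fewer than two donors frequencies are returned but
    the test is skipped; a gene absent from both arms is likewise skipped.
    """
    donors = sorted(library.donors)
    out: list[UsageComparison] = []
    for chain in CHAINS:
        chain_lib = [c for c in library.clonotypes if c.chain == chain]
        if not chain_lib:
            continue
        genes = sorted({c.v_gene for c in chain_lib})
        for gene in genes:
            freqs = {"dominant": [], "weak": []}
            for phenotype in ("dominant", "weak"):
                for donor in donors:
                    arm = [
                        c for c in chain_lib
                        if c.donor_id == donor and c.phenotype == phenotype
                    ]
                    if arm:
                        freqs[phenotype].append(
                            sum(1 for c in arm if c.v_gene == gene) / len(arm)
                        )
                    else:
                        freqs[phenotype].append(0.0)
            dom, weak = freqs["dominant"], freqs["weak"]
            if len(donors) < 2 or (not any(dom) and not any(weak)):
                out.append(UsageComparison(gene, chain, dom, weak, None, None, skipped=True))
                continue
            if dom == weak:
                out.append(UsageComparison(gene, chain, dom, weak, 0.0, 1.0))
                continue
            t_stat, p = stats.ttest_ind(dom, weak, equal_var=not welch)
            out.append(UsageComparison(gene, chain, dom, weak, float(t_stat), float(p)))
    return out
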