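"""Divergently-paired gene (DPG) calling and spacing classification.

A DPG is a (minus-strand gene, plus-strand gene) pair on the same chromosome
transcribed head-to-head with an inter-TSS distance below 1 kb. The signed
distance is ``plus.tss - minus.tss``: negative values mean the two 5' regions
overlap, positive values leave a shared bidirectional promoter between the
TSSs. Spacing falls into three modes — overlapping (d < 0), optimal (short
positive gap) and distant (large gap) — that differ in co-expression
behaviour and indel pressure.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, GeneModel

logger = logging.getLogger(__name__)

SPACING_CLASSES = ("overlapping", "optimal", "distant", "unclassified")


def inter_tss_distance(minus_gene: GeneModel, plus_gene: GeneModel) -> int:
    """Signed inter-TSS distance, ``plus.tss - minus.tss``.

    Raises ``ValueError`` unless the genes are on the same chromosome with
    minus/plus strands respectively.
    """
    if minus_gene.strand != "-" or plus_gene.strand != "+":
        raise ValueError(
            f"expected (minus, plus) strands, got ({minus_gene.strand}, {plus_gene.strand})"
        )
    if minus_gene.chrom != plus_gene.chrom:
        raise ValueError("genes on different chromosomes")
    return plus_gene.tss - minus_gene.tss


@dataclass(frozen=True)
class DPGPair:
    minus_gene: GeneModel
    plus_gene: GeneModel
    spacing_class: str = "unclassified"

    def __post_init__(self) -> None:
        inter_tss_distance(self.minus_gene, self.plus_gene)  # contract check

    @property
    def chrom(self) -> str:
        return self.minus_gene.chrom

    @property
    def inter_tss_distance(self) -> int:
        return self.plus_gene.tss - self.minus_gene.tss

    @property
    def pair_id(self) -> str:
        return f"{self.minus_gene.gene_id}|{self.plus_gene.gene_id}"

    @property
    def region(self) -> tuple[int, int]:
        """Closed genomic interval between the two TSSs (the shared promoter space)."""
        a, b = self.minus_gene.tss, self.plus_gene.tss
        return (a, b) if a <= b else (b, a)

    @property
    def symbols(self) -> tuple[str | None, str | None]:
        return self.minus_gene.symbol, self.plus_gene.symbol


@dataclass
class DPGSet:
    pairs: list[DPGPair] = field(default_factory=list)
    assembly_name: str = ""
    ambiguity_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def member_ids(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.minus_gene.gene_id)
            out.add(p.plus_gene.gene_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair_id": p.pair_id,
                    "minus_id": p.minus_gene.gene_id,
                    "plus_id": p.plus_gene.gene_id,
                    "minus_symbol": p.minus_gene.symbol,
                    "plus_symbol": p.plus_gene.symbol,
                    "chrom": p.chrom,
                    "tss_minus": p.minus_gene.tss,
                    "tss_plus": p.plus_gene.tss,
                    "inter_tss_distance": p.inter_tss_distance,
                    "spacing_class": p.spacing_class,
                }
                for p in self.pairs
            ]
        )


def _candidate_sort_key(minus: GeneModel, plus: GeneModel):
    # Minimal |d| wins; ties go to the smaller partner TSS (the TSS sum
    # compares partners symmetrically whichever member is contested), then IDs.
    d = plus.tss - minus.tss
    return (abs(d), minus.tss + plus.tss, minus.gene_id, plus.gene_id)


def identify_dpgs(catalog: GeneCatalog, max_dist: int = 1000) -> DPGSet:
    """Call divergent pairs with |inter-TSS distance| < ``max_dist``.

    Candidates are every (minus, plus) gene pair on one chromosome whose TSSs
    lie strictly within ``max_dist`` of each other. A gene can belong to only
    one final pair: when it qualifies for several, the candidate with minimal
    |d| wins (tie-break: smaller partner TSS, then gene IDs); displaced
    candidates are recorded in the ambiguity log.
    """
    candidates: list[tuple[GeneModel, GeneModel]] = []
    for chrom, genes in catalog.by_chrom().items():
        minus = [g for g in genes if g.strand == "-"]
        plus = sorted((g for g in genes if g.strand == "+"), key=lambda g: g.tss)
        plus_tss = [g.tss for g in plus]
        for m in minus:
            lo = bisect_right(plus_tss, m.tss - max_dist)
            hi = bisect_left(plus_tss, m.tss + max_dist)
            for p in plus[lo:hi]:
                if abs(p.tss - m.tss) < max_dist:
                    candidates.append((m, p))
    candidates.sort(key=lambda mp: _candidate_sort_key(*mp))

    used: set[str] = set()
    multi: dict[str, int] = {}
    for m, p in candidates:
        multi[m.gene_id] = multi.get(m.gene_id, 0) + 1
        multi[p.gene_id] = multi.get(p.gene_id, 0) + 1

    pairs: list[DPGPair] = []
    ambiguity: list[str] = []
    for m, p in candidates:
        if m.gene_id in used or p.gene_id in used:
            ambiguity.append(
                f"dropped candidate {m.gene_id}|{p.gene_id} (d={p.tss - m.tss}): member already paired"
            )
            continue
        used.add(m.gene_id)
        used.add(p.gene_id)
        pairs.append(DPGPair(minus_gene=m, plus_gene=p))
    for gid, n in multi.items():
        if n > 1:
            ambiguity.append(f"gene {gid} was eligible for {n} candidate pairs")
    pairs.sort(key=lambda p: (p.chrom, min(p.minus_gene.tss, p.plus_gene.tss), p.pair_id))
    return DPGSet(pairs=pairs, assembly_name=catalog.assembly_name, ambiguity_log=ambiguity)


def classify_spacing(pair: DPGPair, t_distant: int = 500) -> str:
    """Distance-based spacing mode: overlapping / optimal / distant.

    d < 0 means the TSSs have crossed (overlapping 5' regions); 0 <= d <=
    ``t_distant`` is the optimal short shared promoter; larger gaps are
    distant. The |d| < 1 kb pair contract is enforced.
    """
    d = pair.inter_tss_distance
    if abs(d) >= 1000:
        raise ValueError(f"|d|={abs(d)} outside the DPG window")
    if d < 0:
        return "overlapping"
    if d <= t_distant:
        return "optimal"
    return "distant"


def classify_spacing_by_peaks(
    pair: DPGPair, peak_positions, cluster_gap: int = 200
) -> str:
    """Alternative spacing mode from promoter-mark peak positions.

    Heuristic mirror of classifying pairs by where active-promoter peaks
    (e.g. H3K4me3) sit relative to the two TSSs: two separated peak clusters
    mean the promoters act independently (distant); peaks concentrated
    between the TSSs mean one shared promoter (optimal); peaks only outside
    the inter-TSS interval, over the gene bodies, indicate overlapping 5'
    arrangements.
    """
    positions = sorted(int(p) for p in peak_positions)
    if not positions:
        return "unclassified"
    gaps = np.diff(positions)
    n_clusters = 1 + int(np.sum(gaps > cluster_gap))
    if n_clusters >= 2:
        return "distant"
    lo, hi = pair.region
    if any(lo <= p <= hi for p in positions):
        return "optimal"
    return "overlapping"


def classify_all_spacing(dpgset: DPGSet, t_distant: int = 500) -> DPGSet:
    """Return a new set with spacing classes filled in."""
    pairs = [
        DPGPair(p.minus_gene, p.plus_gene, classify_spacing(p, t_distant))
        for p in dpgset.pairs
    ]
    return DPGSet(pairs=pairs, assembly_name=dpgset.assembly_name, ambiguity_log=list(dpgset.ambiguity_log))


def sample_random_pairs(
    catalog: GeneCatalog, n: int, seed: int, exclude: set[str] | None = None
) -> list[tuple[GeneModel, GeneModel]]:
    """Sample ``n`` distinct unordered gene pairs uniformly without replacement.

    The pool is every unordered pair of non-excluded genes; ``seed`` is
    mandatory for reproducibility. Raises ``ValueError`` if ``n`` exceeds the
    number of available pairs.
    """
    exclude = exclude or set()
    genes = sorted((g for g in catalog.genes if g.gene_id not in exclude), key=lambda g: g.gene_id)
    m = len(genes)
    total = m * (m - 1) // 2
    if n > total:
        raise ValueError(f"requested {n} pairs but only {total} are possible")
    rng = np.random.default_rng(seed)
    if total <= 10_000_000:
        idx = rng.choice(total, size=n, replace=False)
    else:  # rejection sampling for very large pools
        chosen: set[int] = set()
        while len(chosen) < n:
            chosen.add(int(rng.integers(total)))
        idx = np.fromiter(chosen, dtype=np.int64)
    def offset(i: int) -> int:
        return i * (2 * m - i - 1) // 2

    pairs = []
    for k in np.sort(idx):
        k = int(k)
        # decode linear index into the (i<j) combination, guarding float sqrt
        i = int((2 * m - 1 - np.sqrt((2 * m - 1) ** 2 - 8 * k)) // 2)
        while i + 1 < m and offset(i + 1) <= k:
            i += 1
        while i > 0 and offset(i) > k:
            i -= 1
        j = k - offset(i) + i + 1
        pairs.append((genes[i], genes[j]))
    return pairs


def all_unordered_pairs(catalog: GeneCatalog):
    """Enumerate every unordered gene pair (reference for small catalogs)."""
    genes = sorted(catalog.genes, key=lambda g: g.gene_id)
    return list(combinations(genes, 2))


def compare_reference_sets(
    dpgset_a: DPGSet, dpgset_b: DPGSet, case_insensitive: bool = False
):
    """Symbol-level comparison of two assemblies' DPG sets.

    A pair matches iff the unordered set of its two gene symbols appears in
    the other set; unmatched pairs are the population/assembly-specific DPGs.
    Pairs missing a symbol cannot be mapped and go to their unique list with
    an ``unmappable`` flag.

    Returns ``(shared, unique_a, unique_b)`` where shared is a list of
    (pair_a, pair_b) tuples and each unique list holds (pair, unmappable).
    """

    def key(pair: DPGPair):
        syms = pair.symbols
        if syms[0] is None or syms[1] is None:
            return None
        if case_insensitive:
            syms = tuple(s.upper() for s in syms)
        return frozenset(syms)

    index_b: dict[frozenset, DPGPair] = {}
    for p in dpgset_b.pairs:
        k = key(p)
        if k is not None:
            index_b[k] = p
    shared: list[tuple[DPGPair, DPGPair]] = []
    unique_a: list[tuple[DPGPair, bool]] = []
    matched_b: set[frozenset] = set()
    for p in dpgset_a.pairs:
        k = key(p)
        if k is None:
            unique_a.append((p, True))
        elif k in index_b:
            shared.append((p, index_b[k]))
            matched_b.add(k)
        else:
            unique_a.append((p, False))
    unique_b = [
        (p, key(p) is None)
        for p in dpgset_b.pairs
        if key(p) is None or key(p) not in matched_b
    ]
    return shared, unique_a, unique_b
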