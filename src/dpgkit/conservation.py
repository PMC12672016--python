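"""Cross-species conservation coding of divergent gene pairs.

Each human pair is scored in every comparison species with a four-level code:

* ``2`` — both members have orthologs and at least one ortholog combination
  forms a divergent pair in the target species (arrangement preserved);
* ``1`` — both members have orthologs but no combination is a target pair
  (the divergent orientation or spacing was lost);
* ``0`` — exactly one member has an ortholog (one gene lost);
* ``-1`` — neither member has an ortholog (both genes lost).

Row-wise the codes form a pairs x species matrix from which the fully
conserved set (vcDPGs, code 2 everywhere) and the orientation-specific set
(osDPGs, code exactly 1 somewhere) are derived. Species are clustered on
their code rows with complete linkage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .annotation import GeneCatalog
from .pairs import DPGPair, DPGSet

logger = logging.getLogger(__name__)

CODES = (2, 1, 0, -1)


@dataclass
class OrthologMap:
    """Many-to-many gene mapping between one species pair."""

    species_pair: tuple[str, str]
    mappings: dict[str, set[str]] = field(default_factory=dict)
    provenance: str = "orthology_run"

    def orthologs(self, gene_id: str) -> set[str]:
        return self.mappings.get(gene_id, set())

    @classmethod
    def from_tsv(cls, path: str, species_pair: tuple[str, str]) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        mappings: dict[str, set[str]] = {}
        for src, tgt in zip(df["source_id"], df["target_id"]):
            mappings.setdefault(src, set()).add(tgt)
        prov = df["provenance"].iloc[0] if "provenance" in df and len(df) else "orthology_run"
        return cls(species_pair=species_pair, mappings=mappings, provenance=prov)

    def to_tsv(self, path: str) -> None:
        rows = [
            {"source_id": s, "target_id": t, "species": self.species_pair[1], "provenance": self.provenance}
            for s, targets in sorted(self.mappings.items())
            for t in sorted(targets)
        ]
        pd.DataFrame(rows, columns=["source_id", "target_id", "species", "provenance"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ConservationMatrix:
    """Pairs x species grid of conservation codes, plus an uncertainty mask.

    The ``uncertain`` flag is set from an explicit exception list (e.g. novel
    genes lacking annotation in a target assembly), never inferred.
    """

    data: pd.DataFrame  # index pair_id, columns species, int codes
    uncertain: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = ~self.data.isin(CODES)
        if bad.to_numpy().any():
            raise ValueError("conservation codes must be in {2, 1, 0, -1}")
        if self.uncertain is None:
            self.uncertain = pd.DataFrame(
                False, index=self.data.index, columns=self.data.columns
            )

    def tally(self) -> pd.DataFrame:
        """Per-species counts of each code."""
        return pd.DataFrame(
            {sp: self.data[sp].value_counts().reindex(CODES, fill_value=0) for sp in self.data.columns}
        ).T

    def mark_uncertain(self, pair_ids, species=None) -> None:
        cols = list(self.data.columns) if species is None else list(species)
        for pid in pair_ids:
            self.uncertain.loc[pid, cols] = True

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t")


def classify_conservation(
    pair: DPGPair,
    ortholog_map: OrthologMap,
    target_catalog: GeneCatalog,
    target_dpgset: DPGSet,
) -> int:
    """Conservation code of one pair in one target species (see module docs).

    With many-to-many orthologs, code 2 requires only that *some* ortholog
    combination forms a target pair — the most favourable reading of
    "orthologous genes maintaining the same orientation".
    """
    orth_minus = ortholog_map.orthologs(pair.minus_gene.gene_id)
    orth_plus = ortholog_map.orthologs(pair.plus_gene.gene_id)
    # restrict to orthologs actually present in the target annotation
    present = {g.gene_id for g in target_catalog.genes}
    orth_minus = orth_minus & present
    orth_plus = orth_plus & present
    if not orth_minus and not orth_plus:
        return -1
    if not orth_minus or not orth_plus:
        return 0
    target_pairs = {
        frozenset((p.minus_gene.gene_id, p.plus_gene.gene_id)) for p in target_dpgset.pairs
    }
    for om in orth_minus:
        for op in orth_plus:
            if frozenset((om, op)) in target_pairs:
                return 2
    return 1


def build_conservation_matrix(
    dpgset: DPGSet,
    species_list: list[str],
    maps: dict[str, OrthologMap],
    catalogs: dict[str, GeneCatalog],
    dpgsets: dict[str, DPGSet] | None = None,
) -> ConservationMatrix:
    """Score every pair in every species. Target DPG sets are taken from
    ``dpgsets`` or called from each catalog on the fly."""
    from .pairs import identify_dpgs

    missing = [sp for sp in species_list if sp not in maps or sp not in catalogs]
    if missing:
        raise ValueError(f"missing ortholog map or catalog for species: {missing}")
    dpgsets = dpgsets or {}
    grid = {}
    for sp in species_list:
        target_set = dpgsets.get(sp) or identify_dpgs(catalogs[sp])
        grid[sp] = [
            classify_conservation(p, maps[sp], catalogs[sp], target_set) for p in dpgset.pairs
        ]
    data = pd.DataFrame(grid, index=[p.pair_id for p in dpgset.pairs])
    # cells are per-(pair, species); column order follows the input list but
    # values are independent of it
    mat = ConservationMatrix(data=data[species_list])
    logger.info("conservation tallies:\n%s", mat.tally())
    return mat


def find_vcdpgs(matrix: ConservationMatrix, min_code: int = 2) -> list[str]:
    """Pairs whose code is >= ``min_code`` in every species (fully conserved)."""
    mask = (matrix.data >= min_code).all(axis=1)
    return list(matrix.data.index[mask])


def find_osdpgs(matrix: ConservationMatrix, species_subset: list[str] | None = None) -> list[str]:
    """Pairs with code exactly 1 (orientation lost, genes kept) in at least
    one species of the subset."""
    cols = list(matrix.data.columns) if species_subset is None else list(species_subset)
    mask = (matrix.data[cols] == 1).any(axis=1)
    return list(matrix.data.index[mask])


def tag_hk_dpgs(dpgset: DPGSet, hk_genes) -> tuple[dict[str, bool], float]:
    """Flag pairs containing at least one housekeeping gene.

    ``hk_genes`` may hold gene IDs or symbols. Returns the per-pair flags and
    the flagged proportion.
    """
    hk = set(hk_genes)
    if not hk:
        warnings.warn("empty housekeeping list: no pair can be flagged", stacklevel=2)
    flags: dict[str, bool] = {}
    for p in dpgset.pairs:
        members = {
            p.minus_gene.gene_id,
            p.plus_gene.gene_id,
            p.minus_gene.symbol,
            p.plus_gene.symbol,
        } - {None}
        flags[p.pair_id] = bool(members & hk)
    prop = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, prop


def read_hk_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def cluster_species(matrix: ConservationMatrix):
    """Complete-linkage hierarchical clustering of species on their code rows.

    Features are the per-pair codes; the metric is Euclidean distance between
    species code vectors. Returns ``(leaf_order, linkage_matrix)`` with a
    deterministic leaf order.
    """
    species = list(matrix.data.columns)
    if len(species) < 2:
        raise ValueError("need at least two species to cluster")
    obs = matrix.data.to_numpy(dtype=float).T  # species x pairs
    link = hierarchy.linkage(obs, method="complete", metric="euclidean")
    order = [species[i] for i in hierarchy.leaves_list(link)]
    return order, link
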