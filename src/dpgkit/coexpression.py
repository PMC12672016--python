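"""Tissue-resolved co-expression of divergent gene pairs.

Expression is TPM per gene per sample with sample-level tissue and RIN
metadata. Samples are quality-filtered (RIN strictly above 6), small tissues
dropped (strictly more than 20 samples required), and each pair's Spearman
rank correlation is computed on ln(TPM+1) across the samples of each tissue.
A pair is co-expressed in a tissue when rho > 0.8 and p < 0.05 (both
strict); generally co-expressed when rho > 0.7 in more than 70% of tissues;
and its overall level — high (> 0.9), medium (0.8-0.9 closed), RLow (< 0.8)
— comes from the maximum rho over tissues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import DPGPair, DPGSet

logger = logging.getLogger(__name__)

LEVELS = ("high", "medium", "RLow")

#: sample sizes below which the Spearman p-value is computed by exact
#: permutation enumeration instead of the t approximation
EXACT_P_MAX_N = 9


@dataclass
class ExpressionStore:
    """Gene x sample TPM matrix plus sample -> (tissue, RIN) metadata."""

    tpm: pd.DataFrame  # genes x samples, TPM >= 0
    sample_meta: pd.DataFrame  # index sample, columns tissue, rin

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.tpm.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_meta.loc[list(self.tpm.columns), "tissue"].unique())

    def samples_in(self, tissue: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.tpm.columns)]
        return list(meta.index[meta["tissue"] == tissue])

    def log_tpm(self) -> pd.DataFrame:
        return np.log1p(self.tpm)

    @classmethod
    def from_tsv(cls, tpm_path: str, meta_path: str) -> "ExpressionStore":
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(tpm=tpm, sample_meta=meta)


@dataclass
class CoexpressionRecord:
    pair_id: str
    tissue: str
    rho: float | None  # None when undefined (zero variance)
    p: float | None
    coexpressed: bool
    n_samples: int


def filter_samples(
    store: ExpressionStore, rin_min: float = 6.0, min_tissue_n: int = 20
) -> ExpressionStore:
    """RIN and tissue-size quality control, both thresholds strict.

    Samples with RIN > ``rin_min`` are kept, then tissues with more than
    ``min_tissue_n`` surviving samples. Raises if no tissue survives.
    """
    meta = store.sample_meta.loc[list(store.tpm.columns)]
    good_rin = meta.index[meta["rin"] > rin_min]
    n_rin_removed = len(meta) - len(good_rin)
    meta = meta.loc[good_rin]
    counts = meta["tissue"].value_counts()
    good_tissues = set(counts.index[counts > min_tissue_n])
    kept = meta.index[meta["tissue"].isin(good_tissues)]
    logger.info(
        "filter_samples: removed %d low-RIN samples, %d small tissues (%d samples kept)",
        n_rin_removed,
        int((~counts.index.isin(good_tissues)).sum()),
        len(kept),
    )
    if not good_tissues:
        raise ValueError("no tissue survives sample filtering")
    return ExpressionStore(tpm=store.tpm[list(kept)], sample_meta=store.sample_meta.loc[kept])


def tissue_median(store: ExpressionStore, log_space: bool = False) -> pd.DataFrame:
    """Per-tissue median expression per gene (raw TPM by default)."""
    values = store.log_tpm() if log_space else store.tpm
    meta = store.sample_meta.loc[list(store.tpm.columns)]
    return values.T.groupby(meta["tissue"]).median().T


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n.

    Enumerates all permutations of y's ranks; p is the fraction of
    permutations with |rho| >= |rho_obs| (within float tolerance).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    denom = math.sqrt(np.sum(rx_c**2))
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    sy = math.sqrt(np.sum(ry_c**2))
    if denom == 0 or sy == 0:
        return float("nan")
    for perm in permutations(range(n)):
        r = float(np.dot(rx_c, ry_c[list(perm)])) / (denom * sy)
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def pair_correlation(
    store: ExpressionStore, gene_a: str, gene_b: str, tissue: str
) -> tuple[float | None, float | None, int]:
    """Spearman rho and two-sided p for two genes across one tissue's samples.

    Computed on ln(TPM+1) with average-rank tie handling. The p-value uses
    the t approximation at n >= 10 and exact permutation enumeration below.
    Zero variance in either gene leaves rho undefined (``None``).
    Returns ``(rho, p, n_samples)``.
    """
    samples = store.samples_in(tissue)
    if len(samples) < 3:
        raise ValueError(f"tissue {tissue!r} has fewer than 3 samples")
    logv = np.log1p(store.tpm.loc[[gene_a, gene_b], samples].to_numpy(dtype=float))
    x, y = logv[0], logv[1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None, len(samples)
    rho, p = stats.spearmanr(x, y)
    if len(samples) <= EXACT_P_MAX_N:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p), len(samples)


def flag_coexpressed(rho: float | None, p: float | None, rho_min: float = 0.8, p_max: float = 0.05) -> bool:
    """Strict thresholds: co-expressed iff rho > rho_min and p < p_max."""
    if rho is None or p is None or math.isnan(p):
        return False
    return rho > rho_min and p < p_max


def flag_generally_coexpressed(rhos, rho_min: float = 0.7, frac_min: float = 0.7) -> bool:
    """True iff rho > ``rho_min`` in strictly more than ``frac_min`` of tissues.

    ``rhos`` is the pair's per-tissue rho list; undefined entries count
    against the fraction's denominator but can never pass the threshold.
    """
    values = list(rhos)
    if not values:
        return False
    n_pass = sum(1 for r in values if r is not None and r > rho_min)
    return n_pass / len(values) > frac_min


def classify_level(rhos) -> str | None:
    """Co-expression level from the max rho over tissues.

    > 0.9 high; 0.8-0.9 (closed interval) medium; < 0.8 RLow. Undefined rhos
    are excluded; with nothing defined the pair is unclassifiable (``None``).
    """
    defined = [r for r in rhos if r is not None and not math.isnan(r)]
    if not defined:
        return None
    top = max(defined)
    if top > 0.9:
        return "high"
    if top >= 0.8:
        return "medium"
    return "RLow"


def expression_fold_change(
    pair: DPGPair, records: list[CoexpressionRecord], medians: pd.DataFrame
) -> float | None:
    """Fold change between the pair's members in the best-correlated tissue.

    The tissue t* maximises rho (ties go to the smallest tissue name, logged);
    fc = higher/lower tissue-median TPM there. A zero lower median leaves the
    fold change undefined (``None``), never infinite.
    """
    defined = [r for r in records if r.rho is not None]
    if not defined:
        raise ValueError("no tissue with a defined correlation")
    best_rho = max(r.rho for r in defined)
    best = sorted(r.tissue for r in defined if r.rho == best_rho)
    if len(best) > 1:
        logger.info("fold-change tissue tie for %s: %s -> %s", pair.pair_id, best, best[0])
    t_star = best[0]
    a = float(medians.loc[pair.minus_gene.gene_id, t_star])
    b = float(medians.loc[pair.plus_gene.gene_id, t_star])
    lo, hi = min(a, b), max(a, b)
    if lo == 0:
        return None
    return hi / lo


def score_pairs(
    store: ExpressionStore, dpgset: DPGSet, rho_min: float = 0.8, p_max: float = 0.05
) -> pd.DataFrame:
    """Per-(pair, tissue) correlation table for a whole pair set."""
    rows = []
    for pair in dpgset.pairs:
        for tissue in store.tissues:
            rho, p, n = pair_correlation(
                store, pair.minus_gene.gene_id, pair.plus_gene.gene_id, tissue
            )
            rows.append(
                {
                    "pair_id": pair.pair_id,
                    "tissue": tissue,
                    "rho": np.nan if rho is None else rho,
                    "p": np.nan if p is None else p,
                    "coexpressed": flag_coexpressed(rho, p, rho_min, p_max),
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame, pair_id: str) -> list[CoexpressionRecord]:
    sub = df[df["pair_id"] == pair_id]
    return [
        CoexpressionRecord(
            pair_id=pair_id,
            tissue=r.tissue,
            rho=None if pd.isna(r.rho) else float(r.rho),
            p=None if pd.isna(r.p) else float(r.p),
            coexpressed=bool(r.coexpressed),
            n_samples=int(r.n_samples),
        )
        for r in sub.itertuples()
    ]


def coexpression_vs_random(dpg_flags, random_flags):
    """2x2 association between pair type (DPG vs random) and co-expression.

    Each argument is an iterable of booleans, one per pair (co-expressed in
    at least one tissue). Returns the table and the selected test's result
    via :func:`dpgkit.stats.compare_proportions`.
    """
    from .stats import compare_proportions

    d = list(map(bool, dpg_flags))
    r = list(map(bool, random_flags))
    table = [[sum(d), len(d) - sum(d)], [sum(r), len(r) - sum(r)]]
    return table, compare_proportions(table)
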