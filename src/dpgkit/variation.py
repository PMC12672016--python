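"""Population indel pressure on the shared inter-TSS promoter space.

Indels from a population VCF are filtered on allele frequency (>= 0.005)
and length change (>= 2 bp, both inclusive), assigned to each pair whose
closed inter-TSS interval contains the variant position, and aggregated
into 50-bp inter-TSS-distance bins spanning -1 kb .. 1 kb. The per-bin
deletion/insertion ratio is only reported where more than one insertion
was observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import DPGSet

logger = logging.getLogger(__name__)

BIN_WIDTH = 50
BIN_MIN = -1000
BIN_MAX = 1000
N_BINS = (BIN_MAX - BIN_MIN) // BIN_WIDTH  # 40 half-open bins


@dataclass(frozen=True)
class IndelRecord:
    chrom: str
    pos: int  # 1-based anchor position
    ref: str
    alt: str
    af: float | None

    @property
    def length_change(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def kind(self) -> str:
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        raise ValueError("not an indel: ref and alt have equal length")


def read_indels(path: str) -> list[IndelRecord]:
    """Read indels from a VCF; AF is taken from the INFO AF field.

    Multi-allelic records contribute one indel per length-changing allele;
    same-length alleles (SNVs, MNVs) are skipped. The parser upstream holds
    AF at float32 precision, so values are rounded back to 6 decimals — the
    frequency threshold then behaves exactly as the printed VCF text.
    """
    from cyvcf2 import VCF

    records: list[IndelRecord] = []
    for v in VCF(path):
        af = v.INFO.get("AF")
        afs = list(af) if isinstance(af, (tuple, list)) else [af] * len(v.ALT)
        for alt, a in zip(v.ALT, afs):
            if len(alt) == len(v.REF):
                continue
            records.append(
                IndelRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    af=None if a is None else round(float(a), 6),
                )
            )
    return records


def filter_indels(
    records, af_min: float = 0.005, len_min: int = 2
) -> list[IndelRecord]:
    """Keep indels with AF >= ``af_min`` and length change >= ``len_min``
    (both inclusive). Records without an AF are dropped and counted."""
    kept: list[IndelRecord] = []
    n_no_af = 0
    for r in records:
        if r.af is None:
            n_no_af += 1
            continue
        if r.af >= af_min and r.length_change >= len_min:
            kept.append(r)
    if n_no_af:
        logger.warning("filter_indels dropped %d records without an AF", n_no_af)
    return kept


def assign_indels(records, dpgset: DPGSet) -> dict[str, dict[str, int]]:
    """Per-pair insertion/deletion counts over the closed inter-TSS interval.

    An indel at a TSS coordinate counts (closed interval); abutting regions
    can both claim the same indel.
    """
    counts = {
        p.pair_id: {"insertion": 0, "deletion": 0} for p in dpgset.pairs
    }
    by_chrom: dict[str, list] = {}
    for p in dpgset.pairs:
        by_chrom.setdefault(p.chrom, []).append(p)
    for r in records:
        for p in by_chrom.get(r.chrom, []):
            lo, hi = p.region
            if lo <= r.pos <= hi:
                counts[p.pair_id][r.kind] += 1
    return counts


def bin_index(d: int) -> int:
    """50-bp bin index for an inter-TSS distance in (-1000, 1000)."""
    if not (BIN_MIN < d < BIN_MAX):
        raise ValueError(f"inter-TSS distance {d} outside ({BIN_MIN}, {BIN_MAX})")
    return (d - BIN_MIN) // BIN_WIDTH


def del_ins_ratio(n_deletions: int, n_insertions: int) -> float | None:
    """Deletion/insertion ratio, defined only when insertions exceed 1."""
    if n_insertions > 1:
        return n_deletions / n_insertions
    return None


def bin_by_spacing(per_pair_counts: dict[str, dict[str, int]], dpgset: DPGSet) -> pd.DataFrame:
    """Aggregate per-pair indel counts into the 40 spacing bins.

    Each pair contributes its counts to the bin containing its inter-TSS
    distance. Columns report pair counts, raw insertion/deletion totals,
    per-pair means, and the guarded deletion/insertion ratio.
    """
    edges = np.arange(BIN_MIN, BIN_MAX + BIN_WIDTH, BIN_WIDTH)
    n_dpgs = np.zeros(N_BINS, dtype=int)
    n_ins = np.zeros(N_BINS, dtype=int)
    n_del = np.zeros(N_BINS, dtype=int)
    for p in dpgset.pairs:
        b = bin_index(p.inter_tss_distance)
        n_dpgs[b] += 1
        c = per_pair_counts.get(p.pair_id, {"insertion": 0, "deletion": 0})
        n_ins[b] += c["insertion"]
        n_del[b] += c["deletion"]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ins = np.where(n_dpgs > 0, n_ins / np.maximum(n_dpgs, 1), np.nan)
        mean_del = np.where(n_dpgs > 0, n_del / np.maximum(n_dpgs, 1), np.nan)
    ratio = [del_ins_ratio(int(d), int(i)) for d, i in zip(n_del, n_ins)]
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "n_dpgs": n_dpgs,
            "n_insertions": n_ins,
            "n_deletions": n_del,
            "mean_insertions_per_dpg": mean_ins,
            "mean_deletions_per_dpg": mean_del,
            "del_ins_ratio": [np.nan if r is None else r for r in ratio],
        }
    )
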