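"""Regulatory signal profiles over the shared inter-TSS space.

Because inter-TSS spacings vary from overlapping to nearly 1 kb, signals
between the two TSSs are rescaled onto a common 1000-position axis before
averaging: each pair's inter-TSS interval is integrated into 1000 equal
segments (exact piecewise-constant integration, so constant tracks are
preserved bit-for-bit in expectation) and oriented from the minus-gene TSS
to the plus-gene TSS. Fixed-width flanks are appended unscaled at native
1 bp resolution. Group averages over co-expression levels give the
metaprofiles; peaks are located with standard prominence-based detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .coexpression import ExpressionStore
from .pairs import DPGPair

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SignalTrack:
    """Sparse per-chromosome signal: sorted non-overlapping intervals.

    Intervals are stored 1-based inclusive; uncovered bases read as 0.
    """

    label: str = ""
    _chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_intervals(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts)
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"{chrom}: overlapping intervals")
        if np.any(ends < starts):
            raise ValueError(f"{chrom}: interval end before start")
        self._chroms[chrom] = (starts, ends, values)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over the closed interval [start, end]."""
        if end < start:
            raise ValueError("end < start")
        out = np.zeros(end - start + 1)
        if chrom not in self._chroms:
            return out
        starts, ends, values = self._chroms[chrom]
        i = int(np.searchsorted(ends, start, side="left"))
        while i < len(starts) and starts[i] <= end:
            lo = max(starts[i], start)
            hi = min(ends[i], end)
            if lo <= hi:
                out[lo - start : hi - start + 1] = values[i]
            i += 1
        return out

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        return float(self.per_base(chrom, start, end).mean())

    @classmethod
    def from_bedgraph(cls, path: str, label: str = "") -> "SignalTrack":
        """Read a bedGraph (0-based half-open) into 1-based inclusive storage."""
        import io

        with open(path) as fh:
            body = "".join(
                line
                for line in fh
                if line.strip() and not line.startswith(("#", "track", "browser"))
            )
        df = pd.read_csv(
            io.StringIO(body),
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        track = cls(label=label)
        for chrom, sub in df.groupby("chrom", sort=False):
            track.add_intervals(
                chrom,
                sub["start"].astype(np.int64) + 1,
                sub["end"].astype(np.int64),
                sub["value"].astype(float),
            )
        return track

    @classmethod
    def from_bigwig(cls, path: str, label: str = "") -> "SignalTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(path)
        track = cls(label=label)
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if ivs:
                starts, ends, values = zip(*ivs)
                track.add_intervals(chrom, np.array(starts) + 1, np.array(ends), values)
        bw.close()
        return track


@dataclass
class MetaProfile:
    label: str
    values: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metaprofile contains non-finite values")


def gc_profile(sequence: str, window: int = 50, step: int = 3) -> np.ndarray:
    """Sliding-window GC fraction along a sequence.

    Windows start at 0, step, 2*step, ... while they fit. The fraction counts
    G/C among non-N bases; an all-N window yields NaN. A sequence shorter
    than the window gives an empty profile with a warning.
    """
    seq = sequence.upper()
    if len(seq) < window:
        warnings.warn("sequence shorter than the GC window", stacklevel=2)
        return np.empty(0)
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    valid = (is_gc != ord("N")).astype(float)
    cg = np.concatenate([[0.0], np.cumsum(gc)])
    cv = np.concatenate([[0.0], np.cumsum(valid)])
    starts = np.arange(0, len(seq) - window + 1, step)
    num = cg[starts + window] - cg[starts]
    den = cv[starts + window] - cv[starts]
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def _resample_exact(x: np.ndarray, bins: int) -> np.ndarray:
    """Integral resampling of a per-base signal onto ``bins`` equal segments.

    Treats the signal as piecewise constant over unit bases and returns each
    segment's mean; exact for any length ratio, so constants are preserved.
    """
    L = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    edges = np.linspace(0.0, L, bins + 1)
    s = np.interp(edges, np.arange(L + 1), cs)
    return np.diff(s) / (L / bins)


def extract_scaled_profile(
    track: SignalTrack, pair: DPGPair, bins: int = 1000, flank: int = 500
) -> np.ndarray:
    """Inter-TSS signal rescaled to ``bins`` positions with unscaled flanks.

    The closed interval between the two TSSs is resampled to ``bins`` equal
    segments and oriented from the minus-gene TSS toward the plus-gene TSS;
    ``flank`` bases on each side are appended at native resolution. A
    zero-length interval (d = 0) replicates the single-base value.
    """
    lo, hi = pair.region
    full = track.per_base(pair.chrom, lo - flank, hi + flank)
    if pair.minus_gene.tss > pair.plus_gene.tss:
        full = full[::-1]
    left = full[:flank]
    core = full[flank : len(full) - flank]
    right = full[len(full) - flank :] if flank else full[len(full):]
    if len(core) == 1:
        scaled = np.full(bins, core[0])
    else:
        scaled = _resample_exact(core, bins)
    return np.concatenate([left, scaled, right])


def group_average_profiles(
    profiles: dict[str, np.ndarray], levels: dict[str, str]
) -> dict[str, MetaProfile]:
    """Positionwise mean profile per co-expression level group."""
    groups: dict[str, list[np.ndarray]] = {}
    for pair_id, prof in profiles.items():
        level = levels.get(pair_id)
        if level is None:
            continue
        groups.setdefault(level, []).append(np.asarray(prof, dtype=float))
    out: dict[str, MetaProfile] = {}
    for level, vecs in groups.items():
        if not vecs:
            warnings.warn(f"empty profile group {level!r} omitted", stacklevel=2)
            continue
        out[level] = MetaProfile(label=level, values=np.mean(vecs, axis=0), n_pairs=len(vecs))
    return out


def detect_signal_peaks(profile: np.ndarray, min_prominence: float | None = None) -> list[int]:
    """Local maxima above a prominence threshold, ordered by position.

    The default prominence is 10% of the profile's value range; flat profiles
    have no peaks. Plateau maxima report their leftmost index.
    """
    profile = np.asarray(profile, dtype=float)
    rng = float(np.ptp(profile))
    if rng == 0:
        return []
    prom = 0.1 * rng if min_prominence is None else min_prominence
    _, props = find_peaks(profile, prominence=prom, plateau_size=1)
    return [int(i) for i in props["left_edges"]]


def promoter_signal_fc(track: SignalTrack, pair: DPGPair, window: int = 250) -> float | None:
    """Fold change between the two promoters' mean signals (+-window around
    each TSS); undefined (``None``) when the lower intensity is zero."""
    a = track.mean_over(pair.chrom, pair.minus_gene.tss - window, pair.minus_gene.tss + window)
    b = track.mean_over(pair.chrom, pair.plus_gene.tss - window, pair.plus_gene.tss + window)
    lo, hi = min(a, b), max(a, b)
    if lo == 0:
        return None
    return hi / lo


def average_tracks(tracks: list[SignalTrack], label: str = "mean") -> SignalTrack:
    """Positionwise mean of several tracks (e.g. across cell types)."""
    if not tracks:
        raise ValueError("no tracks to average")
    out = SignalTrack(label=label)
    chroms = sorted({c for t in tracks for c in t._chroms})
    for chrom in chroms:
        points = sorted(
            {int(s) for t in tracks if chrom in t._chroms for s in t._chroms[chrom][0]}
            | {int(e) + 1 for t in tracks if chrom in t._chroms for e in t._chroms[chrom][1]}
        )
        starts, ends, values = [], [], []
        for a, b in zip(points[:-1], points[1:]):
            v = float(np.mean([t.per_base(chrom, a, a)[0] for t in tracks]))
            if starts and values[-1] == v and ends[-1] == a - 1:
                ends[-1] = b - 1
            else:
                starts.append(a)
                ends.append(b - 1)
                values.append(v)
        keep = [i for i, v in enumerate(values) if v != 0]
        if keep:
            out.add_intervals(
                chrom,
                [starts[i] for i in keep],
                [ends[i] for i in keep],
                [values[i] for i in keep],
            )
    return out


def shared_tfs(hit_table: pd.DataFrame, pair: DPGPair) -> set[str]:
    """TFs with at least one motif hit on each member's promoter region.

    ``hit_table`` rows carry (region_id, tf_id, start, stop, score, strand)
    where region_id names the gene whose regulatory region was scanned.
    """
    if hit_table.empty:
        return set()
    by_region = hit_table.groupby("region_id")["tf_id"].agg(set)
    a = by_region.get(pair.minus_gene.gene_id, set())
    b = by_region.get(pair.plus_gene.gene_id, set())
    return set(a) & set(b)


def select_core_tfs(
    tf_ids, store: ExpressionStore, pair: DPGPair, k: int = 3
) -> list[tuple[str, float]]:
    """Rank shared TFs by mean co-expression with the pair's two members.

    Each TF's score is the mean Spearman rho against the two member genes
    over all tissues; the top ``k`` by score (ties by TF id) are the core
    TFs. TFs absent from the expression store are skipped with a log entry.
    """
    from .coexpression import pair_correlation

    scores: list[tuple[str, float]] = []
    for tf in sorted(set(tf_ids)):
        if tf not in store.tpm.index:
            logger.info("select_core_tfs: %s absent from expression store", tf)
            continue
        rhos: list[float] = []
        for member in (pair.minus_gene.gene_id, pair.plus_gene.gene_id):
            if member not in store.tpm.index:
                continue
            for tissue in store.tissues:
                rho, _, _ = pair_correlation(store, tf, member, tissue)
                if rho is not None:
                    rhos.append(rho)
        if rhos:
            scores.append((tf, float(np.mean(rhos))))
    scores.sort(key=lambda s: (-s[1], s[0]))
    return scores[:k]
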