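"""Format-faithful synthetic fixtures with planted ground truth.

Every pipeline stage consumes a standard file format (GFF3, TSV, bedGraph,
VCF, aligned FASTA); this module generates each of them from a single
:class:`FixtureSpec` and a seed, together with a machine-readable truth
manifest, so that recovery can be checked exactly.

The planted study conditions mirror the head-to-head pair biology: spacing
is drawn from a three-component truncated-normal mixture (overlapping
centred at -469 bp, optimal at +95 bp, distant at +976 bp, weighted
0.29/0.60/0.11 after the relative abundances of the three modes);
conservation codes are drawn per species from a categorical distribution
and realised structurally in a target annotation; expression is a Gaussian
copula with log-normal TPM marginals at planted Spearman targets; signal
tracks carry a Gaussian bump at each pair's inter-TSS midpoint with
amplitude tied to its co-expression level; indels are Poisson per region
with controlled allele frequencies and length changes; and three-way
alignments contain planted focal-deletion and sister-insertion gap blocks.

Every generator is a pure function of (spec, seed): generator k uses the
independent stream ``default_rng([seed, k])``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .alignment import EventBlock, ThreeWayAlignment
from .annotation import GeneCatalog, GeneModel
from .coexpression import ExpressionStore
from .conservation import OrthologMap
from .pairs import DPGSet, identify_dpgs
from .signals import SignalTrack
from .variation import IndelRecord

_BASES = np.array(list("ACGT"))

# substream ids so each generator has an independent, reproducible stream
_STREAM_ANNOTATION = 1
_STREAM_ORTHOLOGS = 2
_STREAM_EXPRESSION = 3
_STREAM_SIGNAL = 4
_STREAM_INDELS = 5
_STREAM_ALIGNMENT = 6
_STREAM_RANDOM_CATALOG = 7


@dataclass
class FixtureSpec:
    """All knobs for the synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_dpgs: int = 150
    # spacing mixture: (weight, mean, sd, lo, hi) with integer support [lo, hi]
    spacing_mixture: tuple = (
        (0.29, -469.0, 150.0, -999, -1),  # overlapping
        (0.60, 95.0, 80.0, 0, 500),  # optimal
        (0.11, 976.0, 20.0, 501, 999),  # distant
    )
    n_decoy_same_strand: int = 20
    n_decoy_far: int = 20
    n_decoy_convergent: int = 10
    n_decoy_noncoding: int = 10
    n_chroms: int = 2
    unit_spacing: int = 20_000
    gene_len_range: tuple[int, int] = (1_000, 5_000)
    # cross-species conservation class probabilities
    conservation_probs: dict = field(
        default_factory=lambda: {2: 0.5, 1: 0.2, 0: 0.2, -1: 0.1}
    )
    many_to_many_frac: float = 0.1
    # co-expression: (target Spearman rho, weight); levels follow the rho
    rho_levels: tuple = ((0.95, 0.25), (0.85, 0.35), (0.30, 0.40))
    tissues: tuple = ("T01", "T02", "T03", "T04", "T05")
    n_per_tissue: int = 50
    n_low_rin_samples: int = 5
    n_small_tissue_samples: int = 10
    log_tpm_mean: float = 2.0
    log_tpm_gene_sd: float = 0.8
    log_tpm_sigma: float = 1.0
    # signal bump amplitude per co-expression level
    signal_amplitude: dict = field(
        default_factory=lambda: {"high": 10.0, "medium": 5.0, "RLow": 2.0}
    )
    # indels: mean passing/failing counts per inter-TSS region; insertion
    # probability by spacing class (overlapping regions lean to insertions)
    indel_rate: float = 3.0
    indel_fail_rate: float = 1.5
    insertion_prob: dict = field(
        default_factory=lambda: {"overlapping": 0.65, "optimal": 0.35, "distant": 0.35}
    )
    # three-way alignments
    aln_ancestral_len: int = 1_500
    n_focal_lost: int = 3
    n_sister_insertion: int = 3
    n_other_events: int = 1
    aln_event_len_range: tuple[int, int] = (2, 12)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def spacing_class_of(d: int, t_distant: int = 500) -> str:
    if d < 0:
        return "overlapping"
    return "optimal" if d <= t_distant else "distant"


def _draw_spacing(spec: FixtureSpec, rng: np.random.Generator) -> int:
    weights = np.array([c[0] for c in spec.spacing_mixture])
    k = rng.choice(len(weights), p=weights / weights.sum())
    _, mean, sd, lo, hi = spec.spacing_mixture[k]
    while True:  # truncated-normal rejection on integer support
        d = int(round(rng.normal(mean, sd)))
        if lo <= d <= hi:
            return d


# ---------------------------------------------------------------------------
# annotation


def build_annotation(spec: FixtureSpec) -> tuple[GeneCatalog, dict]:
    """In-memory synthetic catalog with planted pairs and decoys.

    Pair units are spaced ``unit_spacing`` apart so planted pairs never
    interfere with each other or with decoys. Decoys exercise every reason a
    gene must *not* pair: same strand, opposite strands too far apart,
    convergent orientation, and non-coding biotype.
    """
    rng = spec.rng(_STREAM_ANNOTATION)
    genes: list[GeneModel] = []
    truth_pairs: list[dict] = []
    cursors = {f"chr{c + 1}": 10_000 for c in range(spec.n_chroms)}
    chrom_names = sorted(cursors)

    def glen() -> int:
        return int(rng.integers(*spec.gene_len_range))

    def place(chrom: str, advance: int) -> int:
        pos = cursors[chrom]
        cursors[chrom] = pos + advance + spec.unit_spacing
        return pos

    for i in range(spec.n_dpgs):
        chrom = chrom_names[i % spec.n_chroms]
        d = _draw_spacing(spec, rng)
        lm, lp = glen(), glen()
        anchor = place(chrom, lm + lp + abs(d))
        tss_minus = anchor + lm
        tss_plus = tss_minus + d
        minus = GeneModel(
            gene_id=f"GM{i:04d}",
            symbol=f"SYM{i:04d}A",
            chrom=chrom,
            strand="-",
            start=tss_minus - lm + 1,
            end=tss_minus,
            biotype="protein_coding",
            tss=tss_minus,
            canonical_length=lm,
        )
        plus = GeneModel(
            gene_id=f"GP{i:04d}",
            symbol=f"SYM{i:04d}B",
            chrom=chrom,
            strand="+",
            start=tss_plus,
            end=tss_plus + lp - 1,
            biotype="protein_coding",
            tss=tss_plus,
            canonical_length=lp,
        )
        genes.extend([minus, plus])
        truth_pairs.append(
            {
                "minus_id": minus.gene_id,
                "plus_id": plus.gene_id,
                "chrom": chrom,
                "tss_minus": tss_minus,
                "tss_plus": tss_plus,
                "d": d,
                "spacing_class": spacing_class_of(d),
            }
        )

    def decoy_gene(tag: str, i: int, chrom: str, strand: str, tss: int, length: int, biotype: str = "protein_coding") -> GeneModel:
        if strand == "+":
            start, end = tss, tss + length - 1
        else:
            start, end = tss - length + 1, tss
        return GeneModel(
            gene_id=f"{tag}{i:04d}",
            symbol=f"{tag}SYM{i:04d}",
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            biotype=biotype,
            tss=tss,
            canonical_length=length,
        )

    for i in range(spec.n_decoy_same_strand):
        chrom = chrom_names[i % spec.n_chroms]
        l1, l2 = glen(), glen()
        gap = int(rng.integers(100, 900))
        anchor = place(chrom, l1 + gap + l2)
        genes.append(decoy_gene("DS", 2 * i, chrom, "+", anchor, l1))
        genes.append(decoy_gene("DS", 2 * i + 1, chrom, "+", anchor + l1 + gap, l2))
    for i in range(spec.n_decoy_far):
        chrom = chrom_names[i % spec.n_chroms]
        l1, l2 = glen(), glen()
        d = int(rng.integers(1200, 5000))
        anchor = place(chrom, l1 + d + l2)
        genes.append(decoy_gene("DF", 2 * i, chrom, "-", anchor + l1, l1))
        genes.append(decoy_gene("DF", 2 * i + 1, chrom, "+", anchor + l1 + d, l2))
    for i in range(spec.n_decoy_convergent):
        chrom = chrom_names[i % spec.n_chroms]
        l1, l2 = glen(), glen()
        gap = int(rng.integers(200, 900))
        anchor = place(chrom, l1 + gap + l2)
        # '+' gene then '-' gene facing it: TSSs at the outer ends
        genes.append(decoy_gene("DC", 2 * i, chrom, "+", anchor, l1))
        genes.append(decoy_gene("DC", 2 * i + 1, chrom, "-", anchor + l1 + gap + l2 - 1, l2))
    for i in range(spec.n_decoy_noncoding):
        chrom = chrom_names[i % spec.n_chroms]
        length = glen()
        anchor = place(chrom, length)
        genes.append(decoy_gene("DN", i, chrom, "-", anchor + length, length, biotype="lncRNA"))

    catalog = GeneCatalog(genes=genes, assembly_name=f"synthetic_seed{spec.seed}")
    truth = {
        "seed": spec.seed,
        "n_genes": len(genes),
        "pairs": truth_pairs,
        "n_decoy_noncoding": spec.n_decoy_noncoding,
    }
    return catalog, truth


def _convergent_check(genes: list[GeneModel]) -> None:  # pragma: no cover
    pass


def write_annotation_gff3(catalog: GeneCatalog, path: str, rng: np.random.Generator | None = None) -> None:
    """Write the synthetic catalog as GFF3 with multi-transcript genes.

    Every gene gets its canonical (full-span) transcript plus, for roughly a
    third of genes, a shorter decoy transcript whose span would shift the
    TSS if the longest-transcript rule were violated.
    """
    rng = rng or np.random.default_rng(0)
    lines = ["##gff-version 3"]
    for g in sorted(catalog.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        if g.symbol:
            attrs += f";Name={g.symbol}"
        lines.append(f"{g.chrom}\tdpgkit-sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}")
        lines.append(
            f"{g.chrom}\tdpgkit-sim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.t1;Parent={g.gene_id}"
        )
        if rng.random() < 0.33 and g.end - g.start + 1 > 400:
            trim = int(rng.integers(100, min(300, g.end - g.start)))
            if g.strand == "+":
                t_start, t_end = g.start + trim, g.end
            else:
                t_start, t_end = g.start, g.end - trim
            lines.append(
                f"{g.chrom}\tdpgkit-sim\tmRNA\t{t_start}\t{t_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t2;Parent={g.gene_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def simulate_annotation(spec: FixtureSpec, gff_path: str, manifest_path: str | None = None) -> tuple[GeneCatalog, dict]:
    """Write the planted annotation to GFF3 (+ JSON truth manifest)."""
    catalog, truth = build_annotation(spec)
    write_annotation_gff3(catalog, gff_path, rng=spec.rng(_STREAM_ANNOTATION + 100))
    if manifest_path:
        with open(manifest_path, "w") as fh:
            json.dump(truth, fh, indent=2)
    return catalog, truth


def random_catalog(n_genes: int, seed: int, n_chroms: int = 2, span: int = 300_000) -> GeneCatalog:
    """Unstructured random catalog for stress/oracle testing.

    Genes land uniformly with random strands and may overlap arbitrarily, so
    multi-candidate pairing and tie resolution are exercised.
    """
    rng = np.random.default_rng([seed, _STREAM_RANDOM_CATALOG])
    genes = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(n_chroms)) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(500, 3_000))
        tss = int(rng.integers(length + 10, span))
        if strand == "+":
            start, end = tss, tss + length - 1
        else:
            start, end = tss - length + 1, tss
        genes.append(
            GeneModel(
                gene_id=f"R{i:05d}",
                symbol=f"RS{i:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                biotype="protein_coding",
                tss=tss,
                canonical_length=length,
            )
        )
    return GeneCatalog(genes=genes, assembly_name=f"random_seed{seed}")


# ---------------------------------------------------------------------------
# orthologs / conservation


@dataclass
class SpeciesFixture:
    species: str
    ortholog_map: OrthologMap
    catalog: GeneCatalog
    dpgset: DPGSet
    codes: dict[str, int]  # pair_id -> planted conservation code


def simulate_orthologs(
    spec: FixtureSpec, dpgset: DPGSet, species_list: list[str]
) -> dict[str, SpeciesFixture]:
    """Per species: draw a conservation code per pair and realise it.

    Code 2 places both orthologs as a divergent pair (< 1 kb) in the target
    annotation; code 1 places both on the same strand (orientation lost);
    code 0 keeps only the minus member's ortholog; code -1 omits both. A
    fraction of code-2 pairs get an extra, non-pairing ortholog to exercise
    the many-to-many rule.
    """
    rng = spec.rng(_STREAM_ORTHOLOGS)
    codes_alphabet = np.array(list(spec.conservation_probs))
    probs = np.array([spec.conservation_probs[c] for c in codes_alphabet], dtype=float)
    probs /= probs.sum()
    out: dict[str, SpeciesFixture] = {}
    for sp in species_list:
        mappings: dict[str, set[str]] = {}
        genes: list[GeneModel] = []
        codes: dict[str, int] = {}
        cursor = 10_000
        n = 0

        def add_gene(strand: str, tss: int, length: int = 1_500) -> GeneModel:
            nonlocal n
            if strand == "+":
                start, end = tss, tss + length - 1
            else:
                start, end = tss - length + 1, tss
            g = GeneModel(
                gene_id=f"{sp}_G{n:05d}",
                symbol=None,
                chrom="chr1",
                strand=strand,
                start=start,
                end=end,
                biotype="protein_coding",
                tss=tss,
                canonical_length=length,
            )
            n += 1
            genes.append(g)
            return g

        for pair in dpgset.pairs:
            code = int(rng.choice(codes_alphabet, p=probs))
            codes[pair.pair_id] = code
            if code == 2:
                d = _draw_spacing(spec, rng)
                t_minus = add_gene("-", cursor + 1_600)
                t_plus = add_gene("+", t_minus.tss + d)
                cursor = max(t_minus.end, t_plus.end) + spec.unit_spacing
                mappings[pair.minus_gene.gene_id] = {t_minus.gene_id}
                mappings[pair.plus_gene.gene_id] = {t_plus.gene_id}
                if rng.random() < spec.many_to_many_frac:
                    extra = add_gene("-", cursor + 1_600)
                    cursor = extra.end + spec.unit_spacing
                    mappings[pair.minus_gene.gene_id].add(extra.gene_id)
            elif code == 1:
                a = add_gene("+", cursor + 1_600)
                b = add_gene("+", a.tss + 5_000)
                cursor = b.end + spec.unit_spacing
                mappings[pair.minus_gene.gene_id] = {a.gene_id}
                mappings[pair.plus_gene.gene_id] = {b.gene_id}
            elif code == 0:
                a = add_gene("-", cursor + 1_600)
                cursor = a.end + spec.unit_spacing
                mappings[pair.minus_gene.gene_id] = {a.gene_id}
            # code -1: no orthologs at all
        catalog = GeneCatalog(genes=genes, assembly_name=sp)
        out[sp] = SpeciesFixture(
            species=sp,
            ortholog_map=OrthologMap(species_pair=("focal", sp), mappings=mappings),
            catalog=catalog,
            dpgset=identify_dpgs(catalog),
            codes=codes,
        )
    return out


# ---------------------------------------------------------------------------
# expression


def spearman_to_pearson(rho_s: float) -> float:
    """Copula correlation giving a bivariate-normal Spearman of ``rho_s``."""
    if not -1 <= rho_s <= 1:
        raise ValueError(f"|rho| must be <= 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def copula_pair_tpm(
    rho_s: float,
    n: int,
    rng: np.random.Generator,
    mu: tuple[float, float] = (2.0, 2.0),
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One tissue's TPM vectors for a pair at a target Spearman correlation.

    Draws a bivariate Gaussian at the Pearson value whose normal-copula
    Spearman equals ``rho_s``, then maps each margin through a log-normal.
    """
    r = spearman_to_pearson(rho_s)
    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(1.0 - r * r) * e
    return np.exp(mu[0] + sigma * z1), np.exp(mu[1] + sigma * z2)


@dataclass
class ExpressionFixture:
    store: ExpressionStore
    rho_targets: dict[str, float]  # pair_id -> planted Spearman target
    levels: dict[str, str]  # pair_id -> planted co-expression level


def _level_of(rho: float) -> str:
    if rho > 0.9:
        return "high"
    if rho >= 0.8:
        return "medium"
    return "RLow"


def simulate_expression(
    spec: FixtureSpec,
    dpgset: DPGSet,
    tpm_path: str | None = None,
    meta_path: str | None = None,
) -> ExpressionFixture:
    """Correlated TPM matrix + sample metadata for a pair set.

    Each pair draws one Spearman target from ``spec.rho_levels`` and keeps it
    across tissues. Low-RIN decoy samples (RIN 5) and an undersized decoy
    tissue are planted to exercise the sample filters.
    """
    rng = spec.rng(_STREAM_EXPRESSION)
    rhos = np.array([r for r, _ in spec.rho_levels])
    weights = np.array([w for _, w in spec.rho_levels], dtype=float)
    weights /= weights.sum()
    rho_targets: dict[str, float] = {}
    levels: dict[str, str] = {}
    gene_mu: dict[str, float] = {}
    for pair in dpgset.pairs:
        rho = float(rng.choice(rhos, p=weights))
        rho_targets[pair.pair_id] = rho
        levels[pair.pair_id] = _level_of(rho)
        for g in (pair.minus_gene, pair.plus_gene):
            gene_mu[g.gene_id] = float(
                rng.normal(spec.log_tpm_mean, spec.log_tpm_gene_sd)
            )

    samples: list[str] = []
    tissue_of: dict[str, str] = {}
    rin_of: dict[str, float] = {}
    columns: dict[str, np.ndarray] = {}
    gene_ids = [gid for pair in dpgset.pairs for gid in (pair.minus_gene.gene_id, pair.plus_gene.gene_id)]
    data: dict[str, dict[str, np.ndarray]] = {}

    def add_samples(tissue: str, count: int, rin_lo: float, rin_hi: float) -> list[str]:
        ids = [f"S{len(samples) + k:05d}" for k in range(count)]
        for sid in ids:
            samples.append(sid)
            tissue_of[sid] = tissue
            rin_of[sid] = float(np.round(rng.uniform(rin_lo, rin_hi), 2))
        return ids

    matrix = {}
    tissue_samples: dict[str, list[str]] = {}
    for tissue in spec.tissues:
        tissue_samples[tissue] = add_samples(tissue, spec.n_per_tissue, 6.5, 9.8)
    low_rin_ids = add_samples(spec.tissues[0], spec.n_low_rin_samples, 4.5, 5.5)
    small_ids = add_samples("T_SMALL", spec.n_small_tissue_samples, 6.5, 9.8)

    values = np.zeros((len(gene_ids), len(samples)))
    row = {gid: i for i, gid in enumerate(gene_ids)}
    col = {sid: j for j, sid in enumerate(samples)}
    for pair in dpgset.pairs:
        gm, gp = pair.minus_gene.gene_id, pair.plus_gene.gene_id
        mu = (gene_mu[gm], gene_mu[gp])
        for tissue in spec.tissues:
            a, b = copula_pair_tpm(
                rho_targets[pair.pair_id],
                spec.n_per_tissue,
                rng,
                mu=mu,
                sigma=spec.log_tpm_sigma,
            )
            js = [col[s] for s in tissue_samples[tissue]]
            values[row[gm], js] = a
            values[row[gp], js] = b
        # decoy samples get uncorrelated noise
        for sid in low_rin_ids + small_ids:
            values[row[gm], col[sid]] = float(np.exp(rng.normal(mu[0], spec.log_tpm_sigma)))
            values[row[gp], col[sid]] = float(np.exp(rng.normal(mu[1], spec.log_tpm_sigma)))

    tpm = pd.DataFrame(np.round(values, 4), index=gene_ids, columns=samples)
    meta = pd.DataFrame(
        {
            "tissue": [tissue_of[s] for s in samples],
            "rin": [rin_of[s] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    if tpm_path:
        tpm.to_csv(tpm_path, sep="\t")
    if meta_path:
        meta.to_csv(meta_path, sep="\t")
    return ExpressionFixture(
        store=ExpressionStore(tpm=tpm, sample_meta=meta),
        rho_targets=rho_targets,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# signal tracks


def simulate_signal_track(
    spec: FixtureSpec,
    dpgset: DPGSet,
    levels: dict[str, str],
    bedgraph_path: str | None = None,
    pad: int = 600,
) -> SignalTrack:
    """Gaussian bump at each pair's inter-TSS midpoint, amplitude by level."""
    track = SignalTrack(label="synthetic")
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for pair in dpgset.pairs:
        lo, hi = pair.region
        L = hi - lo + 1
        mid = (lo + hi) / 2.0
        sigma = max(L / 8.0, 5.0)
        amp = spec.signal_amplitude.get(levels.get(pair.pair_id, "RLow"), 1.0)
        xs = np.arange(lo - pad, hi + pad + 1)
        vals = amp * np.exp(-((xs - mid) ** 2) / (2.0 * sigma**2))
        keep = vals >= 1e-4
        for x, v in zip(xs[keep], np.round(vals[keep], 6)):
            per_chrom.setdefault(pair.chrom, []).append((int(x), int(x), float(v)))
    for chrom, triples in per_chrom.items():
        triples.sort()
        starts, ends, values = zip(*triples)
        track.add_intervals(chrom, starts, ends, values)
    if bedgraph_path:
        with open(bedgraph_path, "w") as fh:
            for chrom in sorted(track._chroms):
                starts, ends, values = track._chroms[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{v}\n")
    return track


# ---------------------------------------------------------------------------
# indels


@dataclass
class IndelFixture:
    records: list[IndelRecord]
    passing: list[IndelRecord]
    failing: list[IndelRecord]
    per_pair_counts: dict[str, dict[str, int]]  # planted passing counts


def simulate_indel_vcf(
    spec: FixtureSpec,
    dpgset: DPGSet,
    vcf_path: str | None = None,
    af_min: float = 0.005,
    len_min: int = 2,
) -> IndelFixture:
    """Poisson indels per inter-TSS region with planted filter outcomes.

    Passing records satisfy AF >= ``af_min`` and length change >= ``len_min``;
    failing records violate exactly one of the two, half-and-half.
    """
    rng = spec.rng(_STREAM_INDELS)
    records: list[IndelRecord] = []
    passing: list[IndelRecord] = []
    failing: list[IndelRecord] = []
    per_pair: dict[str, dict[str, int]] = {}
    for pair in dpgset.pairs:
        lo, hi = pair.region
        cls = spacing_class_of(pair.inter_tss_distance)
        p_ins = spec.insertion_prob.get(cls, 0.5)
        counts = {"insertion": 0, "deletion": 0}
        n_pass = int(rng.poisson(spec.indel_rate))
        n_fail = int(rng.poisson(spec.indel_fail_rate))
        for k in range(n_pass + n_fail):
            is_pass = k < n_pass
            pos = int(rng.integers(lo, hi + 1))
            kind = "insertion" if rng.random() < p_ins else "deletion"
            if is_pass:
                dlen = len_min + int(rng.geometric(0.3)) - 1
                af = float(np.round(rng.uniform(af_min, 0.5), 5))
            elif rng.random() < 0.5:  # fails on AF
                dlen = len_min + int(rng.geometric(0.3)) - 1
                af = float(np.round(rng.uniform(af_min / 10, af_min * 0.9), 6))
            else:  # fails on length change
                dlen = len_min - 1
                af = float(np.round(rng.uniform(af_min, 0.5), 5))
            if kind == "insertion":
                ref, alt = "A", "A" + "T" * dlen
            else:
                ref, alt = "A" + "T" * dlen, "A"
            rec = IndelRecord(chrom=pair.chrom, pos=pos, ref=ref, alt=alt, af=af)
            records.append(rec)
            if is_pass:
                passing.append(rec)
                counts[kind] += 1
            else:
                failing.append(rec)
        per_pair[pair.pair_id] = counts
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    if vcf_path:
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
            for chrom in sorted({r.chrom for r in records}):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in records:
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tAF={r.af}\n"
                )
    return IndelFixture(
        records=records, passing=passing, failing=failing, per_pair_counts=per_pair
    )


# ---------------------------------------------------------------------------
# three-way alignments


@dataclass
class AlignmentFixture:
    alignment: ThreeWayAlignment
    events: list[EventBlock]


def simulate_threeway_alignment(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> AlignmentFixture:
    """Ancestral sequence with planted lineage gap blocks.

    ``focal_lost`` blocks gap only the focal row; ``sister_insertion`` blocks
    gap focal and outgroup; ``other`` blocks gap focal and sister. Events are
    inserted at distinct ancestral positions so each planted block is a
    maximal run with exact known span.
    """
    rng = rng if rng is not None else spec.rng(_STREAM_ALIGNMENT)
    n_anc = spec.aln_ancestral_len
    anc = rng.choice(_BASES, size=n_anc)
    n_events = spec.n_focal_lost + spec.n_sister_insertion + spec.n_other_events
    # insertion points strictly inside, all distinct
    points = np.sort(rng.choice(np.arange(1, n_anc), size=n_events, replace=False))
    labels = (
        ["focal_lost"] * spec.n_focal_lost
        + ["sister_insertion"] * spec.n_sister_insertion
        + ["other"] * spec.n_other_events
    )
    rng.shuffle(labels)
    lo, hi = spec.aln_event_len_range
    lengths = rng.integers(lo, hi + 1, size=n_events)

    focal: list[str] = []
    sister: list[str] = []
    outgroup: list[str] = []
    events: list[EventBlock] = []
    prev = 0
    col = 0
    for point, label, length in zip(points, labels, lengths):
        chunk = anc[prev:point]
        focal.extend(chunk)
        sister.extend(chunk)
        outgroup.extend(chunk)
        col += len(chunk)
        block = rng.choice(_BASES, size=int(length))
        events.append(EventBlock(start=col + 1, end=col + int(length), label=label))
        for b in block:
            focal.append("-")
            if label == "focal_lost":
                sister.append(b)
                outgroup.append(b)
            elif label == "sister_insertion":
                sister.append(b)
                outgroup.append("-")
            else:  # other: sister gapped too
                sister.append("-")
                outgroup.append(b)
        col += int(length)
        prev = point
    chunk = anc[prev:]
    focal.extend(chunk)
    sister.extend(chunk)
    outgroup.extend(chunk)
    aln = ThreeWayAlignment(
        focal="".join(focal), sister="".join(sister), outgroup="".join(outgroup)
    )
    return AlignmentFixture(alignment=aln, events=events)


def write_threeway_fasta(fixture: AlignmentFixture, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in (
            ("focal", fixture.alignment.focal),
            ("sister", fixture.alignment.sister),
            ("outgroup", fixture.alignment.outgroup),
        ):
            fh.write(f">{name}\n{seq}\n")
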