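"""Genome annotation parsing into validated gene models.

Divergent-pair calling operates on transcription start sites (TSSs), so the
central object here is a :class:`GeneModel` carrying a strand-aware TSS taken
from the gene's canonical transcript (the longest one, as is conventional when
collapsing multi-transcript loci to a single representative). All coordinates
are 1-based inclusive, matching GFF3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


@dataclass(frozen=True)
class GeneModel:
    """A single gene with its canonical-transcript TSS.

    Invariants: ``start <= end``; ``tss`` equals the canonical transcript's
    start on the plus strand and its end on the minus strand, so the TSS always
    lies inside ``[start, end]``.
    """

    gene_id: str
    symbol: str | None
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    tss: int
    canonical_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if not (self.start <= self.tss <= self.end):
            raise ValueError(f"{self.gene_id}: tss {self.tss} outside [{self.start}, {self.end}]")

    @property
    def transcript_span(self) -> tuple[int, int]:
        """Span of the canonical transcript implied by (tss, length, strand)."""
        if self.strand == "+":
            return self.tss, self.tss + self.canonical_length - 1
        return self.tss - self.canonical_length + 1, self.tss


@dataclass
class GeneCatalog:
    """Collection of gene models with a per-chromosome TSS-sorted index."""

    genes: list[GeneModel] = field(default_factory=list)
    assembly_name: str = ""
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (record, reason)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel | None:
        return self._by_id().get(gene_id)

    def _by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        """Genes grouped by chromosome, sorted by (tss, gene_id)."""
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for chrom in out:
            out[chrom].sort(key=lambda g: (g.tss, g.gene_id))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "start": g.start,
                    "end": g.end,
                    "biotype": g.biotype,
                    "tss": g.tss,
                    "canonical_length": g.canonical_length,
                }
                for g in self.genes
            ]
        )


def _attr_first(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def _prevalidate_gff3(text: str) -> tuple[str, list[tuple[str, str]]]:
    """Drop structurally broken feature lines before handing off to gffutils.

    Returns the cleaned text and a list of (line, reason) rejections. GFF3
    requires start <= end and a defined strand for stranded features; lines
    violating either are unusable for TSS work.
    """
    kept: list[str] = []
    rejected: list[tuple[str, str]] = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            kept.append(line)
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            rejected.append((line, "not 9 tab-separated columns"))
            continue
        ftype = parts[2]
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError:
            rejected.append((line, "non-integer coordinates"))
            continue
        if start > end:
            rejected.append((line, f"start {start} > end {end}"))
            continue
        if ftype in ("gene",) + _TRANSCRIPT_TYPES and parts[6] not in ("+", "-"):
            rejected.append((line, f"missing/invalid strand {parts[6]!r}"))
            continue
        kept.append(line)
    for line, reason in rejected:
        logger.warning("rejected GFF3 record (%s): %s", reason, line[:120])
    return "\n".join(kept) + "\n", rejected


def parse_gff3(path: str, assembly_name: str = "", tss_source: str = "transcript") -> GeneCatalog:
    """Parse a GFF3 file into a :class:`GeneCatalog`.

    One :class:`GeneModel` is produced per gene feature. The canonical
    transcript is the longest by span (ties broken by lexicographically
    smallest transcript ID); genes with no transcript children fall back to
    the gene feature's own span. ``tss_source`` selects whether the TSS is
    taken from the canonical transcript bounds (default) or the gene bounds.

    Records with start > end or an undefined strand are rejected with a
    logged reason and recorded in ``catalog.rejected``.
    """
    if tss_source not in ("transcript", "gene"):
        raise ValueError(f"tss_source must be 'transcript' or 'gene', got {tss_source!r}")
    with open(path) as fh:
        text = fh.read()
    cleaned, rejected = _prevalidate_gff3(text)
    db = gffutils.create_db(
        cleaned,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        gene_id = _attr_first(gf, "ID", "gene_id") or gf.id
        symbol = _attr_first(gf, "Name", "gene_name")
        biotype = _attr_first(gf, "biotype", "gene_biotype", "gene_type") or "unknown"
        transcripts = sorted(
            db.children(gf, featuretype=_TRANSCRIPT_TYPES, level=1),
            key=lambda t: (-(t.end - t.start + 1), _attr_first(t, "ID") or t.id),
        )
        if transcripts:
            canon = transcripts[0]
            c_start, c_end = canon.start, canon.end
        else:
            c_start, c_end = gf.start, gf.end
        if tss_source == "gene":
            c_start, c_end = gf.start, gf.end
        tss = c_start if gf.strand == "+" else c_end
        try:
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=symbol,
                    chrom=gf.seqid,
                    strand=gf.strand,
                    start=gf.start,
                    end=gf.end,
                    biotype=biotype,
                    tss=tss,
                    canonical_length=c_end - c_start + 1,
                )
            )
        except ValueError as exc:
            logger.warning("rejected gene %s: %s", gene_id, exc)
            rejected.append((gene_id, str(exc)))
    return GeneCatalog(genes=genes, assembly_name=assembly_name, rejected=rejected)


def filter_protein_coding(catalog: GeneCatalog) -> GeneCatalog:
    """Restrict a catalog to protein-coding genes.

    Counts of removed biotypes are logged; an empty result is signalled with
    an explicit warning rather than a silent empty catalog.
    """
    kept = [g for g in catalog.genes if g.biotype == "protein_coding"]
    removed: dict[str, int] = {}
    for g in catalog.genes:
        if g.biotype != "protein_coding":
            removed[g.biotype] = removed.get(g.biotype, 0) + 1
    if removed:
        logger.info("filter_protein_coding removed: %s", removed)
    if not kept:
        warnings.warn("no protein-coding genes left after filtering", stacklevel=2)
    return GeneCatalog(genes=kept, assembly_name=catalog.assembly_name)


def write_gff3(catalog: GeneCatalog, path: str) -> None:
    """Write a catalog back to GFF3 (gene + canonical mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(catalog.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            if g.symbol:
                attrs += f";Name={g.symbol}"
            fh.write(
                f"{g.chrom}\tdpgkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            t_start, t_end = g.transcript_span
            fh.write(
                f"{g.chrom}\tdpgkit\tmRNA\t{t_start}\t{t_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )


def write_gene_table(catalog: GeneCatalog, path: str) -> None:
    """TSV export of the gene table."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def subset(catalog: GeneCatalog, gene_ids) -> GeneCatalog:
    wanted = set(gene_ids)
    return GeneCatalog(
        genes=[g for g in catalog.genes if g.gene_id in wanted],
        assembly_name=catalog.assembly_name,
    )


def with_tss_from_gene_bounds(catalog: GeneCatalog) -> GeneCatalog:
    """Recompute TSSs from gene bounds instead of canonical transcripts."""
    genes = [
        replace(
            g,
            tss=g.start if g.strand == "+" else g.end,
            canonical_length=g.end - g.start + 1,
        )
        for g in catalog.genes
    ]
    return GeneCatalog(genes=genes, assembly_name=catalog.assembly_name)
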