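"""Lineage assignment of gap blocks in three-way intergenic alignments.

With an outgroup (macaque) polarising a focal (human) vs sister (chimpanzee)
comparison, maximal runs of alignment columns where the focal sequence is
gapped classify as:

* ``focal_lost`` — sister and outgroup both carry sequence (the ancestral
  state), so the focal lineage deleted it;
* ``sister_insertion`` — only the sister carries sequence, so it was gained
  on the sister lineage;
* ``other`` — any remaining gap pattern (e.g. sister also gapped).

Runs are maximal per joint gap pattern, so a label change splits a block.
``N`` counts as sequence, not gap.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

GAP = "-"
_ALPHABET = set("ACGTN-")
LABELS = ("focal_lost", "sister_insertion", "other")


@dataclass(frozen=True)
class ThreeWayAlignment:
    """Equal-length aligned focal / sister / outgroup sequences."""

    focal: str
    sister: str
    outgroup: str

    def __post_init__(self) -> None:
        if not (len(self.focal) == len(self.sister) == len(self.outgroup)):
            raise ValueError("aligned sequences must have equal length")
        for name in ("focal", "sister", "outgroup"):
            seq = getattr(self, name)
            extra = set(seq.upper()) - _ALPHABET
            if extra:
                raise ValueError(f"{name} contains invalid characters {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.focal)


@dataclass(frozen=True)
class EventBlock:
    """A maximal labelled gap block, columns 1-based inclusive."""

    start: int
    end: int
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _column_label(f: str, s: str, o: str) -> str | None:
    """Label of one column, or None when the focal base is present."""
    if f != GAP:
        return None
    if s != GAP and o != GAP:
        return "focal_lost"
    if s != GAP and o == GAP:
        return "sister_insertion"
    return "other"


def classify_gap_blocks(alignment: ThreeWayAlignment, min_len: int = 2) -> list[EventBlock]:
    """Classify maximal focal-gap runs into lineage events.

    A run is maximal over columns sharing one joint gap pattern; mixed
    patterns split the run so each block carries a single unambiguous label.
    Blocks shorter than ``min_len`` columns are dropped.
    """
    f, s, o = alignment.focal.upper(), alignment.sister.upper(), alignment.outgroup.upper()
    blocks: list[EventBlock] = []
    run_start: int | None = None
    run_label: str | None = None
    for i in range(len(f) + 1):
        label = _column_label(f[i], s[i], o[i]) if i < len(f) else None
        if label != run_label:
            if run_label is not None and i - run_start >= min_len:
                blocks.append(EventBlock(start=run_start + 1, end=i, label=run_label))
            run_start = i if label is not None else None
            run_label = label
    return blocks


def read_threeway_fasta(path: str, names: tuple[str, str, str] | None = None) -> ThreeWayAlignment:
    """Read a 3-record aligned FASTA.

    Records are taken in file order as (focal, sister, outgroup) unless
    ``names`` gives the three record IDs explicitly.
    """
    records = {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
    if len(records) != 3:
        raise ValueError(f"expected exactly 3 aligned records, found {len(records)}")
    if names is None:
        focal, sister, outgroup = records.values()
    else:
        try:
            focal, sister, outgroup = (records[n] for n in names)
        except KeyError as exc:
            raise ValueError(f"record {exc} not found in {sorted(records)}") from exc
    return ThreeWayAlignment(focal=focal, sister=sister, outgroup=outgroup)


def events_to_frame(blocks: list[EventBlock]):
    import pandas as pd

    return pd.DataFrame(
        [{"start": b.start, "end": b.end, "length": b.length, "label": b.label} for b in blocks]
    )
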