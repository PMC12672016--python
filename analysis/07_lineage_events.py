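"""Lineage assignment of gap blocks in three-way intergenic alignments.

With an outgroup polarising focal-vs-sister differences, classifies maximal
focal-gap runs as focal-lineage deletions (sequence kept by sister and
outgroup) or sister-lineage insertions (sequence only in the sister), and
verifies exact recovery of the planted events over 20 alignments.

Writes results/alignment_events.tsv.
"""

import pandas as pd
from common import SEED, outpath

from dpgkit import simulate as sim
from dpgkit.alignment import classify_gap_blocks, events_to_frame


def main() -> None:
    frames = []
    exact = 0
    for i in range(20):
        fx = sim.simulate_threeway_alignment(sim.FixtureSpec(seed=SEED + i))
        blocks = classify_gap_blocks(fx.alignment, min_len=2)
        exact += blocks == sorted(fx.events, key=lambda b: b.start)
        df = events_to_frame(blocks)
        df.insert(0, "alignment", i)
        frames.append(df)
    events = pd.concat(frames, ignore_index=True)
    events.to_csv(outpath("alignment_events.tsv"), sep="\t", index=False)

    print(f"alignments with exact planted-span recovery: {exact}/20")
    print(events.groupby("label")["length"].agg(n="size", total_bp="sum", mean_bp="mean")
          .round(2).to_string())


if __name__ == "__main__":
    main()
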