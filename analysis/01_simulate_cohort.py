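"""Generate the synthetic study cohort and write every input file.

Outputs (results/fixture/): GFF3 annotation with planted divergent pairs,
per-species ortholog tables + target annotations, TPM matrix + sample
metadata, bedGraph signal track, indel VCF, three-way alignment FASTA, and
JSON truth manifests for each.
"""

import json
import os

from common import N_DPGS, SEED, cohort, outpath

from dpgkit import simulate as sim
from dpgkit.annotation import write_gff3

SPECIES = [f"sp{k}" for k in range(6)]


def main() -> None:
    spec, catalog, coding, dpgset, truth = cohort()
    fixture = outpath("fixture")
    os.makedirs(fixture, exist_ok=True)

    sim.write_annotation_gff3(catalog, os.path.join(fixture, "annotation.gff3"), rng=spec.rng(101))
    with open(os.path.join(fixture, "annotation_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)

    species_fx = sim.simulate_orthologs(spec, dpgset, SPECIES)
    for sp, fx in species_fx.items():
        fx.ortholog_map.to_tsv(os.path.join(fixture, f"orthologs_{sp}.tsv"))
        write_gff3(fx.catalog, os.path.join(fixture, f"annotation_{sp}.gff3"))
    with open(os.path.join(fixture, "conservation_truth.json"), "w") as fh:
        json.dump({sp: fx.codes for sp, fx in species_fx.items()}, fh, indent=2)

    expr = sim.simulate_expression(
        spec, dpgset, os.path.join(fixture, "tpm.tsv"), os.path.join(fixture, "samples.tsv")
    )
    with open(os.path.join(fixture, "expression_truth.json"), "w") as fh:
        json.dump({"rho_targets": expr.rho_targets, "levels": expr.levels}, fh, indent=2)

    sim.simulate_signal_track(spec, dpgset, expr.levels, os.path.join(fixture, "signal.bedgraph"))
    sim.simulate_indel_vcf(spec, dpgset, os.path.join(fixture, "indels.vcf"))
    for i in range(5):
        afx = sim.simulate_threeway_alignment(sim.FixtureSpec(seed=SEED + i))
        sim.write_threeway_fasta(afx, os.path.join(fixture, f"alignment_{i}.fasta"))
        with open(os.path.join(fixture, f"alignment_{i}_truth.json"), "w") as fh:
            json.dump([vars(b) for b in afx.events], fh, indent=2)

    print(f"cohort: {len(catalog)} genes ({len(coding)} protein-coding), "
          f"{N_DPGS} planted pairs, {len(SPECIES)} comparison species")
    print(f"fixture bundle written under {fixture}")


if __name__ == "__main__":
    main()
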