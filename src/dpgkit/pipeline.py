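"""End-to-end orchestration over a :class:`~dpgkit.config.RunConfig`.

Stages run in dependency order; stages whose inputs are absent are skipped.
Every output table is written with a leading comment line carrying the
config hash, so tables can always be traced back to their parameters.
Stages never mutate one another's outputs, and each stage function can be
re-run on its own.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import alignment, annotation, coexpression, conservation, pairs, signals, variation
from .config import RunConfig

logger = logging.getLogger(__name__)


def _write(df: pd.DataFrame, path: str, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index)


def stage_identify(config: RunConfig) -> pairs.DPGSet:
    catalog = annotation.parse_gff3(config.annotation)
    coding = annotation.filter_protein_coding(catalog)
    logger.info("identify: %d genes, %d protein-coding", len(catalog), len(coding))
    dpgset = pairs.identify_dpgs(coding, max_dist=config.max_dist)
    dpgset = pairs.classify_all_spacing(dpgset, t_distant=config.t_distant)
    logger.info("identify: %d pairs, %d ambiguity entries", len(dpgset), len(dpgset.ambiguity_log))
    return dpgset


def stage_conservation(config: RunConfig, dpgset: pairs.DPGSet):
    species = sorted(config.species)
    maps, catalogs = {}, {}
    for sp in species:
        inputs = config.species[sp]
        maps[sp] = conservation.OrthologMap.from_tsv(inputs["orthologs"], ("focal", sp))
        catalogs[sp] = annotation.filter_protein_coding(
            annotation.parse_gff3(inputs["annotation"])
        )
    matrix = conservation.build_conservation_matrix(dpgset, species, maps, catalogs)
    return matrix


def stage_coexpression(config: RunConfig, dpgset: pairs.DPGSet):
    store = coexpression.ExpressionStore.from_tsv(config.expression_tpm, config.expression_meta)
    store = coexpression.filter_samples(store, rin_min=config.rin_min, min_tissue_n=config.min_tissue_n)
    table = coexpression.score_pairs(store, dpgset, rho_min=config.rho_min, p_max=config.p_max)
    medians = coexpression.tissue_median(store)
    summary_rows = []
    for pair in dpgset.pairs:
        recs = coexpression.records_from_frame(table, pair.pair_id)
        rhos = [r.rho for r in recs]
        level = coexpression.classify_level(rhos)
        general = coexpression.flag_generally_coexpressed(
            rhos, rho_min=config.general_rho, frac_min=config.general_frac
        )
        fc = None
        if any(r.rho is not None for r in recs):
            fc = coexpression.expression_fold_change(pair, recs, medians)
        summary_rows.append(
            {
                "pair_id": pair.pair_id,
                "level": level,
                "generally_coexpressed": general,
                "n_coexpressed_tissues": int(sum(r.coexpressed for r in recs)),
                "fold_change": np.nan if fc is None else fc,
            }
        )
    return store, table, pd.DataFrame(summary_rows)


def stage_profiles(config: RunConfig, dpgset: pairs.DPGSet, levels: dict[str, str]):
    track = signals.SignalTrack.from_bedgraph(config.signal_bedgraph)
    profiles = {
        p.pair_id: signals.extract_scaled_profile(
            track, p, bins=config.profile_bins, flank=config.profile_flank
        )
        for p in dpgset.pairs
    }
    metas = signals.group_average_profiles(profiles, levels)
    rows = {level: m.values for level, m in metas.items()}
    df = pd.DataFrame(rows)
    df.index.name = "position"
    return track, metas, df


def stage_indels(config: RunConfig, dpgset: pairs.DPGSet):
    records = variation.read_indels(config.indel_vcf)
    kept = variation.filter_indels(records, af_min=config.af_min, len_min=config.len_min)
    logger.info("indels: %d read, %d pass filters", len(records), len(kept))
    counts = variation.assign_indels(kept, dpgset)
    table = variation.bin_by_spacing(counts, dpgset)
    return kept, counts, table


def stage_events(config: RunConfig):
    frames = []
    for path in config.alignments:
        aln = alignment.read_threeway_fasta(path)
        blocks = alignment.classify_gap_blocks(aln, min_len=config.len_min)
        df = alignment.events_to_frame(blocks)
        df.insert(0, "alignment", os.path.basename(path))
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["alignment", "start", "end", "length", "label"])
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage whose inputs are configured; write tables to out_dir."""
    if config.annotation is None:
        raise ValueError("stage identify: no annotation input configured")
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_json(os.path.join(config.out_dir, "config.json"))
    bundle: dict = {}

    dpgset = stage_identify(config)
    bundle["pairs"] = dpgset
    _write(dpgset.to_frame(), os.path.join(config.out_dir, "pairs.tsv"), config)

    if config.species:
        matrix = stage_conservation(config, dpgset)
        bundle["conservation"] = matrix
        with open(os.path.join(config.out_dir, "conservation_matrix.tsv"), "w") as fh:
            fh.write(f"# config_hash={config.config_hash()}\n")
            matrix.data.to_csv(fh, sep="\t")

    levels: dict[str, str] = {}
    if config.expression_tpm and config.expression_meta:
        store, table, summary = stage_coexpression(config, dpgset)
        bundle["coexpression"] = table
        bundle["coexpression_summary"] = summary
        levels = dict(zip(summary["pair_id"], summary["level"]))
        _write(table, os.path.join(config.out_dir, "coexpression.tsv"), config)
        _write(summary, os.path.join(config.out_dir, "coexpression_summary.tsv"), config)

    if config.signal_bedgraph:
        _, metas, df = stage_profiles(config, dpgset, levels or {p.pair_id: "RLow" for p in dpgset.pairs})
        bundle["metaprofiles"] = metas
        _write(df, os.path.join(config.out_dir, "metaprofiles.tsv"), config, index=True)

    if config.indel_vcf:
        _, counts, table = stage_indels(config, dpgset)
        bundle["indel_counts"] = counts
        bundle["spacing_bins"] = table
        _write(table, os.path.join(config.out_dir, "spacing_bins.tsv"), config)

    if config.alignments:
        events = stage_events(config)
        bundle["events"] = events
        _write(events, os.path.join(config.out_dir, "alignment_events.tsv"), config)

    return bundle
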