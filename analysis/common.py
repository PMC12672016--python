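"""Shared cohort setup for the analysis drivers.

All drivers work on the same synthetic cohort (seed 20260926, 500 planted
pairs) so their tables are mutually consistent; each driver regenerates the
pieces it needs, which takes seconds.
"""

import os

from dpgkit import simulate as sim
from dpgkit.annotation import filter_protein_coding
from dpgkit.pairs import classify_all_spacing, identify_dpgs

SEED = 20_260_926
N_DPGS = 500
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def cohort():
    spec = sim.FixtureSpec(seed=SEED, n_dpgs=N_DPGS)
    catalog, truth = sim.build_annotation(spec)
    coding = filter_protein_coding(catalog)
    dpgset = classify_all_spacing(identify_dpgs(coding))
    return spec, catalog, coding, dpgset, truth


def outpath(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
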