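"""Shared configuration of the synthetic end-to-end study.

One control cohort and one mutant cohort whose effect directions mirror the
germline-mutant phenotype the pipeline is designed to detect: shorter centra,
higher vertebral TMD, less soft tissue and a smaller body.  Phantoms are
generated at 70% of the default body size to keep runtimes desk-scale; all
fractions and effect sizes are size-invariant.
"""

from pathlib import Path

from fishct.phantom import CohortSpec, PhantomSpec, apply_effects

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

SEED = 0
N_PER_GROUP = 4
NOISE_SD = 8.0  # low-noise acquisition model

# histogram slab of ~half a vertebral pitch around the mid slice, so the
# threshold sample always contains bone even if the exact midpoint falls in
# an intervertebral gap (the operator's "representative slice")
SLICE_HALFWIDTH = 11

MUTANT_EFFECTS = {
    "centrum_length": 0.90,   # -10% centrum length
    "tmd": 1.08,              # +8% tissue mineral density
    "lean_volume": 0.90,      # -10% soft-tissue volume
    "standard_length": 0.95,  # -5% body size
}

#: screen inputs: per-gene effect profiles and TIDE %WT (efficiency = 1-%WT)
SCREEN_GENES = {
    "geneA_strong": ({"centrum_length": 0.88, "lean_volume": 0.90,
                      "standard_length": 0.95}, 39.5),
    "geneB_weak": ({"centrum_length": 0.97}, 48.2),
    "geneC_null": ({}, 17.6),
}


def control_spec(seed: int = SEED) -> PhantomSpec:
    base = PhantomSpec(n_vertebrae=20, noise_sd=NOISE_SD, seed=seed)
    return apply_effects(base, {"standard_length": 0.7}).replace(seed=seed)


def cohort_spec(seed: int = SEED) -> CohortSpec:
    return CohortSpec(
        control=control_spec(seed),
        groups={"control": {}, "mutant": MUTANT_EFFECTS},
        n_per_group=N_PER_GROUP,
        scale_sd=0.03,
        seed=seed,
    )
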