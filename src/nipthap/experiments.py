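"""Replicated simulation experiments: accuracy over fetal fraction x depth.

Reproduces, in silico, the artificial-mixture + depth-downsampling protocol
used to probe the method's detection limits: for each (fetal fraction,
mean depth) condition a fresh trio family is simulated, plasma counts are
drawn, the trio is phased, the fetal fraction re-estimated from
opposite-homozygote sites, both parental chains are decoded by the HMM, and
the calls are scored against the simulated truth at the gene locus.

The replicate pipeline decodes the simulated counts directly (zero-depth
sites skipped): the depth-40 and allele-ratio rules of the filters module
belong to de novo variant detection on deeply sequenced plasma, and a
dataset downsampled to 30x could not pass them at panel sites whose
genotypes are already known from parental gDNA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from nipthap.fraction import estimate_fetal_fraction, select_fraction_sites
from nipthap.hmm import GeneticMap, infer_fetal_haplotypes
from nipthap.phasing import ProbandCarries, phase_trio
from nipthap.simulator import SimConfig, simulate_family, simulate_plasma


@dataclass
class ReplicateOutcome:
    """Scored result of one simulated pregnancy."""

    pat_correct: bool
    mat_correct: bool
    pat_final_log_odds: float
    mat_final_log_odds: float
    pat_evidence_log_odds: float     # final cumulative emission-only evidence
    mat_evidence_log_odds: float
    f_true: float
    f_est: float
    n_pat_sites: int
    n_mat_sites: int


def run_replicate(
    f: float,
    mean_depth: float,
    seed,
    config: SimConfig | None = None,
    use_estimated_f: bool = True,
) -> ReplicateOutcome:
    """Simulate one family + plasma sample and run the full inference chain.

    ``seed`` may be an int or a sequence of ints (entropy-spawned key).
    The fetal fraction fed to the HMM is the ratio-estimator value from the
    opposite-homozygote sites (error-inverted with the known assay error
    rate) unless ``use_estimated_f`` is False, in which case the true
    simulated fraction is used.
    """
    base = config if config is not None else SimConfig()
    cfg = replace(base, f=f, mean_depth=mean_depth)
    rng = np.random.default_rng(seed)
    family = simulate_family(cfg, rng)
    plasma = simulate_plasma(family, rng, include_strand=False)

    panel = phase_trio(family.trio_sites(), ProbandCarries(
        paternal=cfg.proband_carries_paternal, maternal=cfg.proband_carries_maternal))
    plasma_by_pos = {s.pos: s for s in plasma}

    ff_sites = select_fraction_sites(panel, plasma_by_pos)
    f_est = estimate_fetal_fraction(ff_sites, error_rate=cfg.error_rate).f
    f_used = f_est if use_estimated_f else cfg.f

    inference = infer_fetal_haplotypes(
        panel, plasma, f=f_used,
        gene_interval=cfg.gene_interval,
        genetic_map=GeneticMap.constant(cfg.recomb_rate_cm_per_mb),
        error_rate=cfg.error_rate,
        f_floor=0.0,  # score the maternal chain even in the unreliable regime
    )
    pat_call = inference.paternal.transmitted_hap
    mat_call = inference.maternal.transmitted_hap
    return ReplicateOutcome(
        pat_correct=(pat_call == family.truth_pat_hap),
        mat_correct=(mat_call == family.truth_mat_hap),
        pat_final_log_odds=float(inference.paternal.log_odds[-1]),
        mat_final_log_odds=float(inference.maternal.log_odds[-1]),
        pat_evidence_log_odds=float(inference.paternal.emission_log_odds[-1]),
        mat_evidence_log_odds=float(inference.maternal.emission_log_odds[-1]),
        f_true=cfg.f,
        f_est=f_est,
        n_pat_sites=len(inference.paternal.positions),
        n_mat_sites=len(inference.maternal.positions),
    )


def accuracy_cell(
    f: float,
    mean_depth: float,
    n_replicates: int,
    seed: int,
    config: SimConfig | None = None,
) -> list[ReplicateOutcome]:
    """Run ``n_replicates`` independent replicates of one grid cell.

    Per-replicate seeds are spawned from ``(seed, f-in-percent-x100,
    depth, replicate)`` so cells are independent and reproducible.
    """
    return [
        run_replicate(f, mean_depth, seed=[seed, int(round(f * 10000)), int(mean_depth), r], config=config)
        for r in range(n_replicates)
    ]


def accuracy_grid(
    fractions: list[float],
    depths: list[float],
    n_replicates: int,
    seed: int,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Accuracy surface over a fetal-fraction x depth grid.

    Returns one row per cell with paternal/maternal per-replicate accuracy
    (fraction of replicates whose call at the gene locus matches the
    simulated truth) and mean absolute final log-odds per chain.
    """
    rows = []
    for f in fractions:
        for d in depths:
            outcomes = accuracy_cell(f, d, n_replicates, seed, config=config)
            rows.append({
                "f": f,
                "mean_depth": d,
                "n_replicates": n_replicates,
                "paternal_accuracy": float(np.mean([o.pat_correct for o in outcomes])),
                "maternal_accuracy": float(np.mean([o.mat_correct for o in outcomes])),
                "paternal_mean_abs_log_odds": float(np.mean([abs(o.pat_evidence_log_odds) for o in outcomes])),
                "maternal_mean_abs_log_odds": float(np.mean([abs(o.mat_evidence_log_odds) for o in outcomes])),
                "mean_f_est": float(np.mean([o.f_est for o in outcomes])),
            })
    return pd.DataFrame(rows)
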