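"""Shared fixtures: one small mapping population reused across the suite.

The session population mirrors the analysis's desk-scale study conditions:
two 5-Mb chromosome arms on a 2 cM/Mb map (a 1000-point 10-kb grid), 300
RILs per parental population (two subpopulations each), soft HMM emulation
at 0.95 certainty, and 300 F1 crosses.  Tests that need phenotypes draw
them on top of these genotypes with their own seeds.
"""

import numpy as np
import pytest

from mpqtl import (
    GeneticMap,
    HaplotypeProbSet,
    QTLEffectSpec,
    calibrate_qtl_effects,
    make_crosses,
    simulate_founder_pair,
    simulate_phenotypes,
    simulate_ril_set,
)
from mpqtl.pheno import cross_means

MAF = {"dist": "uniform", "low": 0.05, "high": 0.5}

VAR_GENETIC = 100.0  # between-cross genetic variance, offspring-count units
VAR_ENV = 160.0  # replicate (vial) variance; with r=3 gives H2 ~ 0.38 / 0.65


@pytest.fixture(scope="session")
def gmap():
    return GeneticMap.uniform({"2L": 5_000_000, "2R": 5_000_000}, cm_per_mb=2.0)


@pytest.fixture(scope="session")
def pop(gmap):
    pa, pb = simulate_founder_pair(600, gmap, MAF, {"n_te": 6}, seed=101)
    rils_a = simulate_ril_set(pa, gmap, 300, breakpoint_rate=50.0, het_fraction=0.01, seed=102)
    rils_b = simulate_ril_set(pb, gmap, 300, breakpoint_rate=50.0, het_fraction=0.01, seed=103)
    probsA = HaplotypeProbSet.from_mosaics(rils_a, gmap, certainty=0.95, seed=104)
    probsB = HaplotypeProbSet.from_mosaics(rils_b, gmap, certainty=0.95, seed=105)
    design = make_crosses(rils_a, rils_b)
    return {
        "gmap": gmap, "pa": pa, "pb": pb, "rils_a": rils_a, "rils_b": rils_b,
        "probsA": probsA, "probsB": probsB, "design": design,
    }


def qtl_phenotypes(pop, qtl_specs, seed, subpop_effect=5.0, n_datasets=1):
    """Cross-mean phenotype vector(s) with planted QTL on the shared genotypes.

    ``qtl_specs`` is a list of (arm, pos_bp, fraction-of-genetic-variance);
    returns (y, qtls) where y is (n,) or (n, n_datasets) of cross means with
    fresh polygenic and replicate noise per dataset.
    """
    design, probsA, probsB = pop["design"], pop["probsA"], pop["probsB"]
    rng = np.random.default_rng(seed)
    qtls = [
        QTLEffectSpec(arm, bp, rng.normal(size=8), rng.normal(size=8), target_fraction=f)
        for arm, bp, f in qtl_specs
    ]
    qtls, var_poly = calibrate_qtl_effects(qtls, design, probsA, probsB, VAR_GENETIC)
    cols = []
    for d in range(n_datasets):
        phen = simulate_phenotypes(
            design, probsA, probsB, qtls, mu=60.0, subpop_effect=subpop_effect,
            var_poly=var_poly, var_env=VAR_ENV, n_reps=3,
            seed=int(rng.integers(2**31)),
        )
        m = cross_means(phen.table).set_index("cross_id")
        cols.append(m.loc[design["cross_id"], "mean"].to_numpy())
    y = cols[0] if n_datasets == 1 else np.column_stack(cols)
    return y, qtls
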