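"""Self-validation experiments on synthetic cohorts.

These routines exercise the full pipeline under the generative model the
synthetic-data module defines — calibrate on intergenic cohorts, score
planted selection signals, measure error rates — and return summary
statistics.  They are used by the acceptance machinery and are convenient
for sanity-checking any change to the calibration or statistics code.

All randomness is keyed off a single seed; problem sizes default to the
study conditions used throughout the test-suite (20,000 variants per
scored class, calibration cohorts in the 10^5 range, 100-200 replicates).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ContextCalibrator, _codes
from .contexts import assign_context_codes
from .rep_sites import call_rep_sites, positional_enrichment_test
from .simulate import (
    SimConfig,
    candidate_sites,
    gen_psam_and_peaks,
    gen_reference,
    gen_variant_cohort,
    singleton_probability,
)
from .stats import nchg_sf, null_odds_ratio


def imaps_recovery(
    seed: int,
    deltas: Sequence[float] = (0.0, 0.02, 0.05),
    n_per_class: int = 20_000,
    n_replicates: int = 200,
    n_calibration: int = 150_000,
) -> dict:
    """Parameter recovery of planted singleton excess.

    One calibration table is fit on an intergenic cohort and shared by all
    replicates; per delta, ``n_replicates`` cohorts of ``n_per_class``
    variants are drawn with singleton probability baseline+delta and
    scored.  Because the calibration table is shared, the standard error
    of the mean estimate includes the propagated calibration variance
    (sum over resolved contexts of w_c^2 ps_c (1-ps_c) / N_c) on top of
    the across-replicate component.
    """
    ref = gen_reference(SimConfig(seed=seed))
    calib = gen_variant_cohort(ref, ref.intergenic_regions, n_calibration, seed=seed + 1)
    cal = ContextCalibrator().fit(calib)

    rng = np.random.default_rng((seed, 0x4EC0))
    sites = candidate_sites(ref, ref.intergenic_regions, rng, n_per_class)
    known = set(cal.parent_table_.index)
    parent_codes = _codes(sites, "di")
    sites = sites.loc[[c in known for c in parent_codes]].reset_index(drop=True)
    n = len(sites)

    detail = cal.predict_detail(sites)
    expected_total = float(detail["expected_ps"].sum())
    counts = cal.table_counts()
    grp = detail.groupby("code").size()
    tab = counts.loc[grp.index]
    w = grp.to_numpy() / n
    var_calib = float(
        np.sum(w**2 * tab["ps"].to_numpy() * (1 - tab["ps"].to_numpy()) / tab["n"].to_numpy())
    )

    base = singleton_probability(ref, sites)
    out = {"n_per_class": n, "n_replicates": n_replicates, "deltas": {}}
    for delta in deltas:
        p = base + delta
        draws = rng.random((n_replicates, n)) < p[None, :]
        est = (draws.sum(axis=1) - expected_total) / n
        mean_est = float(est.mean())
        se = math.sqrt(var_calib + float(est.var(ddof=1)) / n_replicates)
        out["deltas"][delta] = {"mean_estimate": mean_est, "se": se}
    return out


def compare_groups_type_i_error(
    seed: int,
    n_sims: int = 2000,
    n_per_group: int = 2000,
    p_a: float = 0.45,
    p_b: float = 0.55,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the null-odds-ratio exact test when the null holds.

    Both groups draw singletons at their own true rates; the test is run
    against the odds ratio implied by the true expected counts, so the
    null hypothesis is exactly true and the rejection rate should not
    exceed alpha (exact tests are conservative).
    """
    rng = np.random.default_rng((seed, 0x7E57))
    psi0 = null_odds_ratio(p_a * n_per_group, n_per_group, p_b * n_per_group, n_per_group)
    rejections = 0
    for _ in range(n_sims):
        a = int(rng.binomial(n_per_group, p_a))
        b = int(rng.binomial(n_per_group, p_b))
        t = a + b
        if t == 0 or t == 2 * n_per_group:
            continue
        p = nchg_sf(a, n_per_group, n_per_group, t, psi0)
        if p <= alpha:
            rejections += 1
    rate = rejections / n_sims
    return {"rate": rate, "se": math.sqrt(alpha * (1 - alpha) / n_sims), "alpha": alpha}


def calibration_fdr_null(
    seed: int,
    n_replicates: int = 100,
    n_variants: int = 5_000,
    fdr: float = 0.2,
) -> dict:
    """False-discovery behaviour with no planted extended-context deviations.

    Every accepted extended context is then a false discovery, so the
    per-replicate false-discovery proportion is 1 when anything is
    accepted and 0 otherwise; its mean is bounded by the BH level.
    """
    ref = gen_reference(SimConfig(seed=seed))
    fdp = []
    n_accepted = []
    for r in range(n_replicates):
        cohort = gen_variant_cohort(ref, ref.intergenic_regions, n_variants, seed=seed + 100 + r)
        cal = ContextCalibrator(fdr=fdr).fit(cohort)
        k = len(cal.extended_table_)
        n_accepted.append(k)
        fdp.append(1.0 if k > 0 else 0.0)
    mean_fdp = float(np.mean(fdp))
    return {
        "mean_fdp": mean_fdp,
        "se": math.sqrt(mean_fdp * (1 - mean_fdp) / n_replicates) if 0 < mean_fdp < 1
        else math.sqrt(0.25 / n_replicates),
        "total_accepted": int(np.sum(n_accepted)),
        "n_replicates": n_replicates,
    }


PLANTED_WINDOW = "AGCTACATTGA"
PLANTED_DERIVED = "G"


def calibration_planted_power(
    seed: int,
    n_replicates: int = 100,
    n_planted_variants: int = 5_000,
    n_background_variants: int = 10_000,
    deviation: float = 0.15,
    fdr: float = 0.2,
) -> dict:
    """Acceptance rate of a hexanucleotide context with a planted deviation.

    The reference carries many copies of one 11-mer (a single hexa
    context) plus background windows sharing its parent context; the
    planted context's singleton probability deviates from the parent
    baseline by ``deviation``.
    """
    code = assign_context_codes(
        [PLANTED_WINDOW], [PLANTED_DERIVED], [np.nan], [False], [False], "hexa"
    )[0]
    cfg = SimConfig(
        seed=seed,
        planted_window=PLANTED_WINDOW,
        planted_derived=PLANTED_DERIVED,
        n_planted=60,
        n_planted_background=2_000,
        extended_deviations={code: deviation},
    )
    ref = gen_reference(cfg)
    hits = 0
    for r in range(n_replicates):
        planted = gen_variant_cohort(
            ref, [], n_planted_variants, seed=seed + 200 + r,
            positions=ref.planted_positions, derived=PLANTED_DERIVED,
        )
        background = gen_variant_cohort(
            ref, [], n_background_variants, seed=seed + 700 + r,
            positions=ref.background_positions, derived=PLANTED_DERIVED,
        )
        cal = ContextCalibrator(fdr=fdr).fit(
            pd.concat([planted, background], ignore_index=True)
        )
        if code in set(cal.extended_table_["code"]):
            hits += 1
    return {"acceptance_rate": hits / n_replicates, "n_replicates": n_replicates}


def rep_pipeline_validation(
    seed: int,
    n_peaks: int = 40,
    n_sims: int = 10_000,
    n_null_fixtures: int = 20,
) -> dict:
    """ReP-site recall on planted motifs plus positional-test behaviour."""
    ref = gen_reference(SimConfig(seed=seed))
    psam, peaks, truth, genome = gen_psam_and_peaks(
        ref, "RBP1", 11, n_peaks, seed=seed + 1, planted_offset=20
    )
    sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
    got = {(s.chrom, s.start, s.end) for s in sites}
    want = {(r.chrom, r.start, r.end) for r in truth.itertuples()}
    recall = len(got & want) / len(want)
    p_planted = positional_enrichment_test(
        [s.offset for s in sites], n_sims=n_sims, seed=seed + 2
    )
    null_ps = []
    for i in range(n_null_fixtures):
        ps_i, pk, _, gn = gen_psam_and_peaks(
            ref, "RBP1", 11, n_peaks, seed=seed + 10 + i, planted_offset=None
        )
        s = call_rep_sites(pk, {"RBP1": ps_i}, gn)
        null_ps.append(
            positional_enrichment_test([x.offset for x in s], n_sims=n_sims, seed=seed + 3)
        )
    return {
        "recall": recall,
        "p_planted": p_planted,
        "null_p_values": null_ps,
        "null_frac_below_0.05": float(np.mean(np.asarray(null_ps) <= 0.05)),
    }
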