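"""Pharmacological classification of VTA units and group rate comparison.

Units are labeled from their home-cage baseline rate and their response to
the D2 agonist apomorphine: putative DA neurons fire below 10 Hz at baseline
and are suppressed by at least 50% after the drug; units above 10 Hz are
putative GABA neurons; low-rate units without the suppression are left
unclassified.  Group firing rates are compared with a two-sided permutation
test on the difference of means.
"""

from __future__ import annotations

import numpy as np

from .core import InvalidParameterError, PharmacologySummary

DA_RATE_CEILING_HZ = 10.0
DA_SUPPRESSION = 0.5  # post <= 0.5 * baseline counts as suppressed


class UnclassifiableError(ValueError):
    """Baseline below 10 Hz but no post-drug rate available."""


def classify_unit(p: PharmacologySummary) -> str:
    """'DA', 'GABA', or 'unclassified' from the baseline/post-drug rates.

    Baseline exactly 10 Hz is assigned GABA (the DA rule requires < 10 Hz);
    exactly 50% suppression counts as DA.
    """
    if p.baseline_rate >= DA_RATE_CEILING_HZ:
        return "GABA"
    if p.post_rate is None:
        raise UnclassifiableError(
            f"unit {p.unit_id}: baseline < 10 Hz but no post-drug rate"
        )
    if p.post_rate <= DA_SUPPRESSION * p.baseline_rate:
        return "DA"
    return "unclassified"


def classify_population(summaries, units=None) -> dict:
    """Classify every unit; optionally write labels back onto SpikeTrains."""
    labels = {}
    for p in summaries:
        labels[p.unit_id] = classify_unit(p)
    if units is not None:
        for u in units:
            if u.unit_id in labels:
                u.cell_class = labels[u.unit_id]
    return labels


def permutation_rate_test(
    rates_a, rates_b, n_perm: int = 10000, seed: int | None = None
) -> float:
    """Two-sided permutation p-value for the difference of group mean rates.

    Uses random relabelings of the pooled rates with the add-one correction
    p = (1 + #extreme) / (n_perm + 1).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("both groups need >= 2 units")
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = a.size
    extreme = 0
    # vectorized in chunks to bound memory
    chunk = max(1, int(2e6 // max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(pooled, (m, pooled.size)), axis=1)
        diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        extreme += int(np.sum(np.abs(diffs) >= obs - 1e-12))
        done += m
    return (1 + extreme) / (n_perm + 1)
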