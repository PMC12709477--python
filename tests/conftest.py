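import numpy as np
import pytest

from mbsub.classifier import TrainConfig, train_model
from mbsub.ssgsea import SsgseaParams, ssgsea_matrix
from mbsub.synthetic import CohortSpec, SimulatedCohort, simulate_cohort


# --- independent oracles (deliberately naive; never share code with mbsub) ---

def ssgsea_oracle(values: dict, members: set, alpha: float) -> float:
    """Direct-summation ssGSEA reference: explicit sort and running sums."""
    genes = sorted(values, key=lambda g: (-values[g], g))
    n = len(genes)
    weight_sum = sum(
        (n - i) ** alpha for i, g in enumerate(genes) if g in members
    )
    n_out = sum(1 for g in genes if g not in members)
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for i, g in enumerate(genes):
        if g in members:
            cum_in += (n - i) ** alpha
        else:
            cum_out += 1
        score += cum_in / weight_sum - cum_out / n_out
    return score


def hypergeom_tail_oracle(k: int, m: int, n_success: int, n_draw: int) -> float:
    """P(X >= k) by exact summation of binomial coefficients."""
    from math import comb

    total = comb(m, n_draw)
    upper = min(n_draw, n_success)
    return sum(
        comb(n_success, j) * comb(m - n_success, n_draw - j) for j in range(k, upper + 1)
    ) / total


def union_oracle(intervals):
    """Per-base boolean-array union of intervals on one chromosome."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    covered = np.zeros(hi + 1, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    out = []
    start = None
    for pos in range(hi + 1):
        if covered[pos] and start is None:
            start = pos
        elif not covered[pos] and start is not None:
            out.append((start, pos))
            start = None
    if start is not None:
        out.append((start, hi + 1))
    return out


# --- shared simulated data ---

SMALL_SPEC = CohortSpec(
    n_subgroups=3,
    samples_per_subgroup=12,
    n_genes=400,
    marker_sets_per_subgroup=2,
    n_gene_sets=40,
    genes_per_set=10,
    seed=11,
)

PLANTED_SPEC = CohortSpec(seed=7)  # the full study conditions


@pytest.fixture(scope="session")
def small_cohort() -> SimulatedCohort:
    return simulate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def planted_cohort() -> SimulatedCohort:
    return simulate_cohort(PLANTED_SPEC)


@pytest.fixture(scope="session")
def planted_profile(planted_cohort):
    return ssgsea_matrix(
        planted_cohort.expression, planted_cohort.gene_sets, SsgseaParams()
    )


@pytest.fixture(scope="session")
def planted_model(planted_cohort, planted_profile):
    return train_model(planted_profile, planted_cohort.labels, TrainConfig(seed=7))
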