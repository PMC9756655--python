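import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cdgmap.model import CdgmapError, EnzymeClass
from cdgmap.stats import (
    class_ratios,
    genus_mean_ratios,
    kde_circular,
    ks_two_sample,
    kuiper_two_sample,
    median_counts,
    per_genus_mean_counts,
    size_count_correlation,
)

C = EnzymeClass


# ---------------------------------------------------------------------------
# circular KDE


def test_kde_uniform_lattice_is_flat():
    positions = np.arange(0, 100, 0.25)
    est = kde_circular(positions, bandwidth=2.0)
    assert est.density.max() - est.density.min() < 0.05 * est.density.mean()


def test_kde_integrates_to_one(rng):
    for _ in range(5):
        est = kde_circular(rng.uniform(0, 100, 50))
        assert est.integral() == pytest.approx(1.0, abs=1e-6)


def test_kde_mass_straddling_wrap_is_continuous(rng):
    x = np.concatenate([rng.normal(0, 3, 250) % 100, rng.normal(99, 3, 250) % 100])
    est = kde_circular(x)
    step = est.grid[1] - est.grid[0]
    assert abs(est.density[0] - est.density[-1]) < 1e-3
    # single mode near the seam, not two half-modes
    peak = est.argmax()
    assert min(peak, 100 - peak) < 5


def test_kde_recovers_planted_mode(rng):
    x = rng.normal(50, 5, 500) % 100
    est = kde_circular(x)
    assert abs(est.argmax() - 50) <= 2


def test_kde_needs_two_points():
    with pytest.raises(CdgmapError):
        kde_circular([10.0])


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def brute_force_d(x, y):
    """Direct ECDF-sup oracle, quadratic and independent of the package."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def brute_force_exact_p(x, y):
    """Full enumeration over all C(n, |x|) label assignments."""
    pooled = list(x) + list(y)
    d_obs = brute_force_d(x, y)
    n_ge = total = 0
    for combo in itertools.combinations(range(len(pooled)), len(x)):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        n_ge += brute_force_d(xs, ys) >= d_obs - 1e-12
    return n_ge / total


def test_ks_identical_samples(rng):
    x = rng.uniform(0, 100, 8)
    res = ks_two_sample(x, x, method="exact_permutation")
    assert res.d_statistic == 0.0
    assert res.p_value == 1.0


def test_ks_disjoint_supports():
    res = ks_two_sample([1, 2, 3], [4, 5, 6])
    assert res.d_statistic == 1.0


def test_ks_interleaved_matches_enumeration():
    x, y = [1, 3, 5, 7], [2, 4, 6, 8]
    res = ks_two_sample(x, y, method="exact_permutation")
    assert res.d_statistic == pytest.approx(brute_force_d(x, y))
    assert res.p_value == pytest.approx(brute_force_exact_p(x, y))


def test_ks_d_matches_scipy(rng):
    # independent cross-check of the statistic against scipy's implementation
    for _ in range(20):
        x, y = rng.uniform(0, 100, 23), rng.uniform(0, 100, 17)
        ours = ks_two_sample(x, y).d_statistic
        assert ours == pytest.approx(sps.ks_2samp(x, y).statistic)


def test_ks_asymptotic_close_to_exact_at_n8(rng):
    diffs = []
    for _ in range(100):
        x, y = rng.uniform(0, 100, 8), rng.uniform(0, 100, 8)
        a = ks_two_sample(x, y, "asymptotic").p_value
        e = ks_two_sample(x, y, "exact_permutation").p_value
        diffs.append(abs(a - e))
    assert max(diffs) < 0.05


def test_ks_exact_size_capped():
    with pytest.raises(CdgmapError):
        ks_two_sample(range(10), range(10), method="exact_permutation")


def test_ks_empty_sample_rejected():
    with pytest.raises(CdgmapError):
        ks_two_sample([], [1.0])


def test_kuiper_rotation_invariant(rng):
    x, y = rng.uniform(0, 100, 40), rng.normal(20, 5, 40) % 100
    v1 = kuiper_two_sample(x, y).d_statistic
    v2 = kuiper_two_sample((x + 30) % 100, (y + 30) % 100).d_statistic
    assert v1 == pytest.approx(v2, abs=0.08)  # discrete ECDF, near-invariant


# ---------------------------------------------------------------------------
# counts, ratios, medians, correlation

TAX = pd.DataFrame({
    "genome_id": ["G1", "G2", "G3"],
    "order": ["O1", "O1", "O1"],
    "genus": ["A", "A", "B"],
    "species_or_strain": ["s1", "s2", "s3"],
})


def test_per_genus_mean_counts():
    out = per_genus_mean_counts({"G1": 10, "G2": 14, "G3": 7}, TAX)
    means = dict(zip(out["genus"], out["mean_count"]))
    assert means == {"A": 12.0, "B": 7.0}


def test_class_ratios_and_zero_guard():
    counts = {C.GGDEF: 4, C.EAL: 2, C.GGDEF_EAL: 0, C.HD_GYP: 0}
    r = class_ratios(counts)
    assert r["GGDEF:EAL"] == 2.0
    assert r["GGDEF:GGDEF_EAL"] is None
    assert r["GGDEF:HD-GYP"] is None


def test_genus_mean_ratio_excludes_undefined():
    counts = {
        "G1": {C.GGDEF: 4, C.EAL: 2, C.GGDEF_EAL: 1, C.HD_GYP: 0},
        "G2": {C.GGDEF: 4, C.EAL: 1, C.GGDEF_EAL: 1, C.HD_GYP: 0},
        "G3": {C.GGDEF: 3, C.EAL: 0, C.GGDEF_EAL: 1, C.HD_GYP: 1},
    }
    out = genus_mean_ratios(counts, TAX)
    a = out[(out["genus"] == "A") & (out["ratio"] == "GGDEF:EAL")]
    assert a["mean"].iloc[0] == pytest.approx(3.0)  # (2.0 + 4.0) / 2
    b_hd = out[(out["genus"] == "B") & (out["ratio"] == "GGDEF:HD-GYP")]
    assert b_hd["mean"].iloc[0] == pytest.approx(3.0)
    # genus A has no defined GGDEF:HD-GYP ratio at all
    assert out[(out["genus"] == "A") & (out["ratio"] == "GGDEF:HD-GYP")].empty


@pytest.mark.parametrize("counts,expected", [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5)])
def test_median_convention(counts, expected):
    assert median_counts(counts) == expected


def test_spearman_monotone_and_reverse():
    lengths = [1e6, 2e6, 3e6, 4e6]
    assert size_count_correlation(lengths, [1, 2, 3, 4]).rho == pytest.approx(1.0)
    assert size_count_correlation(lengths, [4, 3, 2, 1]).rho == pytest.approx(-1.0)


def test_spearman_matches_rank_oracle(rng):
    x = rng.uniform(1e6, 9e6, 50)
    y = rng.permutation(np.arange(50)).astype(float)
    res = size_count_correlation(x, y)
    # direct tie-free rank oracle: Pearson correlation of the rank vectors
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    expected = np.corrcoef(rx, ry)[0, 1]
    assert res.rho == pytest.approx(expected, abs=1e-12)


def test_spearman_constant_vector_flagged():
    res = size_count_correlation([1e6, 1e6, 1e6], [1, 2, 3])
    assert not res.defined and np.isnan(res.rho)
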