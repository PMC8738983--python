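"""Odds ratios: 2x2 closed form, logistic equivalence, mixed-model behaviour."""

import subprocess
import textwrap

import numpy as np
import pytest

from prepdiary.association import (
    DegenerateTableError,
    Method,
    SeparationError,
    logistic,
    mixed_logistic,
    odds_ratio_2x2,
)


# ----------------------------------------------------------------- 2x2 table

def test_2x2_wald_on_published_condomless_counts():
    """198/36 condomless/with-condom vs 197/87 in the reference class."""
    r = odds_ratio_2x2(198, 36, 197, 87)
    assert round(r.odds_ratio, 2) == 2.43
    assert round(r.ci95[0], 2) == 1.57
    assert round(r.ci95[1], 2) == 3.75  # Wald upper bound
    assert r.p_value < 0.001
    assert r.method is Method.TWO_BY_TWO_WALD


def test_2x2_symmetric_table_is_null():
    r = odds_ratio_2x2(10, 10, 10, 10)
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.p_value == pytest.approx(1.0)


def test_2x2_unit_cells_hand_arithmetic():
    r = odds_ratio_2x2(1, 1, 1, 1)
    assert r.se_log_or == pytest.approx(2.0)
    assert r.ci95 == pytest.approx((np.exp(-1.959963984540054 * 2),
                                    np.exp(1.959963984540054 * 2)))


def test_2x2_zero_cell_is_degenerate():
    with pytest.raises(DegenerateTableError):
        odds_ratio_2x2(33, 0, 197, 87)


def test_2x2_swap_inverts_or_and_mirrors_ci():
    r = odds_ratio_2x2(198, 36, 197, 87)
    s = odds_ratio_2x2(197, 87, 198, 36)
    assert s.odds_ratio == pytest.approx(1 / r.odds_ratio)
    assert s.ci95[0] == pytest.approx(1 / r.ci95[1])
    assert s.ci95[1] == pytest.approx(1 / r.ci95[0])
    assert s.p_value == pytest.approx(r.p_value)


# --------------------------------------------------------------- logistic

def _event_wise(a, b, c, d):
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(bool)
    cl = np.r_[np.full(a + b, 1), np.full(c + d, 2)]
    return y, cl


def test_logit_coefficient_equals_2x2_odds_ratio():
    y, cl = _event_wise(198, 36, 197, 87)
    [r] = logistic(y, cl, reference=2)
    table = odds_ratio_2x2(198, 36, 197, 87)
    assert r.odds_ratio == pytest.approx(table.odds_ratio, abs=1e-8)
    assert r.se_log_or == pytest.approx(table.se_log_or, abs=1e-8)
    assert r.method is Method.LOGISTIC


def test_logistic_separation_error_names_class():
    y = np.r_[np.ones(33), np.ones(10), np.zeros(10)].astype(bool)
    cl = np.r_[np.full(33, 3), np.full(20, 2)]
    with pytest.raises(SeparationError, match="3"):
        logistic(y, cl, reference=2)


def test_logistic_requires_two_classes():
    with pytest.raises(SeparationError):
        logistic(np.array([True, False]), np.array([1, 1]), reference=1)


def test_logistic_null_coverage():
    """Outcome independent of class: CI covers OR=1 in >=93% of simulations."""
    rng = np.random.default_rng(99)
    covered = 0
    n_sim = 400
    for _ in range(n_sim):
        cl = rng.integers(1, 3, size=160)
        y = rng.random(160) < 0.6
        # re-draw in the rare degenerate case
        while len({(c, o) for c, o in zip(cl, y)}) < 4:
            cl = rng.integers(1, 3, size=160)
            y = rng.random(160) < 0.6
        [r] = logistic(y, cl, reference=2)
        covered += r.ci95[0] <= 1.0 <= r.ci95[1]
    assert covered / n_sim >= 0.93


# ----------------------------------------------------------- mixed logistic

def _clustered_data(rng, n_groups=30, per_group=20, sd=1.0, beta=(0.0, np.log(2.0))):
    groups = np.repeat(np.arange(n_groups), per_group)
    cl = rng.integers(1, 3, size=n_groups * per_group)
    u = rng.normal(0, sd, size=n_groups)
    eta = beta[0] + beta[1] * (cl == 1) + u[groups]
    y = rng.random(len(eta)) < 1 / (1 + np.exp(-eta))
    return y, cl, groups


def test_mixed_with_sd_fixed_to_zero_equals_plain_logit():
    rng = np.random.default_rng(7)
    y, cl, groups = _clustered_data(rng, sd=0.0)
    [plain] = logistic(y, cl, reference=2)
    [mixed] = mixed_logistic(y, cl, groups, reference=2, fix_sd=0.0)
    assert np.log(mixed.odds_ratio) == pytest.approx(np.log(plain.odds_ratio), abs=1e-6)
    assert mixed.random_intercept_sd == 0.0


def test_mixed_free_fit_reduces_to_logit_when_no_clustering():
    rng = np.random.default_rng(8)
    y, cl, groups = _clustered_data(rng, n_groups=40, per_group=15, sd=0.0)
    [plain] = logistic(y, cl, reference=2)
    [mixed] = mixed_logistic(y, cl, groups, reference=2)
    assert np.log(mixed.odds_ratio) == pytest.approx(np.log(plain.odds_ratio), abs=1e-4)
    assert mixed.random_intercept_sd < 0.15


def test_mixed_recovers_conditional_or_and_exceeds_marginal():
    """30 participants x 20 events, intercept sd 1, conditional OR 2: the
    median estimate over seeds lands near 2 and is no smaller than the
    attenuated marginal (plain-logit) estimate on average."""
    ors, plains = [], []
    for seed in range(50):
        rng = np.random.default_rng(200 + seed)
        y, cl, groups = _clustered_data(rng, sd=1.0)
        try:
            [mixed] = mixed_logistic(y, cl, groups, reference=2)
            [plain] = logistic(y, cl, reference=2)
        except SeparationError:
            continue
        ors.append(mixed.odds_ratio)
        plains.append(plain.odds_ratio)
    assert 1.6 <= np.median(ors) <= 2.5
    assert np.median(ors) >= np.median(plains)


def test_mixed_requires_two_participants():
    y = np.array([True, False, True, False])
    cl = np.array([1, 1, 2, 2])
    with pytest.raises(ValueError, match="2 participants"):
        mixed_logistic(y, cl, np.zeros(4), reference=2)


def test_mixed_single_class_errors():
    y = np.array([True, False, True, False])
    with pytest.raises(SeparationError):
        mixed_logistic(y, np.ones(4), np.array([0, 0, 1, 1]), reference=1)


def test_mixed_matches_lme4_glmer_oracle(tmp_path):
    """Cross-check the adaptive-quadrature ML fit against lme4::glmer."""
    rng = np.random.default_rng(42)
    y, cl, groups = _clustered_data(rng, n_groups=25, per_group=12, sd=0.8)
    [mixed] = mixed_logistic(y, cl, groups, reference=2)

    csv = tmp_path / "d.csv"
    with open(csv, "w") as fh:
        fh.write("y,x,g\n")
        for yi, ci, gi in zip(y, cl, groups):
            fh.write(f"{int(yi)},{int(ci == 1)},{gi}\n")
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1 | g), data = d, family = binomial, nAGQ = 15)
        cat(fixef(m)["x"], sqrt(unlist(VarCorr(m))), sep = "\\n")
    """))
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
        timeout=300,
    )
    assert out.returncode == 0, out.stderr
    ref_beta, ref_sd = map(float, out.stdout.strip().split("\n"))
    assert np.log(mixed.odds_ratio) == pytest.approx(ref_beta, abs=5e-3)
    assert mixed.random_intercept_sd == pytest.approx(ref_sd, abs=2e-2)
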