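import math
from dataclasses import replace

import numpy as np
import pytest

from adcrepeat.error_model import ErrorModelParams
from adcrepeat.inference import (chi_squared_gof, fit_mle,
                                 negative_log_likelihood, standardise)
from adcrepeat.io import InsufficientDataError, pair_sessions
from adcrepeat.metrics import make_record, make_records
from adcrepeat.simulate import SyntheticConfig, generate_cohort

from conftest import make_pair

SYS5 = ErrorModelParams(0, 0, 5.0, "sys_only")


def _record_with_r12(r12):
    # symmetric pair whose percent_change equals r12 exactly
    d2 = 100.0
    d1 = d2 * (200 + r12) / (200 - r12)
    return make_record(make_pair(d1=d1, d2=d2))


def test_nll_single_record_shape():
    rec = _record_with_r12(0.0)
    # with r12 = 0 the NLL is ln(eps): smaller eps, smaller NLL
    a = negative_log_likelihood([rec], ErrorModelParams(0, 0, 2.0, "sys_only"))
    b = negative_log_likelihood([rec], ErrorModelParams(0, 0, 1.0, "sys_only"))
    assert a == pytest.approx(math.log(2.0)) and b == pytest.approx(0.0)
    assert b < a


def test_nll_two_record_hand_oracle():
    # records with r12 = 3 and -4, uncertainties 2 and 5:
    # NLL = ln 2 + 9/8 + ln 5 + 16/50
    recs = [_record_with_r12(3.0), _record_with_r12(-4.0)]
    # evaluate via per-record model eps using sys_only at each eps value
    nll = (negative_log_likelihood([recs[0]],
                                   ErrorModelParams(0, 0, 2.0, "sys_only"))
           + negative_log_likelihood([recs[1]],
                                     ErrorModelParams(0, 0, 5.0, "sys_only")))
    assert nll == pytest.approx(3.7475850929940457, rel=1e-12)


def test_nll_additivity():
    recs = [_record_with_r12(v) for v in (1.0, -2.0, 3.0)]
    whole = negative_log_likelihood(recs, SYS5)
    parts = sum(negative_log_likelihood([r], SYS5) for r in recs)
    assert whole == pytest.approx(parts, rel=1e-12)


def test_fit_sys_only_matches_closed_form():
    """The optimizer must reach the closed-form MLE
    eps_hat = sqrt(mean r12^2) to 1e-6 relative."""
    rng = np.random.default_rng(5)
    recs = [_record_with_r12(float(v))
            for v in rng.normal(0, 5.0, 200)]
    fit = fit_mle(recs, variant="sys_only", seed=2)
    closed = float(np.sqrt(np.mean([r.r12**2 for r in recs])))
    assert fit.params.epsilon_sys == pytest.approx(closed, rel=1e-6)
    assert fit.converged


def test_fit_sys_only_recovers_truth():
    rng = np.random.default_rng(9)
    recs = [_record_with_r12(float(v)) for v in rng.normal(0, 5.0, 200)]
    fit = fit_mle(recs, variant="sys_only", seed=0)
    assert fit.params.epsilon_sys == pytest.approx(5.0, rel=0.10)


def test_fit_reproducible_given_seed(tumour_records):
    a = fit_mle(tumour_records, seed=4)
    b = fit_mle(tumour_records, seed=4)
    assert a.params == b.params
    assert a.neg_log_likelihood == b.neg_log_likelihood


def test_fit_excludes_motion_and_counts(tumour_config):
    cfg = replace(tumour_config, motion_fraction=0.5, seed=21)
    records = make_records(pair_sessions(generate_cohort(cfg)).pairs)
    n_motion = sum(r.motion for r in records)
    assert n_motion > 0
    fit = fit_mle(records, seed=0)
    assert fit.n_excluded_motion == n_motion
    assert fit.n_records_used == len(records) - n_motion


def test_fit_all_motion_insufficient():
    recs = [make_record(make_pair(d1=100 + i, d2=100, motion1=True,
                                  patient=f"P{i}"))
            for i in range(5)]
    with pytest.raises(InsufficientDataError):
        fit_mle(recs, variant="three_param", exclude_motion=True)


def test_nested_variant_nll_ordering(tumour_records):
    fits = {v: fit_mle(tumour_records, variant=v, seed=1)
            for v in ("sys_only", "two_param", "three_param")}
    tol = 1e-6
    assert (fits["three_param"].neg_log_likelihood
            <= fits["two_param"].neg_log_likelihood + tol)
    assert (fits["two_param"].neg_log_likelihood
            <= fits["sys_only"].neg_log_likelihood + tol)


def test_gof_trivial_cases():
    recs = [_record_with_r12(0.0) for _ in range(4)]
    g = chi_squared_gof(recs, SYS5)
    assert g.chi2 == 0.0 and g.p_value == 1.0 and g.dof == 4
    # r12 == eps for every record -> chi2 = n
    recs = [_record_with_r12(5.0) for _ in range(7)]
    g = chi_squared_gof(recs, SYS5)
    assert g.chi2 == pytest.approx(7.0)
    assert g.dof == 7


def test_gof_subset_selector(tumour_records):
    params = ErrorModelParams(4.87, 69.35, 2.65)
    g3d = chi_squared_gof(tumour_records, params, subset="whole_3d")
    assert g3d.dof == 20
    gall = chi_squared_gof(tumour_records, params)
    assert gall.dof == len(tumour_records)
    with pytest.raises(InsufficientDataError):
        chi_squared_gof(tumour_records, params, subset="parenchyma")


def test_standardise_populates_z(tumour_records):
    params = ErrorModelParams(4.87, 69.35, 2.65)
    out, summary = standardise(tumour_records, params)
    assert all(r.z == pytest.approx(r.r12 / r.epsilon_r12) for r in out)
    assert summary.n == len(out)
    rec = _record_with_r12(5.0).with_uncertainty(5.0)
    assert rec.z == pytest.approx(1.0)


def test_standardised_residuals_near_standard_normal(tumour_config):
    """Generated under the model with the true parameters, z should be
    approximately N(0, 1)."""
    zs = []
    for s in range(30):
        cfg = replace(tumour_config, seed=300 + s)
        recs = make_records(pair_sessions(generate_cohort(cfg)).pairs)
        out, _ = standardise(recs, cfg.true_params)
        zs.extend(r.z for r in out)
    z = np.asarray(zs)
    assert abs(z.mean()) < 0.05
    assert 0.9 < z.std() < 1.1
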