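import numpy as np
import pytest

from tnbc_cea import default_cps10_config, run_analysis
from tnbc_cea.economics import apply_price_discount
from tnbc_cea.uncertainty import default_param_specs, run_psa


@pytest.fixture(scope="session")
def cps10():
    return default_cps10_config()


@pytest.fixture(scope="session")
def base_result(cps10):
    return run_analysis(cps10)


@pytest.fixture(scope="session")
def discount80_result(cps10):
    return run_analysis(apply_price_discount(cps10, "pembrolizumab", 0.8))


@pytest.fixture(scope="session")
def psa_result(cps10):
    return run_psa(cps10, default_param_specs(cps10), n_iter=1000, seed=cps10.psa.seed)


@pytest.fixture(scope="session")
def end_to_end_recovery():
    """Fit-and-select pipeline on data simulated from the two printed
    ground-truth families (50 seeds each, n=2000, ~20-30% censoring).
    Shared across the synthetic-data and acceptance suites."""
    from tnbc_cea.survival import ParametricSurvival, _loglik, fit_all_families, fit_mle, select_model
    from tnbc_cea.synthetic import SimulationSpec, simulate_ipd, table_ground_truth_curves

    results = {}
    n_rep = 50
    for name in ("pembrolizumab_pfs", "placebo_os"):
        truth = table_ground_truth_curves()[name]
        censor = 0.2 / truth.median()
        wins = 0
        first = None
        for seed in range(n_rep):
            ipd = simulate_ipd(SimulationSpec(
                truth, 2000, censor_rate=censor, admin_cutoff=120, seed=seed
            ))
            best = select_model(fit_all_families(ipd))
            wins += best.model.family == truth.family
            if seed == 0:
                fit = fit_mle(ipd, truth.family)

                def nll(x, ipd=ipd, fam=truth.family):
                    return -_loglik(ParametricSurvival(fam, tuple(x)),
                                    np.maximum(ipd.time, 1e-8), ipd.event)

                first = {"fit": fit, "se": fisher_se(nll, fit.model.params)}
        results[name] = {"truth": truth, "wins": wins, "n_rep": n_rep, **first}
    return results


def fisher_se(nll, x_opt, h=1e-4):
    """Standard errors from a central finite-difference Hessian of the
    negative log-likelihood at the optimum (observed information)."""
    x_opt = np.asarray(x_opt, dtype=float)
    k = len(x_opt)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            e_i = np.zeros(k)
            e_j = np.zeros(k)
            e_i[i] = h * max(abs(x_opt[i]), 1.0)
            e_j[j] = h * max(abs(x_opt[j]), 1.0)
            H[i, j] = (
                nll(x_opt + e_i + e_j) - nll(x_opt + e_i - e_j)
                - nll(x_opt - e_i + e_j) + nll(x_opt - e_i - e_j)
            ) / (4.0 * e_i[i] * e_j[j])
    return np.sqrt(np.diag(np.linalg.inv(H)))
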