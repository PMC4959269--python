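import numpy as np
import pytest

from adiposwitch import (ModelParameters, NoiseSpec, reference_params,
                         run_population, standard_dim_protocol)


@pytest.fixture(scope="session")
def ref():
    return reference_params()


@pytest.fixture(scope="session")
def unit_params():
    """All rates, basal terms and half-saturations equal to 1."""
    names = ("syn_cebpb syn_pparg syn_cebpa syn_pakt syn_ir syn_fat "
             "deg_cebpb deg_pparg deg_cebpa deg_pakt deg_ir deg_fat "
             "base_cebpb base_pparg base_cebpa base_ir "
             "alpha1 alpha2 alpha3 alpha4 alpha5 alpha6 alpha7 alpha8").split()
    return ModelParameters(**{n: 1.0 for n in names})


@pytest.fixture(scope="session")
def dim_ensemble_96h(ref):
    """A shared 400-cell default-noise population through induction + washout."""
    return run_population(400, standard_dim_protocol(48.0, 96.0), ref,
                          NoiseSpec(), sample_times=[24.0, 48.0, 96.0], seed=20)


def random_valid_params(rng: np.random.Generator) -> ModelParameters:
    """A random well-posed parameter set (for oracle/property tests)."""
    def pos(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ModelParameters(
        syn_cebpb=pos(0.1, 5), syn_pparg=pos(0.1, 5), syn_cebpa=pos(0.1, 5),
        syn_pakt=pos(0.1, 2), syn_ir=pos(0.02, 1), syn_fat=pos(0.05, 1),
        deg_cebpb=pos(0.05, 0.5), deg_pparg=pos(0.05, 0.5),
        deg_cebpa=pos(0.05, 0.5), deg_pakt=pos(0.2, 2),
        deg_ir=pos(0.02, 0.2), deg_fat=pos(0.02, 0.2),
        base_cebpb=pos(0.01, 0.2), base_pparg=pos(0.01, 0.2),
        base_cebpa=pos(0.01, 0.2), base_ir=pos(0.05, 0.3),
        alpha1=pos(1, 12), alpha2=pos(2, 20), alpha3=pos(0.5, 6),
        alpha4=pos(1, 6), alpha5=pos(0.2, 2), alpha6=pos(1, 12),
        alpha7=pos(0.3, 3), alpha8=pos(0.5, 6),
        rosi_gain=pos(1, 30), rosi_k=1.0)
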