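import numpy as np
import pytest

import cardiokin as ck


@pytest.fixture(scope="session")
def topo_2s():
    return ck.topology("2s")


@pytest.fixture(scope="session")
def preset_2s():
    return ck.preset("2s")


@pytest.fixture(scope="session")
def noisefree_2s():
    """Noise-free pooled dataset generated from the 2s preset."""
    return ck.generate_dataset(ck.topology("2s"), ck.preset("2s"),
                               noise=ck.NoiseModel(cv=0.0, seed=0))


@pytest.fixture(scope="session")
def noisefree_1():
    return ck.generate_dataset(ck.topology("1"), ck.preset("1"),
                               noise=ck.NoiseModel(cv=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_2s():
    """One paper-like noisy dataset from the 2s preset (cv = 0.22)."""
    return ck.generate_dataset(ck.topology("2s"), ck.preset("2s"),
                               noise=ck.NoiseModel(cv=0.22, seed=11))


def random_params(rng: np.random.Generator, model_id: str) -> ck.ParameterSet:
    """A random valid parameter draw over physiologically plausible decades."""
    logu = lambda lo, hi: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    values = {
        "V_syn": logu(50, 800), "C_sol_cyt": logu(500, 10000),
        "C_cyt_ims": logu(100, 2000), "V_atpase1": logu(20, 500),
        "Km_atp1": logu(0.05, 10), "Km_adp1": logu(0.05, 10),
    }
    if model_id != "1":
        values.update(V_pkend1=logu(50, 1000), Km_pk_adp=logu(0.05, 2))
    if model_id in ("2", "3", "4"):
        values.update(V_atpase2=logu(20, 500), Km_atp2=logu(0.05, 10),
                      Km_adp2=logu(0.05, 10))
    if model_id in ("3s", "3", "4s", "4"):
        values.setdefault("V_atpase2", logu(20, 5000))
        values.update(C_c4=logu(0.5, 600), V_pkend2=logu(1, 1000))
    return ck.ParameterSet(**values)
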