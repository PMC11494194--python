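import numpy as np
import pandas as pd
import pytest

import reefscape as rs


@pytest.fixture(scope="session")
def true_params() -> rs.TrueVitalParams:
    return rs.TrueVitalParams()


@pytest.fixture(scope="session")
def colony_records(true_params) -> pd.DataFrame:
    return rs.gen_colony_data(true_params, n_colonies=800, n_years=2, seed=11)


@pytest.fixture(scope="session")
def vital_rates(colony_records):
    return rs.fit_vital_rates(colony_records)


@pytest.fixture(scope="session")
def grid(vital_rates) -> rs.SizeGrid:
    return rs.build_size_grid(vital_rates.max_observed_area, n_classes=50)


@pytest.fixture(scope="session")
def type_specs():
    return rs.default_type_specs()


@pytest.fixture(scope="session")
def acropora_kernel(vital_rates, type_specs, grid):
    return rs.assemble_kernel(vital_rates, type_specs["corymbose_acropora"], grid)


@pytest.fixture()
def single_site_seascape():
    """One 1-ha site with full larval self-retention."""
    sites = pd.DataFrame(
        [dict(site_id="s1", reef="r1", zone="Slope", planar_area_m2=1e4,
              substrate_area_m2=1e4, depth_m=5.0, K_pct=80.0, modelled=True)]
    )
    conn = rs.ConnectivityMatrix(site_ids=("s1",), matrix=np.array([[1.0]]))
    return rs.Seascape(sites=sites, connectivity=conn)


def scalar_type_spec(name="scalar", **kw):
    defaults = dict(
        fertilisation_prob=0.0, settlement_prob=0.0, first_year_survival=0.0,
        morphology="branching", cots_preference_weight=1.0,
        bleach_intercept=-4.0, bleach_slope=0.35,
    )
    defaults.update(kw)
    return rs.CoralTypeSpec(name=name, **defaults)


def toy_kernel(P: np.ndarray, grid: rs.SizeGrid, eggs=None,
               fertilisation=0.0, first_year_survival=0.0) -> rs.IPMKernel:
    """Assemble an IPMKernel directly from a hand-set survival-growth block."""
    from reefscape.kernel import EGG, LARVA, N_DISCRETE, SETTLER, IPMKernel

    n = P.shape[0]
    m = N_DISCRETE + n
    F = np.zeros((m, m))
    if eggs is not None:
        F[EGG, N_DISCRETE:] = eggs
    M = np.zeros((m, m))
    M[N_DISCRETE:, N_DISCRETE:] = P
    M[LARVA, EGG] = fertilisation
    M[N_DISCRETE, SETTLER] = first_year_survival
    M += F
    return IPMKernel(matrix=M, P_part=P, F_part=F, grid=grid)


def tiny_grid(n: int, max_area: float = 200.0) -> rs.SizeGrid:
    if n == 1:
        bounds = np.array([1.0, max_area])
        return rs.SizeGrid(bounds=bounds, areas=np.sqrt(bounds[:1] * bounds[1:]))
    return rs.build_size_grid(max_area, n_classes=n)
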