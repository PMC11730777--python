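import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from matage import matrix_model as mm
from matage import synthetic_data as sd
from matage.rate_surfaces import RateSurfaces, build_rate_surfaces


def make_table(rows):
    """Build a life-history DataFrame from (id, trt, ma, day, status, off) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "treatment",
            "maternal_age",
            "age_day",
            "status",
            "offspring",
        ],
    )


@pytest.fixture
def toy_table():
    """Two individuals: A dies on day 3, B is censored on day 4 (7 rows)."""
    return make_table(
        [
            ("A", "AL", 3, 1, "alive", 0),
            ("A", "AL", 3, 2, "alive", 2),
            ("A", "AL", 3, 3, "dead", 0),
            ("B", "LF", 3, 1, "alive", 0),
            ("B", "LF", 3, 2, "alive", 1),
            ("B", "LF", 3, 3, "alive", 3),
            ("B", "LF", 3, 4, "censored", 0),
        ]
    )


@pytest.fixture(scope="session")
def study_table():
    """Synthetic table at the laboratory design: 2 treatments x 4 cohorts x n=70."""
    return sd.generate(sd.SyntheticParams(), seed=101)


@pytest.fixture(scope="session")
def truth_surfaces():
    return sd.ground_truth_surfaces(sd.SyntheticParams())


@pytest.fixture(scope="session")
def truth_models(truth_surfaces):
    return {t: mm.assemble(s) for t, s in truth_surfaces.items()}


@pytest.fixture(scope="session")
def study_surfaces(study_table):
    return {t: build_rate_surfaces(study_table, t) for t in ("AL", "LF")}


@pytest.fixture(scope="session")
def study_models(study_surfaces):
    return {t: mm.assemble(s) for t, s in study_surfaces.items()}


def leslie_model(U, F, treatment="toy"):
    """Wrap explicit small matrices as a BlockModel (no vital-rate grids)."""
    U = sp.csr_matrix(np.asarray(U, dtype=float))
    F = sp.csr_matrix(np.asarray(F, dtype=float))
    return mm.BlockModel(treatment=treatment, U=U, F=F)


def toy_surfaces_2x2(l=None, m=None, treatment="toy"):
    """A 2-maternal-age, 2-age-class rate surface for hand-checked assembly."""
    l = np.array([[1, 0.8, 0.4], [1, 0.6, 0.3]]) if l is None else np.asarray(l)
    m = np.array([[1.0, 2.0], [0.5, 1.0]]) if m is None else np.asarray(m)
    return RateSurfaces(treatment=treatment, l=l, m=m)
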