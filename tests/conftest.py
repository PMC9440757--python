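import warnings

import numpy as np
import pytest

from rootniche import (
    Grid1D,
    LayoutTemplate,
    ModelParams,
    ModelSpec,
    default_config,
    generate_layout,
)


@pytest.fixture(scope="session")
def variant_configs():
    """Packaged default (spec, params) for the four 1D variants."""
    out = {}
    for name in ("sequestration", "sequestration_z", "repression", "mixed"):
        cfg = default_config(name)
        out[name] = (cfg.spec, cfg.params)
    return out


@pytest.fixture
def euler_grid():
    return Grid1D.euler_default()


@pytest.fixture
def quick_grid():
    """Short domain for fast Euler runs in unit tests."""
    return Grid1D(-150.0, 150.0, 1.0)


@pytest.fixture(scope="session")
def tiny_layout():
    """Small typed synthetic layout shared across 2D tests."""
    tpl = LayoutTemplate.small(width=80, height=144)
    layout, stain = generate_layout(tpl, seed=7)
    return tpl, layout, stain


def closed_form_mutant_w(x, p, half_domain):
    """Independent piecewise solution of D W'' - d W + g*1_{|x|<=L/2} = 0
    with W(+-X) = 0: the linear source-diffusion-decay oracle."""
    ell = np.sqrt(p.D_W / p.d_W)
    a = p.L_QC / 2
    g = p.gamma / p.d_W
    X = half_domain
    A = np.array(
        [
            [np.cosh(a / ell), -np.sinh((X - a) / ell)],
            [np.sinh(a / ell), np.cosh((X - a) / ell)],
        ]
    )
    C1, C2 = np.linalg.solve(A, np.array([-g, 0.0]))
    inside = np.abs(x) <= a
    out = np.where(
        inside,
        g + C1 * np.cosh(x / ell),
        C2 * np.sinh(np.clip((X - np.abs(x)) / ell, 0.0, None)),
    )
    return out


@pytest.fixture
def mutant_closed_form():
    return closed_form_mutant_w


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Unit tests often run deliberately short integrations; silence the
    non-stationarity warning so intentional short runs stay quiet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
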