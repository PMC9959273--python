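import numpy as np
import pytest

from chiralloid import DLVOParameters, ProbeGeometry
from chiralloid.synthetic import ForceCurveSpec, gen_force_curve, load_reference_pairs


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_pairs()


@pytest.fixture(scope="session")
def cnc_params():
    """The CNC-CNC pair: kappa = 0.04125 nm^-1, Z = 9.305e-3 nN, 5 um sphere."""
    return DLVOParameters(kappa=0.04125, z_const=9.305e-3, hamaker=3.6e-21,
                          geometry=ProbeGeometry(5000.0))


@pytest.fixture
def make_noiseless_curve():
    """Factory for clean forward-model curves (no artifact, no noise)."""

    def _make(params, d_range=(40.0, 200.0), n_points=200, **kw):
        spec = ForceCurveSpec(
            params=params, d_range=d_range, n_points=n_points,
            noise_sd=0.0, contact_artifact_amplitude=0.0, **kw,
        )
        return gen_force_curve(spec)

    return _make


@pytest.fixture(scope="session")
def all_pair_params(reference_table):
    """DLVOParameters for every reference pair, keyed by label."""
    out = {}
    for row in reference_table.itertuples():
        out[row.pair_label] = DLVOParameters(
            kappa=row.kappa_per_nm, z_const=row.z_nN, hamaker=3.6e-21,
            geometry=ProbeGeometry(5000.0),
        )
    return out
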