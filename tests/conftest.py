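import io

import numpy as np
import pytest

from crispri_circuits.equilibrium_model import BindingParams, SpeciesTotals
from crispri_circuits.plate_kinetics import load_plate
from crispri_circuits.synthetic_data import PlateTruth, WellTruth, generate_plate


@pytest.fixture
def params():
    """Reference dissociation constants: K1 = 0.3 nM, K2 = 2 nM."""
    return BindingParams(K1=0.3, K2=2.0)


@pytest.fixture
def make_plate_truth():
    """Factory for a plate of sample wells with randomized ground truth."""

    def _make(noise_cv=0.0, seed=0, n_samples=4):
        rng = np.random.default_rng(seed)
        # reference strains in biological triplicate, as assayed in practice
        wells = {}
        for i in (1, 2, 3):
            wells[f"A{i}"] = WellTruth(strain="J101R", role="reference",
                                       s_true={"RFP": 80.0, "GFP": 5.0})
            wells[f"A{i + 3}"] = WellTruth(strain="J101G", role="reference",
                                           s_true={"RFP": 5.0, "GFP": 40.0})
        for i in range(n_samples):
            wells[f"B{i + 1}"] = WellTruth(
                strain=f"sample{i + 1}",
                mu_true=float(rng.uniform(0.5, 0.9)),
                s_true={
                    "RFP": float(rng.uniform(20.0, 120.0)),
                    "GFP": float(rng.uniform(10.0, 60.0)),
                },
            )
        return PlateTruth(wells=wells, noise_cv=noise_cv, seed=seed)

    return _make


@pytest.fixture
def wells_from_frames():
    """Round-trip generated DataFrames through the CSV loader."""

    def _load(plate_df, wellmap_df):
        pbuf, wbuf = io.StringIO(), io.StringIO()
        plate_df.to_csv(pbuf, index=False)
        wellmap_df.to_csv(wbuf, index=False)
        pbuf.seek(0)
        wbuf.seek(0)
        return load_plate(pbuf, wbuf)

    return _load


@pytest.fixture
def generated_wells(make_plate_truth, wells_from_frames):
    def _make(noise_cv=0.0, seed=0, n_samples=4):
        truth = make_plate_truth(noise_cv=noise_cv, seed=seed, n_samples=n_samples)
        plate, wellmap, record = generate_plate(truth)
        return wells_from_frames(plate, wellmap), truth

    return _make


@pytest.fixture
def totals_mid():
    return SpeciesTotals(Ctot=1000.0, gtot=1000.0, Dtot=10.0)
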