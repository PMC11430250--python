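"""Shared fixtures: a small synthetic dataset and a quickly trained model.

Everything is generated at test time from seeds; no data files ship with the
package.  The "small" fixtures (2 subjects, 128 Hz, 0.5 s windows) keep the
unit suite fast; the full desk-scale study conditions live in
``dfcgn.pipeline.DEFAULT_RUN_CONFIG`` and are exercised by the acceptance
tests.
"""

import numpy as np
import pytest

import dfcgn
from dfcgn.pipeline import _filter_spec, load_run_config
from dfcgn.preprocess import epochs_from_recordings
from dfcgn.synth import HIGH_CONTRAST_CLASS_BAND_POWER, SynthConfig


@pytest.fixture(scope="session")
def small_synth_cfg() -> SynthConfig:
    return SynthConfig(
        n_subjects=2,
        fs=128.0,
        noise_snr_db=20.0,
        class_band_power={c: dict(v) for c, v in HIGH_CONTRAST_CLASS_BAND_POWER.items()},
        seed=11,
    )


@pytest.fixture(scope="session")
def epochs_small(small_synth_cfg) -> dfcgn.EpochSet:
    """600 half-second windows from 2 subjects, preprocessed end to end."""
    recs = dfcgn.generate_dataset(small_synth_cfg)
    cfg = load_run_config()
    return epochs_from_recordings(
        recs, channels=["FP1", "Pz", "Fz"], spec=_filter_spec(cfg),
        epoch_s=15.0, window_s=0.5,
    )


@pytest.fixture(scope="session")
def trained_small(epochs_small):
    """A briefly trained reduced-ledger model plus its splits."""
    tcfg = dfcgn.TrainConfig(
        optimizer="adam", lr=1e-3, lr_decay=0.9, epochs=10,
        weight_decay=6e-6, ft2_xi=1e-4, seed=3,
    )
    tr, va, te = dfcgn.split_epochs(epochs_small, tcfg)
    G = dfcgn.graph_from_epochs(tr, tau=0.5)
    model = dfcgn.DFCGN(dfcgn.reduced_config(n_nodes=3), G, seed=3)
    model, history = dfcgn.train(model, tr, va, tcfg)
    return {"model": model, "train": tr, "val": va, "test": te,
            "history": history, "cfg": tcfg}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
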