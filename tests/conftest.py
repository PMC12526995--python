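import numpy as np
import pytest

from mdcpr import (
    CompressionScenario,
    RadarConfig,
    SubjectProfile,
    campaign_cycles,
    phase_synthesize,
    project_radial,
    simulate_kinematics,
)
from mdcpr.synthetic import generate_campaign


@pytest.fixture(scope="session")
def config() -> RadarConfig:
    return RadarConfig()


@pytest.fixture(scope="session")
def clean_profile() -> SubjectProfile:
    """A subject that compresses exactly as instructed (no variability)."""
    return SubjectProfile(depth_bias_cm=0.0, depth_jitter_sd_cm=0.0, rate_jitter_sd_cpm=0.0)


@pytest.fixture(scope="session")
def make_signal(config, clean_profile):
    """Factory for noise-free (by default) simulated compression signals."""

    def _make(
        depth_cm=5.0,
        rate_cpm=100.0,
        duration_s=10.0,
        angle_deg=0.0,
        noise_snr_db=None,
        seed=0,
        profile=None,
    ):
        scenario = CompressionScenario(
            target_depth_cm=depth_cm,
            rate_cpm=rate_cpm,
            duration_s=duration_s,
            aspect_angle_deg=angle_deg,
            subject_profile=profile or clean_profile,
            noise_snr_db=noise_snr_db,
            rng_seed=seed,
        )
        trace = simulate_kinematics(scenario, config)
        radial = project_radial(trace, angle_deg)
        sig = phase_synthesize(radial, config, noise_snr_db=noise_snr_db, seed=seed)
        return sig, trace

    return _make


@pytest.fixture(scope="session")
def case1_cycles(config):
    """Per-cycle dataset of the chest-position campaign at 20 dB SNR.

    8 subjects x 4 depths x 3 rates, 30 s records -- the frontal-geometry
    slice of the full measurement campaign.
    """
    manifest = generate_campaign(
        config,
        subjects=8,
        cases={1: 0.0},
        depths_cm=(3.0, 4.0, 5.0, 6.0),
        rates_cpm=(90.0, 100.0, 110.0),
        seed=20260927,
        duration_s=30.0,
        noise_snr_db=20.0,
    )
    cycles = campaign_cycles(manifest, config, with_images=False)
    assert not cycles.empty
    return cycles


@pytest.fixture(scope="session")
def cnn_dataset(config):
    """~300 single-cycle spectrogram crops from 5 subjects (frontal case)."""
    manifest = generate_campaign(
        config,
        subjects=5,
        cases={1: 0.0},
        depths_cm=(3.0, 4.0, 5.0, 6.0),
        rates_cpm=(100.0,),
        seed=42,
        duration_s=10.0,
        noise_snr_db=20.0,
    )
    cycles = campaign_cycles(manifest, config, with_images=True)
    assert len(cycles) >= 250
    return cycles


@pytest.fixture(scope="session")
def cnn_fold(cnn_dataset):
    """One subject-exclusive CNN training fold (train 4 subjects, test 1)."""
    from mdcpr.cnn import TrainConfig, build_cnn, train_cnn

    train = cnn_dataset[cnn_dataset["subject"] != 4]
    test = cnn_dataset[cnn_dataset["subject"] == 4]
    model = build_cnn(seed=7)
    history = train_cnn(
        model,
        np.stack(train["image"].to_list()),
        train["depth_ref_cm"].to_numpy(),
        TrainConfig(max_epochs=30, patience=8, seed=7),
    )
    return model, history, train, test
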