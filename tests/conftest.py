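import pytest

from pulsestage.preprocess import CLASS_ORDER
from pulsestage.synth import SynthConfig, generate_dataset, generate_record


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, jitter-free config whose ground truth is exactly recoverable."""
    return SynthConfig(
        duration_s=10.0, heart_rate_bpm=60.0, hr_jitter_frac=0.0,
        sbp_mmHg=140.0, dbp_mmHg=90.0, bp_jitter_mmHg=0.0,
        noise_snr_db=None, seed=11,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_record(clean_config)


@pytest.fixture(scope="session")
def noisy_record():
    """60 s record at 10 dB SNR for detector stress tests."""
    cfg = SynthConfig(duration_s=60.0, heart_rate_bpm=70.0, hr_jitter_frac=0.05,
                      noise_snr_db=10.0, seed=21)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def small_segments():
    """~600 labeled segments, ~120 per class, under default study conditions."""
    from pulsestage.preprocess import build_segments

    counts = {lab: 120 for lab in CLASS_ORDER}
    records = generate_dataset(counts, SynthConfig(seed=7))
    return build_segments(records)
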