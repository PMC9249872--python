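import pytest

from tstms.simulator import (
    OpticsModel,
    SubjectProfile,
    default_class_templates,
    make_cohort,
    render_recording,
)

SMALL_RES = {c: (200, 140) for c in ["R", "G", "B", "NIR", "LWIR"]}


@pytest.fixture(scope="session")
def templates():
    return default_class_templates()


@pytest.fixture(scope="session")
def oracle_profile():
    # 1.25 Hz at 30 fps samples the sinusoid's extremes exactly
    return SubjectProfile(
        subject_id="S-oracle", gender="F", heart_rate_hz=1.25,
        skin_base_intensity={"R": 150.0, "G": 150.0, "B": 150.0, "NIR": 150.0},
        base_temp_c=34.0, phase_map_seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_optics():
    return OpticsModel(
        specular_Rs=0.0,
        noise_sd={c: 0.0 for c in ["R", "G", "B", "NIR", "LWIR"]},
        quantize=False,
    )


@pytest.fixture(scope="session")
def oracle_recording(oracle_profile, templates, noiseless_optics):
    """Noiseless, unquantized, phase-free trial for closed-form checks."""
    return render_recording(
        oracle_profile, templates["A"], noiseless_optics,
        phase_amplitude=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def noisy_recording(templates):
    profile = SubjectProfile(
        subject_id="S-noisy", gender="M", heart_rate_hz=1.4,
        skin_base_intensity={"R": 140.0, "G": 160.0, "B": 130.0, "NIR": 150.0},
        base_temp_c=34.5, phase_map_seed=3,
    )
    return render_recording(profile, templates["A"],
                            native_resolutions=SMALL_RES, seed=5)


@pytest.fixture(scope="session")
def noisy_cube(noisy_recording):
    from tstms.preprocess import build_cube

    return build_cube(noisy_recording)


@pytest.fixture(scope="session")
def tiny_cohort_dataset(templates):
    """Featurized 2-subject, 2-class cohort shared by classifier-level tests."""
    from tstms.pipeline import featurize_cohort

    cohort = make_cohort(2, classes="AN", trials_per_class=3, seed=9,
                         templates=templates, native_resolutions=SMALL_RES)
    ds, table = featurize_cohort(cohort)
    return ds, table
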