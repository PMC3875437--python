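import pytest

import rheoscan as rs


@pytest.fixture(scope="session")
def clean_dataset():
    """Benchmark synthetic dataset at zero measurement noise."""
    cfg = rs.default_config(seed=11, noise_cv=0.0)
    variants, truth, contexts = rs.simulate_dataset(cfg)
    return cfg, variants, truth, contexts


@pytest.fixture(scope="session")
def noisy_dataset():
    """Benchmark synthetic dataset at the default replicate noise."""
    cfg = rs.default_config(seed=11, noise_cv=0.2)
    variants, truth, contexts = rs.simulate_dataset(cfg)
    return cfg, variants, truth, contexts


@pytest.fixture(scope="session")
def synthetic_msa():
    cfg = rs.default_config(seed=11)
    aln, truth = rs.simulate_msa(cfg)
    return cfg, aln, truth


def make_profile(parent, parent_sd, del_control, activities, sds=None,
                 position="51", homolog="H1"):
    """Build a PositionProfile from bare activity values."""
    aas = "ACDEFGHIKLMNPQRSTVW"
    sds = sds if sds is not None else [0.0] * len(activities)
    ctx = rs.HomologContext(
        homolog_id=homolog, parent_activity=parent, parent_sd=parent_sd,
        del_control=del_control,
    )
    ms = [
        rs.RepressionMeasurement(
            homolog_id=homolog, position=position, wildtype_aa="Y",
            substituted_aa=aas[i], condition=rs.MINUS,
            mean_activity=float(a), sd_activity=float(s), n_replicates=4,
        )
        for i, (a, s) in enumerate(zip(activities, sds))
    ]
    return rs.PositionProfile(ctx, position, ms)
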