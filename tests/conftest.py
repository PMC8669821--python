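import pytest

import mobifof as m


@pytest.fixture(scope="session")
def fofneg_spec():
    return m.default_phenotype("FOF-")


@pytest.fixture(scope="session")
def lab_session(fofneg_spec):
    """One synthesized lab session (TUG + two 5xSTS blocks) with truth."""
    rec, tl = m.generate_lab_session(fofneg_spec, seed=0)
    return rec, tl


@pytest.fixture(scope="session")
def short_days():
    """Three synthesized short wear days (18 min) with ground truth."""
    spec = m.default_phenotype("FOF-", bouts_per_day_by_class=(3, 2, 1),
                               wear_hours_per_day=0.3)
    days = m.generate_daily_recording(spec, 3, seed=3, synthesize=True,
                                      wear_hours=0.3)
    return spec, days


@pytest.fixture(scope="session")
def small_cohort():
    """Timeline-only cohort (5 FOF+ / 8 FOF-, 2 days) with features."""
    from mobifof.pipeline import cohort_feature_table

    subs = m.generate_cohort(5, 8, seed=11, n_days=2)
    return subs, cohort_feature_table(subs, seed=11)
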