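"""Shared helper for building two-group synthetic cohorts in tests."""

from manimouse import GroupSpec, generate_cohort


def cohort_recordings(params_a: dict, params_b: dict, n_sessions: int, seed: int):
    """Recordings of a two-group cohort ('baseline' vs 'compact') from one seed."""
    groups = [
        GroupSpec(name="baseline", n_sessions=n_sessions, **params_a),
        GroupSpec(name="compact", n_sessions=n_sessions, **params_b),
    ]
    return [rec for rec, _ in generate_cohort(groups, seed=seed, with_behavior=False)]
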