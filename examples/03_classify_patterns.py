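"""Classify canonical spatial patterns of Oct4 expression.

Each fixture realises one of the six pattern classes by construction:
uniform Oct4+, an Oct4- core (inside-out), an Oct4- rim (outside-in), two
contiguous Oct4- blobs (connected), and i.i.d. coin-flip states (random).
The classifier recovers each label from the aggregate's contact graph and
radial composition alone.
"""

from ebsim import FixtureKind, FixtureSpec, classify, make_fixture, pattern_metrics

for kind in [
    FixtureKind.UNIFORM_STATE,
    FixtureKind.SHELL_INSIDE_OUT,
    FixtureKind.SHELL_OUTSIDE_IN,
    FixtureKind.TWO_BLOB_CONNECTED,
    FixtureKind.CHECKERBOARD_RANDOM,
]:
    agg = make_fixture(FixtureSpec(kind=kind, size=400, seed=1))
    m = pattern_metrics(agg)
    print(
        f"{kind.value:20s} -> {classify(agg).value:12s} "
        f"(%Oct4+ {100 * m.fraction_pos:4.0f}, UCN {m.ucn}, DCN {m.dcn})"
    )
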