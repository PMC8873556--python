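"""Extract the nine tapping features from a single session.

A session is a stream of (t, x, y) tap events.  The features summarize
tapping speed (meanTapInter, medianTapInter, numberTaps), timing
regularity (cvTapInter), spatial precision per target side (cvDrift*,
skewDrift*) and diagonal drift of the tap positions (corXY).
"""

from tapclust import FEATURE_NAMES, default_archetypes, extract_features, generate_session

low, mid, high = default_archetypes()
for arch in (low, high):
    session = generate_session(arch, duration=20.0, seed=5)
    v = extract_features(session)
    print(f"archetype {arch.name!r}: {session.n_taps} taps in 20 s")
    for name in FEATURE_NAMES:
        print(f"    {name:>15}: {getattr(v, name):8.3f}")

# The high-severity archetype taps more slowly (larger meanTapInter, fewer
# taps) and with stronger x-y coupling (larger corXY) than the low one.
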