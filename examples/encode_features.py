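"""Encode one window under all eight feature schemes.

Each scheme turns the same 41-bp window into a numeric vector of a
fixed, scheme-specific width (the KNN scheme additionally needs a
labelled reference set, from which it reads the positive fraction among
the nearest neighbours).  These vectors are the inputs of the CNN+BLSTM
extractors.
"""

from mc4deep import (
    GeneratorConfig,
    Scheme,
    encode,
    encode_knn,
    feature_length,
    generate,
)

samples = generate(GeneratorConfig(n_pos=25, n_neg=25, effect=0.8, seed=3))
window = samples[0]
print(f"window {window.id}: {window.sequence} (label={window.label})\n")

for scheme in Scheme:
    if scheme is Scheme.KNN:
        vec = encode_knn(window, samples[1:])
    else:
        vec = encode(window, scheme)
    width = feature_length(scheme, 41)
    head = ", ".join(f"{v:.3f}" for v in vec[:4])
    print(f"{scheme.value:>8}: length {width:>3}, first values [{head}, ...]")

print("\nWidths are fixed by the window length (41 bp) and the scheme's")
print("definition; BKF's 500 is the canonical extractor input size.")
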