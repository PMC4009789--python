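"""Encode two Cα traces as eigenvalue fingerprints and align them.

Builds two synthetic chains — one a jittered copy of the other, one from an
unrelated fold — and prints their comparison scores.  Lower is more
similar: a score of 0 means identical fingerprints, and related structures
score well below unrelated ones.
"""

from eigas import (
    GapModel,
    comparison_score,
    dp_align,
    fingerprint_chain,
    generate_synthetic_family,
    similarity_matrix,
)

KAPPA = 19.0  # contact cutoff, Å
GAPS = GapModel(rho_open=0.5, rho_continue=0.3)

related = generate_synthetic_family(
    n_members=2, length=60, template_seed=11, jitter_sd=0.3, member_seed=101
)
unrelated = generate_synthetic_family(
    n_members=1, length=60, template_seed=99, jitter_sd=0.3, member_seed=900
)[0]

fp_a, fp_b = (fingerprint_chain(c, KAPPA) for c in related)
fp_c = fingerprint_chain(unrelated, KAPPA)

for name, fp_other in [("jittered copy", fp_b), ("unrelated fold", fp_c)]:
    result = dp_align(similarity_matrix(fp_a, fp_other), GAPS)
    n_gaps = sum(1 for i, j in result.path if i is None or j is None)
    print(
        f"{name:>14}: raw value {result.raw_value:6.3f} over {len(result.path)} columns "
        f"({n_gaps} gaps) -> score {comparison_score(result):.4f}"
    )

print(
    "\nThe jittered copy scores near 0 (same fold, small coordinate noise);"
    "\nthe unrelated fold scores an order of magnitude higher."
)
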