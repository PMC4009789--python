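"""How much coordinate noise can the alignment absorb?

Each Cα coordinate is redrawn from a normal whose per-axis variance is
s²·B/(24π²) — the spread implied by its crystallographic B-factor, scaled
by s.  For each scale s the whole benchmark is re-encoded, re-aligned and
re-scored 40 times; the mean AUROC with a trimmed (drop min and max)
interval shows where family recognition starts to degrade.
"""

from eigas import generate_synthetic_family, robustness_curve

chains = generate_synthetic_family(
    n_members=4, length=40, template_seed=11, jitter_sd=0.3, member_seed=101
) + generate_synthetic_family(
    n_members=4, length=40, template_seed=22, jitter_sd=0.3, member_seed=202
)
families = {c.chain_id: c.family_id for c in chains}

table = robustness_curve(
    chains,
    families,
    triple=(19.0, 0.5, 0.3),
    s_values=[0.0, 1.0, 5.0, 20.0, 50.0],
    n_samples=40,
    master_seed=7,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\ns = 0 is the unperturbed run; s = 1 reproduces the experimental"
    "\nuncertainty itself (recognition is unaffected); by s = 50 the noise"
    "\ndwarfs the 3.8 Å backbone spacing and AUROC collapses toward 0.5."
)
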