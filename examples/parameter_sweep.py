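"""Family-recognition quality over a parameter grid, with sub-group tuning.

Generates six labelled synthetic families, evaluates AUROC over a small
(kappa, rho_open, rho_continue) grid, then runs the inverted three-fold
protocol: tune on one random sub-group of families, validate the winning
triple on the union of the other two.
"""

from eigas import crossval_tune, generate_synthetic_family, parameter_grid, sweep

chains = []
for t_seed, m_seed in [(11, 101), (22, 202), (33, 303), (44, 404), (55, 505), (66, 606)]:
    chains.extend(
        generate_synthetic_family(
            n_members=3, length=30, template_seed=t_seed, jitter_sd=0.3, member_seed=m_seed
        )
    )
families = {c.chain_id: c.family_id for c in chains}

grid = parameter_grid(kappas=[5.0, 9.0, 19.0], rho_opens=[0.3, 0.5], rho_continues=[0.3])
table = sweep(chains, families, grid)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nSmall cutoffs see too few contacts to discriminate folds; from"
    "\nkappa ~ 9 Å upward the families separate (near-)perfectly."
)

results = crossval_tune(chains, families, grid, n_subgroups=3, seed=5)
print("\nsub-group tuning (tune on 2 families, validate on the other 4):")
for r in results:
    print(
        f"  group {r.subgroup}: best (kappa, rho_o, rho_c) = "
        f"({r.best_kappa:g}, {r.best_rho_open:g}, {r.best_rho_continue:g}), "
        f"tuning AUROC {r.tuning_auroc:.4f} -> validation AUROC {r.validation_auroc:.4f}"
    )
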