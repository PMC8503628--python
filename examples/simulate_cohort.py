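"""Generate a synthetic preeclampsia lipidomics cohort and inspect it.

The generator reproduces the structure of a 64-sample maternal-serum
case/control study: 729 lipid species, correlated lipid blocks (one
oxidized-phospholipid-like block rewired between conditions), planted
case/control effects, clinical confounders drawn from the published
cohort summary, and left-censored missingness.
"""

from lipidflow.simulate import SimConfig, inject_missingness, simulate_cohort

config = SimConfig(seed=42)
matrix, clinical, truth = simulate_cohort(config)
matrix = inject_missingness(matrix, config.missing_rate,
                            config.censoring_steepness, seed=config.seed)

print(f"abundance matrix: {matrix.n_samples} samples x {matrix.n_lipids} lipids")
print(f"cases / controls: {(clinical.status == 1).sum()} / "
      f"{(clinical.status == 0).sum()}")
print(f"lipid classes: {matrix.lipid_classes.nunique()}")
print(f"missing fraction: {matrix.values.isna().mean().mean():.3f} "
      "(left-censored: low abundances go missing more often)")
print(f"planted differential lipids: {truth.true_differential}")
print(f"rewired module: {truth.rewired_module} "
      "(tightly correlated in cases, loose in controls)")
print(f"planted causal chain: {truth.true_causal_edges}")
print("\nclinical covariates (first cases):")
print(clinical.head(4).to_string())
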