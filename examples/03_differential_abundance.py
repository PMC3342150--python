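"""Find miRNAs differentially present between relapsing and non-relapsing patients.

The cohort carries the two planted markers: miR-375 lower (-1.90 log2) and
miR-122 higher (+1.35 log2) in patients who later relapse with metastatic
disease. The exact conditional NB test (common dispersion, estimated from the
data) should surface exactly these two genes at low FDR; the regimen-adjusted
GLM likelihood-ratio test is the 'multivariate' variant that accounts for the
three chemotherapy regimens.
"""

from circmir import diffabund, synth

ref = synth.make_reference(seed=8)
cfg = synth.SimulationConfig(seed=8, mean_library_size=100_000)
counts, metadata = synth.simulate_cohort(cfg, ref)

table = diffabund.differential_table(counts, metadata, contrast="relapse")
print(f"common dispersion estimate: phi = {table.attrs['phi']:.3f}")
print("top genes, relapsed vs non-relapsed (exact NB test):")
cols = ["gene", "mean_g1", "mean_g2", "log2_fold", "p_value", "fdr"]
print(table[cols].head(4).round({"mean_g1": 0, "mean_g2": 0, "log2_fold": 2})
      .to_string(index=False))

adjusted = diffabund.differential_table(
    counts, metadata, contrast="relapse", adjust="regimen")
print("\nsame contrast adjusted for NCT regimen (NB-GLM likelihood-ratio test):")
print(adjusted[cols].head(4).round({"mean_g1": 0, "mean_g2": 0, "log2_fold": 2})
      .to_string(index=False))

n_hits = int((table["fdr"] < 0.1).sum())
print(f"\n{n_hits} gene(s) at FDR < 0.1; negative log2 fold means lower in "
      "relapsing patients (the miR-375 direction).")
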