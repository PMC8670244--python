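"""Immune microenvironment and Sorafenib-sensitivity scoring.

Cytolytic activity (mean log10 of five granzymes + PRF1), HLA class-I
summary, signature scores from bundled GMT lists, ferroptosis-gene vs
immune-fraction Pearson correlations, a 5-cluster immune-composition
contrast across risk groups, and the six-gene Sorafenib sensitivity score
with CTD-style gene classification and IC50 concordance.
"""

import pandas as pd

import ferrostrat as fs

cohort = fs.simulate_cohort(fs.CohortConfig(seed=1))
risk = cohort.truth_labels
expr = cohort.expression

cyt = fs.cytolytic_score(expr)
hla = fs.hla_summary(expr)
sigs = fs.read_gene_sets(fs.bundled_path("immune_signatures.gmt"))
ifng = fs.signature_score(expr, sigs["IFNG_6"], name="ifng")
print("group means (higher = more immune-active microenvironment):")
print(pd.DataFrame({"cytolytic": cyt, "hla_mean": hla, "ifng": ifng})
      .groupby(risk).mean().round(3).to_string())

kept = fs.filter_immune_samples(cohort.immune_fractions, p_max=0.05)
print(f"\nimmune deconvolution quality gate kept {len(kept)} of {len(cohort.immune_fractions)} samples")

corr = fs.frg_immune_correlation(expr, kept, genes=list(fs.FRG_PANEL))
strongest = corr.abs().stack().idxmax()
print(f"strongest gene/cell-type correlation: {strongest} r={corr.loc[strongest]:.3f}")

labels, table, chi = fs.immune_composition_clusters(kept, risk.loc[kept.index], k=5, seed=0)
print("\nimmune-composition cluster x risk-group contingency:")
print(table.to_string())
print(chi[["group_a", "group_b", "neg_log10_p"]].round(2).to_string(index=False))

sor = fs.sorafenib_sensitivity_score(expr)
print("\nSorafenib sensitivity score by group (higher = predicted more sensitive):")
print(sor.groupby(risk).mean().round(3).to_string())

ctd = fs.read_gene_sets(fs.bundled_path("sorafenib_genes.synthetic_subset.gmt"))
cls = fs.classify_ctd_genes(expr, risk, [g for g in ctd["SORAFENIB_ASSOCIATED"] if g in expr.index])
print("CTD-style classification:", cls["class"].value_counts().to_dict())

# three synthetic cell lines: score vs IC50 concordance
lines = pd.Index(["LINE_A", "LINE_B", "LINE_C"])
scores = pd.Series([1.5, 0.2, -1.1], index=lines)
ic50 = pd.Series([0.8, 3.0, 11.0], index=lines)  # micromolar
rho, concordant, n = fs.score_ic50_concordance(scores, ic50)
print(f"score vs IC50 Spearman rho = {rho:.2f} over {n} lines; "
      f"{'concordant' if concordant else 'not concordant'} "
      "(negative rho: higher score, lower IC50, i.e. more drug-sensitive)")
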