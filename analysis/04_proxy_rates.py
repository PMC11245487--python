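"""Estimate per-gene Proxy Rates (ROCC) in both conditions.

Runs the zero-intercept regression over all three timepoints (the
"global" variant) and the two single-timepoint variants, with the
per-quartile breakdown for the latter, then contrasts the conditions:
the elongation-accelerated condition should show the higher median
Proxy Rate.
"""

import pandas as pd

import study
from proxyrate import proxy_rate_table
from proxyrate.quant import paired_signed_rank

genes = study.load_genes()

tables = []
for condition in study.CONDITIONS:
    tracks = study.load_tracks(condition)
    for variant, quartiles in (
        ("global", False), ("single_5", True), ("single_10", True),
    ):
        tables.append(
            proxy_rate_table(
                tracks, genes, study.GRID,
                variant=variant, quartiles=quartiles, condition=condition,
            )
        )
rates = pd.concat(tables, ignore_index=True)
rates.to_csv(study.RESULTS / "04_proxy_rates.tsv", sep="\t", index=False)

print("Median Proxy Rate by condition and variant (signal units / min):")
medians = rates.groupby(["variant", "condition"])["proxy_rate"].median().unstack()
print(medians.round(4).to_string())

wide = rates.query("variant == 'global'").pivot(
    index="gene_id", columns="condition", values="proxy_rate"
)
stat, p = paired_signed_rank(wide["control"], wide["depleted"])
ratio = medians.loc["global", "depleted"] / medians.loc["global", "control"]
print(f"\nGlobal variant: depleted/control median ratio = {ratio:.2f} "
      f"(Wilcoxon signed-rank W = {stat:g}, p = {p:.3g})")

q5 = rates.query("variant == 'single_5'").groupby("condition")[
    ["Q1", "Q2", "Q3", "Q4"]
].median()
print("\nMedian quartile Proxy Rates, single-timepoint 5 min variant:")
print(q5.round(4).to_string())
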