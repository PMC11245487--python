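"""Quantify promoter-proximal, gene-body and 3′-end densities.

Reads the cached time-course tracks, computes per-gene region densities
at every timepoint/condition, the induction log2 fold change of gene-body
density against control 0 min, Tukey five-number summaries per contrast,
and the condition-mean metagene profile at 10 min.
"""

import pandas as pd

import study
from proxyrate import (
    condition_log2fc,
    derive_regions,
    five_number_summary,
    metagene_matrix,
)
from proxyrate.quant import density_table, paired_signed_rank

genes = study.load_genes()
region_sets = [derive_regions(g) for g in genes]

tables = []
for condition in study.CONDITIONS:
    for t, track in study.load_tracks(condition).items():
        tables.append(density_table(track, region_sets))
dens = pd.concat(tables, ignore_index=True)
dens.to_csv(study.RESULTS / "03_region_densities.tsv", sep="\t", index=False)

# gene-body induction relative to control at 0 min
gb = dens.query("region == 'GB'").pivot_table(
    index="gene_id", columns=["condition", "timepoint"], values="density"
)
ref = gb[("control", 0.0)]
lfc_rows = []
for condition in study.CONDITIONS:
    for t in study.GRID.times[1:]:
        lfc = [
            condition_log2fc(gb.loc[g, (condition, t)], ref.loc[g]) for g in gb.index
        ]
        s = five_number_summary(lfc)
        lfc_rows.append(
            dict(
                condition=condition, timepoint=t,
                median_log2fc=s.median, q1=s.q1, q3=s.q3,
                lower_whisker=s.lower_whisker, upper_whisker=s.upper_whisker,
                n_outliers=len(s.outliers),
            )
        )
lfc_summary = pd.DataFrame(lfc_rows)
lfc_summary.to_csv(study.RESULTS / "03_gb_log2fc_summary.tsv", sep="\t", index=False)

# paired contrast of GB density between conditions at 5 min
a = gb[("control", 5.0)]
b = gb[("depleted", 5.0)]
stat, p = paired_signed_rank(a, b)
print("Gene-body density, depleted vs control at 5 min "
      f"(Wilcoxon signed-rank): W = {stat:g}, p = {p:.3g}")
print(lfc_summary.to_string(index=False))

# metagene profiles at 10 min
profiles = {}
for condition in study.CONDITIONS:
    track = study.load_tracks(condition)[10.0]
    mm = metagene_matrix(track, genes, body_bins=100, flank=1000, flank_bin=50)
    profiles[condition] = mm.mean_profile
pd.DataFrame(profiles).to_csv(
    study.RESULTS / "03_metagene_profiles_t10.tsv", sep="\t", index_label="bin"
)
print("Wrote region densities, log2FC summaries and 10-min metagene profiles")
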