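"""Overrepresentation of the methylation-correlated genes in GMT terms.

Fisher's exact test of the top correlated genes against each annotated
term over the screened-gene background, BH-FDR across terms, and the
conventional fold > 2 / q < 0.05 filter.
"""

from pathlib import Path

import pandas as pd

from mtp9 import enrich, exprcorr, p9quant, synth
from mtp9.sites import read_site_table

cohort = Path("scratch/example_cohort")
if not cohort.exists():
    synth.simulate_cohort(synth.SimConfig(n_per_group=20, depth_mean=500, causal_beta=0.3, seed=42), cohort)

sites = read_site_table(cohort / "sites.tsv")
matrix, _ = p9quant.quantify_directory(cohort / "pileups", sites)
counts = pd.read_csv(cohort / "counts.tsv", sep="\t", index_col=0)
t2g = pd.read_csv(cohort / "t2g.tsv", sep="\t", index_col=0)

norm = exprcorr.cpm(counts, exprcorr.tmm_factors(counts), log=True)
corr = exprcorr.correlate_with_methylation(norm, matrix[585])
_, top_genes = exprcorr.select_top(corr, n=100, t2g=t2g)

terms = enrich.load_gmt(cohort / "genesets.gmt")
background = list(dict.fromkeys(t2g["gene"]))
rows = enrich.overrepresentation(top_genes, terms, background)
kept = enrich.filter_fold(rows, min_fold=2.0, max_q=0.05)

print(rows.head(3)[["observed", "expected", "fold", "p", "q"]].round(4).to_string())
print(f"\nterms passing fold>2 and q<0.05: {list(kept.index)}")
# The planted term (genes of the methylation-driven transcripts) should
# lead with fold >> 2; the 19 random terms stay near fold 1.
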