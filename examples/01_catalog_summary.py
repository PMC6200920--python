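"""Summarize the packaged RFamide peptide catalog.

Loads the curated catalog (26 chordate GnIH-family peptides + 71 distinct
C. elegans FLPs) and prints the headline counts.
"""

from rfamide import catalog

peptides, precursors = catalog.load_catalog()
summary = catalog.summarize_catalog(peptides)

print(f"peptides total:        {summary.n_peptides_total}")
print(f"  chordate:            {summary.n_chordate_peptides}")
print(f"  nematode FLPs:       {summary.n_flps_total}")
print(f"  FLPs identified:     {summary.n_flps_identified}")
print(f"flp genes:             {summary.n_flp_genes}")
print(f"max FLPs per gene:     {summary.max_flps_per_gene}")
print(f"precursor manifest:    {len(precursors)} records")

# The totals count distinct sequences: FLP-6 is encoded six times in its
# precursor but contributes one peptide.
flp6 = next(r for r in peptides if r.peptide_id == "FLP-6")
print(f"example: {flp6.peptide_id} = {catalog.display_sequence(flp6)} "
      f"x{flp6.copy_number} copies in {flp6.gene_id}")
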