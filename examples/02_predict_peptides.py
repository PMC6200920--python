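"""Predict mature amidated peptides from a precursor polypeptide.

Builds a miniature precursor around the human RFRP-3 body (VPNLPQRFa) with
the genuine processing signals — an upstream basic residue, the amidation
glycine and a dibasic K/R site — and runs the cleavage predictor.
"""

from rfamide import processing

precursor = "MDSKA" + "R" + "VPNLPQRF" + "GRK" + "SSLEA"
print(f"precursor: {precursor}")

for site in processing.find_amidation_sites(precursor):
    print(f"amidation site: G at {site.position}, basic run "
          f"{site.basic_run!r} ({site.kind})")

for call in processing.predict_from_sequence("demo", precursor):
    print(f"call: [{call.start}, {call.end}) {call.sequence}a "
          f"motif={call.motif}")
# The single call recovers the embedded peptide body exactly: the glycine
# donates the C-terminal amide and is not part of the peptide.
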